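import pytest
from hypothesis import HealthCheck, settings

from aneuvar import fixtures
from aneuvar.classify import classify_batch

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bundle():
    return fixtures.load_bundle()


@pytest.fixture(scope="session")
def golden_classifications(bundle):
    """variant key -> assigned tier for the bundled 47-variant table."""
    results, _ = classify_batch(bundle.variants)
    return {v.key: r.tier for v, r in zip(bundle.variants, results)}
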