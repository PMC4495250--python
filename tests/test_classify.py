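"""Rule engine: golden tiers, precedence, monotonicity and an independent oracle."""

import random

import pytest
from hypothesis import given, strategies as st

from aneuvar.classify import (
    ClassificationError,
    classify_batch,
    classify_variant,
    reclassify_with_alt_frequency,
)
from aneuvar.model import (
    Consequence,
    LiteratureTier,
    SpliceVerdict,
    Tier,
    TruncationFrame,
    VariantAnnotation,
)
from aneuvar.simulate import EvidenceMixture, simulate_variants


def oracle_tier(v: VariantAnnotation, threshold=0.01, source="primary") -> Tier:
    """Independent re-statement of the rule precedence, evaluated row by row.

    Deliberately written as a flat walk over (condition, tier) pairs rather
    than sharing any code with the engine.
    """
    maf = v.maf_primary if source == "primary" else v.maf_alt
    rows = [
        (maf is not None and maf >= threshold, Tier.BENIGN),
        (v.truncation_frame == TruncationFrame.OUT_OF_FRAME, Tier.PATHOGENIC),
        (v.truncation_frame == TruncationFrame.NEW_IN_FRAME, Tier.LIKELY_PATHOGENIC),
        (v.literature_tier == LiteratureTier.REPORTED_SUPPORTED,
         Tier.LIKELY_PATHOGENIC),
        (v.splice_verdict == SpliceVerdict.EFFECT, Tier.VUS),
        (v.consequence == Consequence.INFRAME_INDEL, Tier.VUS),
        (v.consequence == Consequence.MISSENSE and v.damaging_count >= 2, Tier.VUS),
        (v.literature_tier == LiteratureTier.REPORTED_INSUFFICIENT, Tier.VUS),
        (True, Tier.LIKELY_BENIGN),
    ]
    for condition, tier in rows:
        if condition:
            return tier
    raise AssertionError("unreachable")


def test_golden_table_tiers(bundle):
    """Every one of the 47 curated variants classifies to its published tier."""
    results, counts = classify_batch(bundle.variants)
    for v, r in zip(bundle.variants, results):
        assert r.tier is bundle.gold_class[v.key], (v.key, r.rule_fired)
    assert counts == {
        Tier.BENIGN: 0,
        Tier.LIKELY_BENIGN: 23,
        Tier.VUS: 21,
        Tier.LIKELY_PATHOGENIC: 1,
        Tier.PATHOGENIC: 2,
    }


@pytest.mark.parametrize(
    "key,tier,rule",
    [
        ("COL3A1:c.1471C>T", Tier.PATHOGENIC, "TRUNC_OUT_OF_FRAME"),
        ("TGFBR2:c.1573delA", Tier.PATHOGENIC, "TRUNC_OUT_OF_FRAME"),
        ("MYH11:c.760C>T", Tier.LIKELY_PATHOGENIC, "LIT_SUPPORTED"),
        ("EFEMP2:c.277G>A", Tier.LIKELY_BENIGN, "DEFAULT_LB"),
        ("TGFB2:c.703G>C", Tier.VUS, "MISSENSE_DAMAGING_GE2"),
        ("FBN1:c.59A>G", Tier.VUS, "LIT_FLOOR_VUS"),
        ("COL3A1:c.898-14A>G", Tier.VUS, "SPLICE_EFFECT"),
        ("MYLK:c.3403G>A", Tier.VUS, "MISSENSE_DAMAGING_GE2"),
    ],
)
def test_named_examples_and_rules(bundle, key, tier, rule):
    v = {x.key: x for x in bundle.variants}[key]
    result = classify_variant(v)
    assert result.tier is tier and result.rule_fired == rule


def test_frequency_rule_dominates():
    v = VariantAnnotation(
        gene="G", cdna_hgvs="c.1C>T", protein_hgvs="p.Arg1X",
        consequence=Consequence.NONSENSE,
        truncation_frame=TruncationFrame.OUT_OF_FRAME,
        maf_primary=0.5,
    )
    result = classify_variant(v)
    assert result.tier is Tier.BENIGN and result.rule_fired == "FREQ_GE_THRESHOLD"


def test_alt_source_reclassifies_common_dutch_variant(bundle):
    v = {x.key: x for x in bundle.variants}["MYLK:c.1327C>T"]
    assert classify_variant(v, source="primary").tier is Tier.VUS
    alt = classify_variant(v, source="alt")
    assert alt.tier is Tier.BENIGN and alt.freq_used == pytest.approx(0.014)


def test_reclassification_diff_is_exactly_one_variant(bundle):
    changes = reclassify_with_alt_frequency(bundle.variants)
    assert [
        (c.variant_key, c.old_tier, c.new_tier) for c in changes
    ] == [("MYLK:c.1327C>T", Tier.VUS, Tier.BENIGN)]

    # with all alternate frequencies stripped there is nothing to reclassify
    import dataclasses

    stripped = [dataclasses.replace(v, maf_alt=None) for v in bundle.variants]
    assert reclassify_with_alt_frequency(stripped) == []


def test_all_neutral_missense_set_is_likely_benign():
    variants = [
        VariantAnnotation(
            gene="G", cdna_hgvs=f"c.{3 * i + 1}G>A", protein_hgvs="p.Ala1Thr",
            consequence=Consequence.MISSENSE, damaging_count=0, panel_size=5,
            splice_verdict=SpliceVerdict.NO_EFFECT,
        )
        for i in range(20)
    ]
    _, counts = classify_batch(variants)
    assert counts[Tier.LIKELY_BENIGN] == 20


def test_missense_without_panel_is_an_error():
    v = VariantAnnotation(
        gene="G", cdna_hgvs="c.4G>A", consequence=Consequence.MISSENSE,
        panel_size=0,
    )
    with pytest.raises(Exception, match="uninterpretable predictor panel"):
        classify_variant(v)
    with pytest.raises(ClassificationError, match="G:c.4G>A"):
        classify_batch([v])


def test_batch_matches_independent_oracle_on_simulated_variants():
    """1000 mixture-drawn variants: engine tier == decision-table oracle tier."""
    mixture = EvidenceMixture(maf_common_prob=0.05)
    variants = simulate_variants(1000, mixture, seed=2026)
    results, counts = classify_batch(variants)
    from collections import Counter

    expected = Counter(oracle_tier(v) for v in variants)
    for v, r in zip(variants, results):
        assert r.tier is oracle_tier(v), v.key
    assert {t: counts[t] for t in Tier if counts[t]} == dict(expected)


def test_classification_is_deterministic_and_order_free(bundle):
    results_a, _ = classify_batch(bundle.variants)
    results_b, _ = classify_batch(bundle.variants)
    assert results_a == results_b
    shuffled = bundle.variants[:]
    random.Random(7).shuffle(shuffled)
    by_key = {v.key: classify_variant(v) for v in shuffled}
    for v, r in zip(bundle.variants, results_a):
        assert by_key[v.key] == r


# --- property tests ----------------------------------------------------------

@st.composite
def annotated_variants(draw):
    consequence = draw(st.sampled_from(list(Consequence)))
    truncating = consequence in (Consequence.NONSENSE, Consequence.FRAMESHIFT)
    panel = draw(st.integers(1, 8)) if consequence is Consequence.MISSENSE else 0
    maf = draw(st.none() | st.floats(0, 1, allow_nan=False))
    maf_alt = draw(st.none() | st.floats(0, 1, allow_nan=False))
    return VariantAnnotation(
        gene="G",
        cdna_hgvs="c.100G>A",
        consequence=consequence,
        splice_verdict=draw(st.sampled_from(list(SpliceVerdict))),
        damaging_count=draw(st.integers(0, panel)) if panel else 0,
        panel_size=panel,
        maf_primary=maf,
        maf_alt=maf_alt,
        literature_tier=draw(st.sampled_from(list(LiteratureTier))),
        truncation_frame=draw(
            st.sampled_from(
                [TruncationFrame.OUT_OF_FRAME, TruncationFrame.NEW_IN_FRAME]
            )
        )
        if truncating
        else TruncationFrame.NOT_TRUNCATING,
    )


@given(annotated_variants(), st.floats(0.001, 1.0), st.floats(0.0, 1.0))
def test_raising_maf_never_moves_away_from_benign(v, threshold, bump):
    import dataclasses

    base = classify_variant(v, threshold=threshold)
    raised_maf = min(1.0, (v.maf_primary or 0.0) + bump)
    raised = classify_variant(
        dataclasses.replace(v, maf_primary=raised_maf), threshold=threshold
    )
    if base.tier is Tier.BENIGN:
        assert raised.tier is Tier.BENIGN
    if raised_maf >= threshold:
        assert raised.tier is Tier.BENIGN


@given(st.integers(0, 8), st.integers(0, 8), st.booleans())
def test_more_damaging_calls_never_demote_missense(k1, k2, below_threshold):
    import dataclasses

    k1, k2 = min(k1, k2), max(k1, k2)
    v = VariantAnnotation(
        gene="G", cdna_hgvs="c.9G>A", consequence=Consequence.MISSENSE,
        panel_size=8, splice_verdict=SpliceVerdict.NO_EFFECT,
        maf_primary=0.001 if below_threshold else None,
    )
    lo = classify_variant(dataclasses.replace(v, damaging_count=k1))
    hi = classify_variant(dataclasses.replace(v, damaging_count=k2))
    assert hi.tier.rank >= lo.tier.rank


@given(annotated_variants())
def test_rule_is_consistent_with_tier(v):
    result = classify_variant(v)
    assert (result.tier is Tier.BENIGN) == (result.rule_fired == "FREQ_GE_THRESHOLD")
    assert (result.tier is Tier.PATHOGENIC) == (
        result.rule_fired == "TRUNC_OUT_OF_FRAME"
    )
    if result.tier is Tier.LIKELY_PATHOGENIC:
        assert result.rule_fired in ("TRUNC_NEW_IN_FRAME", "LIT_SUPPORTED")
    assert result.tier is oracle_tier(v)
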