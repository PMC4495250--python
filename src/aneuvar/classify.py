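"""Rule-based five-tier pathogenicity classification.

Variants are assigned to one of five tiers — benign, likely benign, VUS
(unknown significance), likely pathogenic, pathogenic — by a fixed-precedence
rule table; the first matching rule wins and is recorded on the result, so
every classification is auditable.

Rule precedence
---------------
1.  ``FREQ_GE_THRESHOLD``   selected-source MAF present and >= threshold
                            (default 0.01)                      -> benign
2.  ``TRUNC_OUT_OF_FRAME``  frameshift/nonsense, or a splice defect, such
                            that no in-frame protein can be made -> pathogenic
3.  ``TRUNC_NEW_IN_FRAME``  truncation creating a new in-frame
                            protein                      -> likely pathogenic
4.  ``LIT_SUPPORTED``       previously linked to disease with reviewed
                            supporting evidence          -> likely pathogenic
5.  ``SPLICE_EFFECT``       any non-truncating variant predicted to affect
                            splicing                                 -> VUS
6.  ``INFRAME_INDEL``       in-frame deletion/insertion              -> VUS
7.  ``MISSENSE_DAMAGING_GE2``  missense with >= 2 damaging predictor
                            calls                                    -> VUS
8.  ``LIT_FLOOR_VUS``       a single prior patient report without
                            sufficient evidence floors the tier at   -> VUS
9.  ``DEFAULT_LB``          remaining intronic/synonymous variants with no
                            splice effect, and missense with <= 1 damaging
                            call                             -> likely benign

The frequency rule is unconditional: a variant at or above the population
frequency threshold is benign regardless of any other evidence.  A common
*truncating* variant is classified benign and flagged with a warning, since
that combination is biologically surprising.

The likely-benign boundary for missense variants generalises the "4/5 or 3/4
predictions neutral" reading to *at most one damaging call* on any panel, so
panels of arbitrary size classify consistently.  Segregation and conservation
are annotations only and never move the tier.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .model import (
    Consequence,
    LiteratureTier,
    ModelError,
    SpliceVerdict,
    Tier,
    TruncationFrame,
    VariantAnnotation,
)

logger = logging.getLogger(__name__)

FREQ_SOURCES = ("primary", "alt")
DEFAULT_THRESHOLD = 0.01


@dataclass(frozen=True)
class ClassificationResult:
    tier: Tier
    rule_fired: str
    freq_source: str
    freq_used: float | None


@dataclass(frozen=True)
class ReclassificationChange:
    """A variant whose tier changed when the frequency source was switched."""

    variant_key: str
    old_tier: Tier
    new_tier: Tier
    freq_used: float | None


class ClassificationError(ModelError):
    """A variant could not be classified; carries the variant key."""


def classify_variant(
    v: VariantAnnotation,
    threshold: float = DEFAULT_THRESHOLD,
    source: str = "primary",
) -> ClassificationResult:
    """Assign one variant to a tier under the fixed rule precedence."""
    if source not in FREQ_SOURCES:
        raise ValueError(f"unknown frequency source {source!r}")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"frequency threshold {threshold} outside (0, 1]")
    v.validate()

    maf = v.maf(source)

    # 1. population frequency, unconditional
    if maf is not None and maf >= threshold:
        if v.truncation_frame is not TruncationFrame.NOT_TRUNCATING:
            logger.warning(
                "%s: frequency rule (MAF %.4g >= %.4g) overrides truncating "
                "consequence; classified benign",
                v.key, maf, threshold,
            )
        return ClassificationResult(Tier.BENIGN, "FREQ_GE_THRESHOLD", source, maf)

    # 2-3. truncation
    if v.truncation_frame is TruncationFrame.OUT_OF_FRAME:
        return ClassificationResult(Tier.PATHOGENIC, "TRUNC_OUT_OF_FRAME", source, maf)
    if v.truncation_frame is TruncationFrame.NEW_IN_FRAME:
        return ClassificationResult(
            Tier.LIKELY_PATHOGENIC, "TRUNC_NEW_IN_FRAME", source, maf
        )

    # 4. reviewed and supported prior disease report
    if v.literature_tier is LiteratureTier.REPORTED_SUPPORTED:
        return ClassificationResult(
            Tier.LIKELY_PATHOGENIC, "LIT_SUPPORTED", source, maf
        )

    # 5. predicted splice effect on a non-truncating variant
    if v.splice_verdict is SpliceVerdict.EFFECT:
        return ClassificationResult(Tier.VUS, "SPLICE_EFFECT", source, maf)

    # 6. in-frame indel
    if v.consequence is Consequence.INFRAME_INDEL:
        return ClassificationResult(Tier.VUS, "INFRAME_INDEL", source, maf)

    # 7. missense with >= 2 damaging predictor calls
    if v.consequence is Consequence.MISSENSE and v.damaging_count >= 2:
        return ClassificationResult(Tier.VUS, "MISSENSE_DAMAGING_GE2", source, maf)

    # 8. prior report without sufficient evidence floors at VUS
    if v.literature_tier is LiteratureTier.REPORTED_INSUFFICIENT:
        return ClassificationResult(Tier.VUS, "LIT_FLOOR_VUS", source, maf)

    # 9. everything else is likely benign
    return ClassificationResult(Tier.LIKELY_BENIGN, "DEFAULT_LB", source, maf)


def classify_batch(
    variants: list[VariantAnnotation],
    threshold: float = DEFAULT_THRESHOLD,
    source: str = "primary",
) -> tuple[list[ClassificationResult], dict[Tier, int]]:
    """Classify each variant in order; return results plus tier counts."""
    if not variants:
        raise ClassificationError("classify_batch requires a non-empty variant list")
    results: list[ClassificationResult] = []
    for v in variants:
        try:
            results.append(classify_variant(v, threshold=threshold, source=source))
        except (ModelError, ValueError) as exc:
            raise ClassificationError(f"{v.key}: {exc}") from exc
    summary = Counter(r.tier for r in results)
    return results, {tier: summary.get(tier, 0) for tier in Tier}


def reclassify_with_alt_frequency(
    variants: list[VariantAnnotation],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[ReclassificationChange]:
    """Tiers that change when the alternate population frequency is used.

    Classifies every variant twice — once with the primary (reference
    database) MAF, once with the alternate (population-specific) MAF — and
    reports only the variants whose tier changed.
    """
    primary, _ = classify_batch(variants, threshold=threshold, source="primary")
    alt, _ = classify_batch(variants, threshold=threshold, source="alt")
    changes = []
    for v, p, a in zip(variants, primary, alt):
        if p.tier is not a.tier:
            changes.append(
                ReclassificationChange(v.key, p.tier, a.tier, a.freq_used)
            )
    return changes


__all__ = [
    "ClassificationResult",
    "ReclassificationChange",
    "ClassificationError",
    "classify_variant",
    "classify_batch",
    "reclassify_with_alt_frequency",
    "DEFAULT_THRESHOLD",
]
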