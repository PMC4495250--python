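"""Minor-allele-frequency arithmetic for a biallelic site.

All arithmetic is exact (integer/rational) until the final display rounding.
MAF = (n_CT + 2 n_TT) / 2n for n = n_CC + n_CT + n_TT subjects.  Rounding is
round-half-up on the exact rational, which is the convention the reference
genotype tables use (e.g. 69/260 -> 0.265, 45/130 -> 35 %).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .model import GenotypeCounts, ModelError


def round_half_up(x: Fraction | float, ndigits: int = 0) -> float:
    """Exact round-half-up for non-negative rationals.

    floor(x * 10^n + 1/2) / 10^n, computed on exact fractions so that
    boundary cases (e.g. 59.5 %) never depend on binary float artefacts.
    """
    q = Fraction(x) * 10**ndigits + Fraction(1, 2)
    rounded = q.numerator // q.denominator  # floor for non-negative inputs
    return rounded / 10**ndigits if ndigits else float(rounded)


@dataclass(frozen=True)
class FrequencySummary:
    """MAF and integer genotype percentages for one genotype-count table."""

    n: int
    maf: float  # rounded to 3 d.p.
    maf_exact: Fraction
    pct_cc: int
    pct_ct: int
    pct_tt: int
    pct_carrier: int  # CT and TT combined


def maf_from_genotypes(g: GenotypeCounts) -> FrequencySummary:
    """Exact MAF and genotype percentages from CC/CT/TT counts."""
    g.validate()
    if g.n == 0:
        raise ModelError(f"{g.study}/{g.group}: no subjects (n = 0)")
    maf_exact = Fraction(g.n_variant_alleles, g.n_alleles)
    pct = lambda count: int(round_half_up(Fraction(100 * count, g.n)))
    return FrequencySummary(
        n=g.n,
        maf=round_half_up(maf_exact, 3),
        maf_exact=maf_exact,
        pct_cc=pct(g.n_cc),
        pct_ct=pct(g.n_ct),
        pct_tt=pct(g.n_tt),
        pct_carrier=pct(g.n_ct + g.n_tt),
    )


def pool_studies(
    groups: list[GenotypeCounts],
    study: str = "Overall",
    group: str = "pooled",
) -> tuple[GenotypeCounts, FrequencySummary]:
    """Cell-wise pooling of genotype counts across studies.

    The pooled MAF is the allele-count-weighted mean of the member MAFs and
    therefore always lies within their range.
    """
    if not groups:
        raise ModelError("pool_studies requires a non-empty group list")
    pooled = GenotypeCounts(
        study=study,
        group=group,
        n_cc=sum(g.n_cc for g in groups),
        n_ct=sum(g.n_ct for g in groups),
        n_tt=sum(g.n_tt for g in groups),
    )
    return pooled, maf_from_genotypes(pooled)


@dataclass(frozen=True)
class ReferenceComparison:
    """Descriptive (non-inferential) comparison with a reference population."""

    study_maf: float
    reference_maf: float
    difference: float  # study - reference, on the 3 d.p. scale


def compare_to_reference(
    g: GenotypeCounts, reference_maf: float
) -> ReferenceComparison:
    if not 0.0 <= reference_maf <= 1.0:
        raise ModelError(f"reference_maf {reference_maf} outside [0, 1]")
    summary = maf_from_genotypes(g)
    return ReferenceComparison(
        study_maf=summary.maf,
        reference_maf=reference_maf,
        difference=round(summary.maf - reference_maf, 3),
    )


__all__ = [
    "FrequencySummary",
    "ReferenceComparison",
    "round_half_up",
    "maf_from_genotypes",
    "pool_studies",
    "compare_to_reference",
]
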