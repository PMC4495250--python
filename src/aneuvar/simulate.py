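"""Synthetic cohort and genotype generation.

The generator emulates the statistical structure of the study the bundled
fixtures come from: a cohort of familial/sporadic AAA patients screened on a
ten-gene panel, with per-gene, per-arm carrier probabilities, an evidence
mixture matching the composition of the 47-variant golden table, and
biallelic genotypes drawn under Hardy-Weinberg equilibrium at a specified
minor allele frequency.

Defaults reproduce the study conditions: 155 patients with familial fraction
99/155, carrier probabilities equal to the published per-gene carrier rates,
evidence category weights equal to the golden-table composition, and
``snp_maf`` equal to the study's MTHFR c.665C>T MAF (0.265).

Randomness flows from one integer seed through ``numpy`` ``SeedSequence``
sub-streams, one per component (patient status, carrier draws, evidence,
genotypes), so enlarging the cohort does not perturb the evidence draws.

Evidence dimensions are sampled independently of gene and of each other,
which is unrealistic (real panels show gene-specific mutation spectra) but
sufficient for rule-engine calibration: the analytic tier distribution
implied by the mixture (`implied_tier_distribution`) is exact under these
independence assumptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    Consequence,
    GenotypeCounts,
    LiteratureTier,
    ModelError,
    PatientRecord,
    Segregation,
    SpliceVerdict,
    Tier,
    TruncationFrame,
    VariantAnnotation,
)

CATEGORIES = (
    "truncating_out_of_frame",
    "truncating_new_in_frame",
    "missense",
    "synonymous",
    "intronic",
    "inframe_indel",
)

# per-gene (familial, sporadic) carrier probabilities: published carrier
# patients over published tested denominators
DEFAULT_GENE_CARRIER_PROBS: dict[str, tuple[float, float]] = {
    "ACTA2": (0.0, 0.0),
    "COL3A1": (3 / 82, 0.0),
    "EFEMP2": (5 / 65, 0.0),
    "FBN1": (5 / 85, 3 / 42),
    "MYH11": (9 / 90, 2 / 43),
    "MYLK": (12 / 90, 6 / 46),
    "SMAD3": (0.0, 0.0),
    "TGFB2": (2 / 40, 0.0),
    "TGFBR1": (4 / 93, 1 / 48),
    "TGFBR2": (2 / 94, 1 / 46),
}


def _golden_table_defaults() -> dict:
    """Mixture parameters matching the 47-variant golden table composition."""
    return dict(
        category_weights={
            "truncating_out_of_frame": 2 / 47,
            "truncating_new_in_frame": 0.0,
            "missense": 25 / 47,
            "synonymous": 13 / 47,
            "intronic": 7 / 47,
            "inframe_indel": 0.0,
        },
        # damaging-count tallies among the 25 golden missense variants
        damaging_probs=(5 / 25, 3 / 25, 5 / 25, 8 / 25, 4 / 25, 0.0),
        splice_effect_probs={"missense": 2 / 25, "synonymous": 0.0, "intronic": 2 / 7},
        literature_probs={
            "none": 41 / 47,
            "reported_insufficient": 5 / 47,
            "reported_supported": 1 / 47,
        },
    )


@dataclass(frozen=True)
class EvidenceMixture:
    """Distribution over the evidence bundle attached to a simulated variant."""

    category_weights: dict[str, float] = field(
        default_factory=lambda: _golden_table_defaults()["category_weights"]
    )
    panel_size: int = 5
    damaging_probs: tuple[float, ...] = field(
        default_factory=lambda: _golden_table_defaults()["damaging_probs"]
    )
    splice_effect_probs: dict[str, float] = field(
        default_factory=lambda: _golden_table_defaults()["splice_effect_probs"]
    )
    literature_probs: dict[str, float] = field(
        default_factory=lambda: _golden_table_defaults()["literature_probs"]
    )
    # MAF-generating mixture: point mass at absent, log-uniform rare range,
    # and an optional common range above the classification threshold.
    maf_absent_prob: float = 31 / 47
    maf_common_prob: float = 0.0
    maf_rare_range: tuple[float, float] = (5e-4, 8e-3)
    maf_common_range: tuple[float, float] = (0.01, 0.05)
    # alternate (population-specific) frequency source; its rare range is
    # allowed to cross the threshold, which is what drives reclassification
    alt_maf_absent_prob: float = 31 / 47
    alt_maf_range: tuple[float, float] = (5e-4, 1.5e-2)

    def validate(self) -> None:
        problems = []
        if set(self.category_weights) != set(CATEGORIES):
            problems.append(f"category_weights keys must be {CATEGORIES}")
        if abs(sum(self.category_weights.values()) - 1.0) > 1e-9:
            problems.append("category_weights must sum to 1")
        if any(w < 0 for w in self.category_weights.values()):
            problems.append("category_weights must be non-negative")
        if self.panel_size < 1:
            problems.append("panel_size must be >= 1")
        if len(self.damaging_probs) != self.panel_size + 1:
            problems.append("damaging_probs must have panel_size + 1 entries")
        if abs(sum(self.damaging_probs) - 1.0) > 1e-9:
            problems.append("damaging_probs must sum to 1")
        if set(self.splice_effect_probs) != {"missense", "synonymous", "intronic"}:
            problems.append(
                "splice_effect_probs needs missense/synonymous/intronic keys"
            )
        if abs(sum(self.literature_probs.values()) - 1.0) > 1e-9:
            problems.append("literature_probs must sum to 1")
        for name in ("maf_absent_prob", "maf_common_prob", "alt_maf_absent_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                problems.append(f"{name} outside [0, 1]")
        if self.maf_absent_prob + self.maf_common_prob > 1.0:
            problems.append("maf_absent_prob + maf_common_prob exceeds 1")
        for name in ("maf_rare_range", "maf_common_range", "alt_maf_range"):
            lo, hi = getattr(self, name)
            if not 0.0 < lo <= hi <= 1.0:
                problems.append(f"{name} must satisfy 0 < lo <= hi <= 1")
        if problems:
            raise ModelError("invalid EvidenceMixture: " + "; ".join(problems))


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_patients: int = 155
    familial_fraction: float = 99 / 155
    gene_carrier_probs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GENE_CARRIER_PROBS)
    )
    evidence: EvidenceMixture = field(default_factory=EvidenceMixture)
    snp_maf: float = 0.265

    def validate(self) -> None:
        problems = []
        if not isinstance(self.seed, (int, np.integer)):
            problems.append("seed must be an integer")
        if self.n_patients < 0:
            problems.append("n_patients must be non-negative")
        if not 0.0 <= self.familial_fraction <= 1.0:
            problems.append("familial_fraction outside [0, 1]")
        for gene, probs in self.gene_carrier_probs.items():
            if len(probs) != 2 or not all(0.0 <= p <= 1.0 for p in probs):
                problems.append(f"gene_carrier_probs[{gene}] must be two values in [0, 1]")
        if not 0.0 <= self.snp_maf <= 1.0:
            problems.append("snp_maf outside [0, 1]")
        if problems:
            raise ModelError("invalid SimulationConfig: " + "; ".join(problems))
        self.evidence.validate()


def _draw_maf(rng, absent_prob, common_prob, rare_range, common_range):
    u = rng.random()
    if u < absent_prob:
        return None
    if u < absent_prob + common_prob:
        lo, hi = common_range
    else:
        lo, hi = rare_range
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def _draw_variant(rng, gene: str, index: int, mix: EvidenceMixture) -> VariantAnnotation:
    cats = list(mix.category_weights)
    weights = [mix.category_weights[c] for c in cats]
    category = cats[rng.choice(len(cats), p=weights)]
    pos = 3 * index + 1  # distinct, codon-aligned cDNA positions

    splice = SpliceVerdict.NO_EFFECT
    damaging, panel = 0, 0
    truncation = TruncationFrame.NOT_TRUNCATING
    if category == "truncating_out_of_frame":
        if rng.random() < 0.5:
            consequence = Consequence.NONSENSE
            cdna, protein = f"c.{pos}C>T", f"p.Arg{index + 1}X"
        else:
            consequence = Consequence.FRAMESHIFT
            cdna, protein = f"c.{pos}delA", f"p.Lys{index + 1}Serfs*9"
        truncation = TruncationFrame.OUT_OF_FRAME
    elif category == "truncating_new_in_frame":
        consequence = Consequence.FRAMESHIFT
        cdna, protein = f"c.{pos}delA", f"p.Lys{index + 1}Serfs*40"
        truncation = TruncationFrame.NEW_IN_FRAME
    elif category == "missense":
        consequence = Consequence.MISSENSE
        cdna, protein = f"c.{pos}G>A", f"p.Ala{index + 1}Thr"
        panel = mix.panel_size
        damaging = int(rng.choice(panel + 1, p=list(mix.damaging_probs)))
        if rng.random() < mix.splice_effect_probs["missense"]:
            splice = SpliceVerdict.EFFECT
    elif category == "synonymous":
        consequence = Consequence.SYNONYMOUS
        cdna, protein = f"c.{pos}C>T", "no-change"
        if rng.random() < mix.splice_effect_probs["synonymous"]:
            splice = SpliceVerdict.EFFECT
    elif category == "intronic":
        consequence = Consequence.INTRONIC
        cdna, protein = f"c.{pos}+{5 + int(rng.integers(0, 20))}G>A", ""
        if rng.random() < mix.splice_effect_probs["intronic"]:
            splice = SpliceVerdict.EFFECT
    else:  # inframe_indel
        consequence = Consequence.INFRAME_INDEL
        cdna, protein = f"c.{pos}_{pos + 2}del", f"p.Lys{index + 1}del"

    lit_levels = ("none", "reported_insufficient", "reported_supported")
    lit = LiteratureTier(
        lit_levels[rng.choice(3, p=[mix.literature_probs[k] for k in lit_levels])]
    )
    maf1 = _draw_maf(rng, mix.maf_absent_prob, mix.maf_common_prob,
                     mix.maf_rare_range, mix.maf_common_range)
    maf2 = _draw_maf(rng, mix.alt_maf_absent_prob, 0.0, mix.alt_maf_range,
                     mix.alt_maf_range)
    return VariantAnnotation(
        gene=gene,
        transcript="NM_SYNTH.1",
        cdna_hgvs=cdna,
        protein_hgvs=protein,
        consequence=consequence,
        splice_verdict=splice,
        damaging_count=damaging,
        panel_size=panel,
        maf_primary=maf1,
        maf_alt=maf2,
        literature_tier=lit,
        truncation_frame=truncation,
        segregation=Segregation.NOT_DETERMINED,
    )


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[VariantAnnotation], list[PatientRecord]]:
    """Draw a synthetic annotated-variant table and patient table.

    Patient statuses are Bernoulli draws at ``familial_fraction``; for each
    patient and gene, carrier status is an independent Bernoulli draw at the
    arm-specific probability, and every carrier event yields one fresh
    variant with evidence drawn from the mixture.  Outputs satisfy all domain
    invariants and round-trip through the TSV readers.
    """
    cfg.validate()
    status_ss, carrier_ss, evidence_ss = np.random.SeedSequence(
        cfg.seed
    ).spawn(3)
    status_rng = np.random.default_rng(status_ss)
    carrier_rng = np.random.default_rng(carrier_ss)
    evidence_rng = np.random.default_rng(evidence_ss)

    genes = sorted(cfg.gene_carrier_probs)
    genes_tested = frozenset(genes)
    statuses = status_rng.random(cfg.n_patients) < cfg.familial_fraction

    variants: list[VariantAnnotation] = []
    patients: list[PatientRecord] = []
    v_index = 0
    for i in range(cfg.n_patients):
        status = "familial" if statuses[i] else "sporadic"
        carried: list[str] = []
        for gene in genes:
            p_fam, p_spor = cfg.gene_carrier_probs[gene]
            p = p_fam if status == "familial" else p_spor
            if p > 0 and carrier_rng.random() < p:
                v = _draw_variant(evidence_rng, gene, v_index, cfg.evidence)
                v.validate()
                variants.append(v)
                carried.append(v.key)
                v_index += 1
        patients.append(
            PatientRecord(
                patient_id=f"SIM-{i + 1:04d}",
                status=status,
                genes_tested=genes_tested,
                variant_keys=tuple(carried),
            )
        )
    return variants, patients


def simulate_variants(
    n: int, mixture: EvidenceMixture, seed: int
) -> list[VariantAnnotation]:
    """Draw ``n`` variants straight from the evidence mixture (no cohort)."""
    mixture.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return [_draw_variant(rng, "SYNTH", i, mixture) for i in range(n)]


def simulate_genotypes(n: int, maf: float, seed: int) -> GenotypeCounts:
    """Genotype counts for ``n`` subjects under Hardy-Weinberg at ``maf``."""
    if n <= 0:
        raise ModelError("simulate_genotypes requires n > 0")
    if not 0.0 <= maf <= 1.0:
        raise ModelError(f"maf {maf} outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    q = maf
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
    n_cc, n_ct, n_tt = rng.multinomial(n, probs)
    return GenotypeCounts(
        study="simulated", group=f"HWE maf={maf}",
        n_cc=int(n_cc), n_ct=int(n_ct), n_tt=int(n_tt),
    )


def implied_tier_distribution(
    mix: EvidenceMixture, threshold: float = 0.01, source: str = "primary"
) -> dict[Tier, float]:
    """Closed-form tier probabilities implied by the evidence mixture.

    Pushes the mixture's independent evidence draws through the rule
    precedence analytically; simulation plus rule-engine classification must
    reproduce these proportions up to multinomial noise.
    """
    mix.validate()
    if source == "primary":
        p_common = (1 - mix.maf_absent_prob - mix.maf_common_prob) * _mass_above(
            mix.maf_rare_range, threshold
        ) + mix.maf_common_prob * _mass_above(mix.maf_common_range, threshold)
    elif source == "alt":
        p_common = (1 - mix.alt_maf_absent_prob) * _mass_above(
            mix.alt_maf_range, threshold
        )
    else:
        raise ValueError(f"unknown frequency source {source!r}")

    p_sup = mix.literature_probs["reported_supported"]
    p_ins = mix.literature_probs["reported_insufficient"]
    p_ins_given_not_sup = p_ins / (1 - p_sup) if p_sup < 1 else 0.0
    p_dmg_ge2 = sum(mix.damaging_probs[2:])

    out = {tier: 0.0 for tier in Tier}
    out[Tier.BENIGN] = p_common
    m = 1.0 - p_common
    for category, w in mix.category_weights.items():
        if w == 0:
            continue
        if category == "truncating_out_of_frame":
            out[Tier.PATHOGENIC] += w * m
            continue
        if category == "truncating_new_in_frame":
            out[Tier.LIKELY_PATHOGENIC] += w * m
            continue
        out[Tier.LIKELY_PATHOGENIC] += w * m * p_sup
        rest = w * m * (1 - p_sup)
        p_splice = mix.splice_effect_probs.get(category, 0.0)
        if category == "inframe_indel":
            out[Tier.VUS] += rest
            continue
        vus = p_splice
        if category == "missense":
            vus += (1 - p_splice) * (
                p_dmg_ge2 + (1 - p_dmg_ge2) * p_ins_given_not_sup
            )
        else:  # synonymous / intronic without splice effect
            vus += (1 - p_splice) * p_ins_given_not_sup
        out[Tier.VUS] += rest * vus
        out[Tier.LIKELY_BENIGN] += rest * (1 - vus)
    return out


def _mass_above(log_uniform_range: tuple[float, float], threshold: float) -> float:
    """P(X >= threshold) for X log-uniform on the given range."""
    lo, hi = log_uniform_range
    if threshold <= lo:
        return 1.0
    if threshold > hi:
        return 0.0
    return (math.log(hi) - math.log(threshold)) / (math.log(hi) - math.log(lo))


__all__ = [
    "CATEGORIES",
    "DEFAULT_GENE_CARRIER_PROBS",
    "EvidenceMixture",
    "SimulationConfig",
    "simulate_cohort",
    "simulate_variants",
    "simulate_genotypes",
    "implied_tier_distribution",
]
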