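"""Per-gene familial-vs-sporadic burden and the two-tailed Fisher exact test.

The exact test is computed from first principles on exact integers.  For a
2x2 table with fixed margins, the number of carrier-column assignments giving
``x`` familial carriers is ``C(r1, x) * C(r2, k - x)`` where ``r1``/``r2`` are
the familial/sporadic row totals and ``k`` the carrier column total.  The
two-tailed p-value is the total weight of all tables whose weight does not
exceed the observed table's (with a small relative tie tolerance), divided by
``C(N, k)``.  All weights are exact Python integers, so the test is exact for
any cell counts a cohort study can produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

from .model import ContingencyTable2x2, ModelError, PatientRecord, Tier

logger = logging.getLogger(__name__)

# Relative tolerance for counting a table's probability as "tied" with the
# observed one; matches the convention of standard implementations, where the
# criterion is point probability <= observed * (1 + 1e-7).
TIE_RTOL_NUM = 10**7 + 1
TIE_RTOL_DEN = 10**7

COUNT_MODES = ("patients", "observations")


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-tailed Fisher exact p-value for a 2x2 table.

    Sums the hypergeometric point probabilities of every table with the
    observed margins whose probability is at most that of the observed table
    (relative tie tolerance 1 + 1e-7).  A degenerate margin carries no
    information: the result is then p = 1.
    """
    t.validate()
    r1, r2 = t.a + t.b, t.c + t.d
    k = t.a + t.c  # carrier column total
    n = t.n
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        logger.debug("degenerate margin in %s; p = 1", t)
        return 1.0

    lo = max(0, k - r2)
    hi = min(r1, k)

    # w(x) = C(r1, x) * C(r2, k - x), built by the exact integer recurrence
    # w(x+1)/w(x) = (r1 - x)(k - x) / ((x + 1)(r2 - k + x + 1)).
    weights: list[int] = []
    w = comb(r1, lo) * comb(r2, k - lo)
    for x in range(lo, hi + 1):
        weights.append(w)
        if x < hi:
            w = w * (r1 - x) * (k - x) // ((x + 1) * (r2 - k + x + 1))

    w_obs = weights[t.a - lo]
    total = sum(weights)
    tail = sum(wx for wx in weights if wx * TIE_RTOL_DEN <= w_obs * TIE_RTOL_NUM)
    return min(1.0, tail / total)


@dataclass(frozen=True)
class BurdenRow:
    """One gene's familial-vs-sporadic carrier summary with exact-test p-values."""

    gene: str
    n_familial: int
    n_sporadic: int
    carriers_familial: int
    carriers_sporadic: int
    lp_p_familial: int
    lp_p_sporadic: int
    p_all: float
    p_lp_p: float

    @property
    def n_total(self) -> int:
        return self.n_familial + self.n_sporadic


@dataclass(frozen=True)
class CarrierSummary:
    """Cohort-level carrier and complex-genotype tallies."""

    familial_carriers: int
    sporadic_carriers: int
    multi_variant_total: int
    multi_variant_familial: int
    multi_variant_sporadic: int
    n_variant_observations: int


def _reported_keys(
    patient: PatientRecord, classifications: dict[str, Tier]
) -> list[str]:
    """The patient's variants at tier likely-benign or above (benign excluded)."""
    keys = []
    for key in patient.variant_keys:
        tier = classifications.get(key)
        if tier is None:
            raise ModelError(
                f"patient {patient.patient_id}: variant {key} has no classification"
            )
        if tier is not Tier.BENIGN:
            keys.append(key)
    return keys


def tabulate_gene_burden(
    patients: list[PatientRecord],
    classifications: dict[str, Tier],
    tested: dict[str, tuple[int, int]],
    mode: str = "patients",
) -> list[BurdenRow]:
    """Per-gene 2x2 burden rows with two-tailed exact-test p-values.

    ``tested`` maps each gene to its (familial, sporadic) tested denominators,
    which are an explicit input because panel coverage varies by gene.  In
    ``patients`` mode a cell counts distinct carrier patients; in
    ``observations`` mode it counts variant observations, so a patient with
    two variants in one gene contributes twice.  Benign variants are excluded.
    P-values are unadjusted for multiple testing.
    """
    if mode not in COUNT_MODES:
        raise ValueError(f"unknown counting mode {mode!r}")
    arm = {"familial": 0, "sporadic": 1}
    # cells[gene][arm] for all reported variants and for tier >= LP
    cells_all: dict[str, list[int]] = {g: [0, 0] for g in tested}
    cells_lpp: dict[str, list[int]] = {g: [0, 0] for g in tested}
    for patient in patients:
        patient.validate()
        keys = _reported_keys(patient, classifications)
        genes_all = [k.split(":", 1)[0] for k in keys]
        genes_lpp = [
            k.split(":", 1)[0]
            for k in keys
            if classifications[k].rank >= Tier.LIKELY_PATHOGENIC.rank
        ]
        if mode == "patients":
            genes_all = sorted(set(genes_all))
            genes_lpp = sorted(set(genes_lpp))
        for gene in genes_all:
            if gene not in tested:
                raise ModelError(
                    f"patient {patient.patient_id}: gene {gene} missing from the "
                    "tested-denominator table"
                )
            cells_all[gene][arm[patient.status]] += 1
        for gene in genes_lpp:
            cells_lpp[gene][arm[patient.status]] += 1

    logger.info("exact-test p-values are unadjusted for multiple testing")
    rows = []
    for gene in tested:
        n_fam, n_spor = tested[gene]
        ca_f, ca_s = cells_all[gene]
        lp_f, lp_s = cells_lpp[gene]
        for label, used, limit in (
            ("familial", ca_f, n_fam),
            ("sporadic", ca_s, n_spor),
        ):
            if used > limit:
                raise ModelError(
                    f"{gene}: {label} carriers ({used}) exceed tested "
                    f"denominator ({limit})"
                )
        rows.append(
            BurdenRow(
                gene=gene,
                n_familial=n_fam,
                n_sporadic=n_spor,
                carriers_familial=ca_f,
                carriers_sporadic=ca_s,
                lp_p_familial=lp_f,
                lp_p_sporadic=lp_s,
                p_all=fisher_exact_two_sided(
                    ContingencyTable2x2(ca_f, n_fam - ca_f, ca_s, n_spor - ca_s)
                ),
                p_lp_p=fisher_exact_two_sided(
                    ContingencyTable2x2(lp_f, n_fam - lp_f, lp_s, n_spor - lp_s)
                ),
            )
        )
    return rows


def carrier_summary(
    patients: list[PatientRecord], classifications: dict[str, Tier]
) -> CarrierSummary:
    """Carrier patients per arm and complex genotypes (>= 2 reported variants)."""
    fam = spor = multi_f = multi_s = observations = 0
    for patient in patients:
        patient.validate()
        keys = _reported_keys(patient, classifications)
        observations += len(keys)
        if not keys:
            continue
        if patient.status == "familial":
            fam += 1
            multi_f += len(keys) >= 2
        else:
            spor += 1
            multi_s += len(keys) >= 2
    return CarrierSummary(
        familial_carriers=fam,
        sporadic_carriers=spor,
        multi_variant_total=multi_f + multi_s,
        multi_variant_familial=multi_f,
        multi_variant_sporadic=multi_s,
        n_variant_observations=observations,
    )


__all__ = [
    "BurdenRow",
    "CarrierSummary",
    "fisher_exact_two_sided",
    "tabulate_gene_burden",
    "carrier_summary",
    "COUNT_MODES",
]
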