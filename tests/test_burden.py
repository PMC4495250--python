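"""Gene burden tabulation, carrier summaries and counting-mode semantics."""

import pytest

from aneuvar.burden import carrier_summary, tabulate_gene_burden
from aneuvar.classify import classify_batch
from aneuvar.model import ModelError, PatientRecord, Tier
from aneuvar.simulate import SimulationConfig, simulate_cohort


def test_patient_mode_reproduces_published_carrier_cells(bundle,
                                                         golden_classifications):
    """Distinct-patient counting reproduces every published per-gene cell."""
    rows = {
        r.gene: r
        for r in tabulate_gene_burden(
            bundle.patients, golden_classifications, bundle.tested, mode="patients"
        )
    }
    for gold in bundle.burden_gold:
        row = rows[gold.gene]
        assert (row.carriers_familial, row.carriers_sporadic) == (
            gold.all_familial, gold.all_sporadic,
        ), gold.gene
        assert (row.lp_p_familial, row.lp_p_sporadic) == (
            gold.lp_p_familial, gold.lp_p_sporadic,
        ), gold.gene


def test_observation_mode_counts_variant_entries(bundle, golden_classifications):
    """Observation counting matches the per-variant observation sums; the two
    modes differ exactly for the genes where one patient carries two variants."""
    rows = {
        r.gene: r
        for r in tabulate_gene_burden(
            bundle.patients, golden_classifications, bundle.tested,
            mode="observations",
        )
    }
    by_gene_fam: dict[str, int] = {g: 0 for g in bundle.tested}
    by_gene_spor: dict[str, int] = {g: 0 for g in bundle.tested}
    for key, (fam, spor) in bundle.observations.items():
        gene = key.split(":", 1)[0]
        by_gene_fam[gene] += fam
        by_gene_spor[gene] += spor
    for gene, row in rows.items():
        assert (row.carriers_familial, row.carriers_sporadic) == (
            by_gene_fam[gene], by_gene_spor[gene],
        ), gene
    assert rows["EFEMP2"].carriers_familial == 6  # 5 patients, one with 2 variants
    assert rows["MYLK"].carriers_familial == 13   # 12 patients, one with 2 variants


def test_published_p_values_informational(bundle, golden_classifications):
    """The published two-tailed p-values that recompute from their own cells."""
    rows = {
        r.gene: r
        for r in tabulate_gene_burden(
            bundle.patients, golden_classifications, bundle.tested, mode="patients"
        )
    }
    assert round(rows["TGFBR1"].p_all, 2) == 0.66
    assert round(rows["TGFB2"].p_all, 2) == 0.52
    assert round(rows["TGFBR2"].p_lp_p, 2) == 0.33
    assert round(rows["MYH11"].p_all, 2) == 0.50
    # genes with no carriers at all carry no information
    assert rows["ACTA2"].p_all == 1.0 and rows["SMAD3"].p_all == 1.0
    # the published EFEMP2 p-value recomputes from observation counting only
    obs_rows = {
        r.gene: r
        for r in tabulate_gene_burden(
            bundle.patients, golden_classifications, bundle.tested,
            mode="observations",
        )
    }
    assert round(obs_rows["EFEMP2"].p_all, 2) == 0.19


def test_carrier_summary_matches_published_totals(bundle, golden_classifications):
    summary = carrier_summary(bundle.patients, golden_classifications)
    assert summary.familial_carriers == 31
    assert summary.multi_variant_total == 13
    assert summary.multi_variant_familial == 11
    assert summary.multi_variant_sporadic == 2
    assert summary.n_variant_observations == 57


def test_empty_cohort_yields_zeros():
    summary = carrier_summary([], {})
    assert summary.familial_carriers == 0
    assert summary.sporadic_carriers == 0
    assert summary.multi_variant_total == 0


def test_unclassified_variant_is_an_error(bundle, golden_classifications):
    incomplete = dict(golden_classifications)
    del incomplete["MYLK:c.1327C>T"]
    with pytest.raises(ModelError, match="MYLK:c.1327C>T"):
        carrier_summary(bundle.patients, incomplete)


def test_benign_variants_are_not_reported():
    genes = frozenset({"G"})
    patients = [
        PatientRecord("p1", "familial", genes, ("G:c.1A>G",)),
        PatientRecord("p2", "sporadic", genes, ("G:c.2A>G",)),
    ]
    classifications = {"G:c.1A>G": Tier.BENIGN, "G:c.2A>G": Tier.VUS}
    summary = carrier_summary(patients, classifications)
    assert (summary.familial_carriers, summary.sporadic_carriers) == (0, 1)
    rows = tabulate_gene_burden(patients, classifications, {"G": (1, 1)})
    assert rows[0].carriers_familial == 0 and rows[0].carriers_sporadic == 1


def test_patient_mode_never_exceeds_observation_mode():
    genes = frozenset({"G", "H"})
    patients = [
        PatientRecord("p1", "familial", genes, ("G:c.1A>G", "G:c.2A>G", "H:c.3A>G")),
        PatientRecord("p2", "familial", genes, ("G:c.4A>G",)),
        PatientRecord("p3", "sporadic", genes, ("H:c.5A>G", "H:c.5A>G")),
    ]
    classifications = {
        k: Tier.VUS
        for p in patients
        for k in p.variant_keys
    }
    tested = {"G": (10, 10), "H": (10, 10)}
    by_patients = tabulate_gene_burden(patients, classifications, tested,
                                       mode="patients")
    by_obs = tabulate_gene_burden(patients, classifications, tested,
                                  mode="observations")
    for rp, ro in zip(by_patients, by_obs):
        assert rp.carriers_familial <= ro.carriers_familial
        assert rp.carriers_sporadic <= ro.carriers_sporadic
    g_pat = {r.gene: r for r in by_patients}
    assert g_pat["G"].carriers_familial == 2      # p1 counted once for G
    g_obs = {r.gene: r for r in by_obs}
    assert g_obs["G"].carriers_familial == 3


def test_burden_cells_match_naive_recount_on_simulated_cohort():
    cfg = SimulationConfig(seed=99, n_patients=400)
    variants, patients = simulate_cohort(cfg)
    results, _ = classify_batch(variants)
    classifications = {v.key: r.tier for v, r in zip(variants, results)}
    tested = {g: (400, 400) for g in cfg.gene_carrier_probs}
    rows = tabulate_gene_burden(patients, classifications, tested, mode="patients")
    for row in rows:
        fam = sum(
            1
            for p in patients
            if p.status == "familial" and any(
                k.startswith(row.gene + ":") and classifications[k] is not Tier.BENIGN
                for k in p.variant_keys
            )
        )
        spor = sum(
            1
            for p in patients
            if p.status == "sporadic" and any(
                k.startswith(row.gene + ":") and classifications[k] is not Tier.BENIGN
                for k in p.variant_keys
            )
        )
        assert (row.carriers_familial, row.carriers_sporadic) == (fam, spor), row.gene


def test_carriers_exceeding_denominator_is_an_error():
    genes = frozenset({"G"})
    patients = [
        PatientRecord(f"p{i}", "familial", genes, (f"G:c.{i}A>G",)) for i in range(3)
    ]
    classifications = {f"G:c.{i}A>G": Tier.VUS for i in range(3)}
    with pytest.raises(ModelError, match="exceed tested denominator"):
        tabulate_gene_burden(patients, classifications, {"G": (2, 5)})
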