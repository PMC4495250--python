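"""Loaders for the bundled golden fixtures.

The package ships a transcription of the published reference tables of a
ten-gene aneurysm-panel screen (see ``data/NOTES.md`` for transcription
decisions and known defects in the printed source):

* ``table2`` — 47 annotated variants with the published tier as gold label;
* ``table3`` — MTHFR c.665C>T genotype counts across studies;
* ``table4`` — carrier patient records (multi-variant patients plus
  reconstructed single-variant carriers);
* ``table5`` — per-gene tested denominators and the published burden cells
  and p-values.

Loading is read-only and idempotent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .io import read_patients_tsv, read_variants_tsv
from .model import GenotypeCounts, PatientRecord, Tier, VariantAnnotation

FIXTURE_NAMES = ("table2", "table3", "table4", "table5")

_CLASS_LABELS = {
    "B": Tier.BENIGN,
    "LB": Tier.LIKELY_BENIGN,
    "VUS": Tier.VUS,
    "LP": Tier.LIKELY_PATHOGENIC,
    "P": Tier.PATHOGENIC,
}


def _data_path(name: str):
    return resources.files("aneuvar.data").joinpath(name)


@dataclass(frozen=True)
class GenotypeRow:
    counts: GenotypeCounts
    maf_printed: float
    pool_arm: str  # "aaa" | "control" | "subset"
    note: str


@dataclass(frozen=True)
class BurdenGoldRow:
    gene: str
    all_familial: int
    lp_p_familial: int
    all_sporadic: int
    lp_p_sporadic: int
    p_all_printed: float
    p_lp_p_printed: float


@dataclass(frozen=True)
class FixtureBundle:
    variants: list[VariantAnnotation]
    gold_class: dict[str, Tier]  # variant key -> published tier
    observations: dict[str, tuple[int, int]]  # key -> (familial, sporadic)
    patients: list[PatientRecord]
    genotype_rows: list[GenotypeRow]
    tested: dict[str, tuple[int, int]]
    burden_gold: list[BurdenGoldRow]


def load_variants() -> tuple[
    list[VariantAnnotation], dict[str, Tier], dict[str, tuple[int, int]]
]:
    """The 47-variant golden table: annotations, gold tiers, observation counts."""
    path = _data_path("table2_variants.tsv")
    with resources.as_file(path) as p:
        variants = read_variants_tsv(p)
        with open(p, newline="", encoding="utf-8") as handle:
            rows = list(csv.DictReader(handle, delimiter="\t"))
    gold, obs = {}, {}
    for v, row in zip(variants, rows):
        gold[v.key] = _CLASS_LABELS[row["gold_class"]]
        obs[v.key] = (int(row["obs_familial"]), int(row["obs_sporadic"]))
    return variants, gold, obs


def load_patients() -> list[PatientRecord]:
    with resources.as_file(_data_path("table4_patients.tsv")) as p:
        return read_patients_tsv(p)


def load_genotype_rows() -> list[GenotypeRow]:
    rows = []
    with _data_path("table3_genotypes.tsv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                GenotypeRow(
                    counts=GenotypeCounts(
                        study=row["study"],
                        group=row["group"],
                        n_cc=int(row["n_cc"]),
                        n_ct=int(row["n_ct"]),
                        n_tt=int(row["n_tt"]),
                    ),
                    maf_printed=float(row["maf_printed"]),
                    pool_arm=row["pool_arm"],
                    note=row["note"],
                )
            )
    return rows


def load_tested() -> dict[str, tuple[int, int]]:
    tested = {}
    with _data_path("table5_tested.tsv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            tested[row["gene"]] = (int(row["n_familial"]), int(row["n_sporadic"]))
    return tested


def load_burden_gold() -> list[BurdenGoldRow]:
    rows = []
    with _data_path("table5_burden_gold.tsv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                BurdenGoldRow(
                    gene=row["gene"],
                    all_familial=int(row["all_familial"]),
                    lp_p_familial=int(row["lp_p_familial"]),
                    all_sporadic=int(row["all_sporadic"]),
                    lp_p_sporadic=int(row["lp_p_sporadic"]),
                    p_all_printed=float(row["p_all_printed"]),
                    p_lp_p_printed=float(row["p_lp_p_printed"]),
                )
            )
    return rows


def load_bundle() -> FixtureBundle:
    """Load every bundled table into one coherent fixture bundle."""
    variants, gold, obs = load_variants()
    return FixtureBundle(
        variants=variants,
        gold_class=gold,
        observations=obs,
        patients=load_patients(),
        genotype_rows=load_genotype_rows(),
        tested=load_tested(),
        burden_gold=load_burden_gold(),
    )


def load_fixture(name: str):
    """Load one bundled table by name (``table2``..``table5``)."""
    if name == "table2":
        return load_variants()
    if name == "table3":
        return load_genotype_rows()
    if name == "table4":
        return load_patients()
    if name == "table5":
        return load_tested(), load_burden_gold()
    raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")


# Alternate-population (Dutch cohort) MAF for MTHFR c.665C>T, used for the
# descriptive study-vs-reference comparison.
MTHFR_REFERENCE_MAF = 0.320


__all__ = [
    "FIXTURE_NAMES",
    "FixtureBundle",
    "GenotypeRow",
    "BurdenGoldRow",
    "load_bundle",
    "load_fixture",
    "load_variants",
    "load_patients",
    "load_genotype_rows",
    "load_tested",
    "load_burden_gold",
    "MTHFR_REFERENCE_MAF",
]
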