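"""End-to-end pipeline: classification -> burden -> allele frequencies.

Every run emits a ``manifest.json`` recording the command, resolved
parameters, SHA-256 checksums of the inputs, the package version and a
timestamp; identical inputs and parameters produce identical stage outputs
(the manifest differs only in its timestamp).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .burden import carrier_summary, tabulate_gene_burden
from .classify import classify_batch, reclassify_with_alt_frequency
from .frequency import maf_from_genotypes, pool_studies
from .io import (
    VARIANT_COLUMNS,
    read_genotype_counts_tsv,
    read_patients_tsv,
    read_tested_tsv,
    read_variants_tsv,
    read_variants_vcf,
    validate_inputs,
    write_variants_tsv,
)
from .model import GenotypeCounts, Tier, VariantAnnotation

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    command: str
    parameters: dict
    inputs: dict  # path -> sha256
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def read_variants_any(path) -> list[VariantAnnotation]:
    """Dispatch on extension: ``.vcf`` via the VCF dialect, else TSV."""
    if str(path).endswith(".vcf"):
        return read_variants_vcf(path)
    return read_variants_tsv(path)


def write_classification_report(
    path, variants, results
) -> None:
    """Input columns plus tier, rule_fired and freq_used."""
    tmp = Path(path)
    with tmp.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS + ["tier", "rule_fired", "freq_used"])
        for v, r in zip(variants, results):
            conservation = v.conservation.value
            if v.conservation_species is not None:
                conservation += f":{v.conservation_species}"
            writer.writerow([
                v.gene, v.transcript, v.cdna_hgvs, v.protein_hgvs,
                v.consequence.value, v.splice_verdict.value,
                v.damaging_count, v.panel_size, conservation, v.dbsnp_id or "",
                "" if v.maf_primary is None else format(v.maf_primary, "g"),
                "" if v.mac_primary is None else v.mac_primary,
                "" if v.maf_alt is None else format(v.maf_alt, "g"),
                v.literature_tier.value, v.truncation_frame.value,
                v.segregation.value,
                r.tier.value, r.rule_fired,
                "" if r.freq_used is None else format(r.freq_used, "g"),
            ])


def write_burden_tsv(path, rows) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "gene", "n_familial", "n_sporadic", "carriers_familial",
            "carriers_sporadic", "lp_p_familial", "lp_p_sporadic",
            "p_all", "p_lp_p",
        ])
        for r in rows:
            writer.writerow([
                r.gene, r.n_familial, r.n_sporadic, r.carriers_familial,
                r.carriers_sporadic, r.lp_p_familial, r.lp_p_sporadic,
                format(r.p_all, ".17g"), format(r.p_lp_p, ".17g"),
            ])


def write_frequency_tsv(path, entries) -> None:
    """entries: list of (GenotypeCounts, FrequencySummary)."""
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "study", "group", "n", "n_cc", "n_ct", "n_tt", "maf",
            "pct_cc", "pct_ct", "pct_tt", "pct_carrier",
        ])
        for g, s in entries:
            writer.writerow([
                g.study, g.group, s.n, g.n_cc, g.n_ct, g.n_tt,
                format(s.maf, ".3f"), s.pct_cc, s.pct_ct, s.pct_tt,
                s.pct_carrier,
            ])


def run_full_pipeline(
    variants_path,
    patients_path,
    tested_path,
    genotype_path,
    outdir,
    threshold: float = 0.01,
    mode: str = "patients",
) -> dict:
    """Classify, reclassify, tabulate burden and compute allele frequencies.

    Writes one TSV per stage plus ``summary.json`` and ``manifest.json`` to
    ``outdir`` and returns the summary dictionary.
    """
    report = validate_inputs(
        variants_path=None if str(variants_path).endswith(".vcf") else variants_path,
        patients_path=patients_path,
        genotype_path=genotype_path,
        tested_path=tested_path,
    )
    if not report.ok:
        raise ValueError("input validation failed:\n" + "\n".join(report.errors))
    for warning in report.warnings:
        logger.warning("%s", warning)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    variants = read_variants_any(variants_path)
    patients = read_patients_tsv(patients_path)
    tested = read_tested_tsv(tested_path)
    genotype_rows = read_genotype_counts_tsv(genotype_path)

    # classification (primary frequency source) and alternate-source diff
    results, tier_counts = classify_batch(variants, threshold=threshold)
    changes = reclassify_with_alt_frequency(variants, threshold=threshold)
    write_classification_report(outdir / "classification.tsv", variants, results)

    classifications = {v.key: r.tier for v, r in zip(variants, results)}
    burden_rows = tabulate_gene_burden(patients, classifications, tested, mode=mode)
    write_burden_tsv(outdir / "burden.tsv", burden_rows)
    carriers = carrier_summary(patients, classifications)

    freq_entries = [(g, maf_from_genotypes(g)) for g in genotype_rows]
    pooled, pooled_summary = pool_studies(genotype_rows) if genotype_rows else (None, None)
    if pooled is not None:
        freq_entries.append((pooled, pooled_summary))
    write_frequency_tsv(outdir / "frequencies.tsv", freq_entries)

    summary = {
        "n_variants": len(variants),
        "tier_counts": {tier.value: tier_counts[tier] for tier in Tier},
        "reclassified": [
            {
                "variant": c.variant_key,
                "old_tier": c.old_tier.value,
                "new_tier": c.new_tier.value,
                "alt_maf": c.freq_used,
            }
            for c in changes
        ],
        "carriers": asdict(carriers),
        "burden": {
            r.gene: {"p_all": r.p_all, "p_lp_p": r.p_lp_p} for r in burden_rows
        },
        "frequency": {
            "per_group_maf": {
                f"{g.study}/{g.group}": s.maf for g, s in freq_entries
            },
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    manifest = RunManifest(
        command="run",
        parameters={"threshold": threshold, "mode": mode},
        inputs={
            str(p): sha256_file(p)
            for p in (variants_path, patients_path, tested_path, genotype_path)
        },
    )
    manifest.write(outdir / "manifest.json")
    return summary


def export_simulated_cohort(cfg, outdir) -> dict:
    """Write variants.tsv / patients.tsv / genotype_counts.tsv for a config."""
    from .io import write_genotype_counts_tsv, write_patients_tsv
    from .simulate import simulate_cohort, simulate_genotypes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants, patients = simulate_cohort(cfg)
    genotypes = simulate_genotypes(
        max(cfg.n_patients, 1), cfg.snp_maf, seed=cfg.seed
    )
    write_variants_tsv(outdir / "variants.tsv", variants)
    write_patients_tsv(outdir / "patients.tsv", patients)
    write_genotype_counts_tsv(outdir / "genotype_counts.tsv", [genotypes])
    resolved = {
        "seed": cfg.seed,
        "n_patients": cfg.n_patients,
        "familial_fraction": cfg.familial_fraction,
        "gene_carrier_probs": {
            g: list(p) for g, p in cfg.gene_carrier_probs.items()
        },
        "snp_maf": cfg.snp_maf,
        "evidence": {
            "category_weights": cfg.evidence.category_weights,
            "panel_size": cfg.evidence.panel_size,
            "damaging_probs": list(cfg.evidence.damaging_probs),
            "splice_effect_probs": cfg.evidence.splice_effect_probs,
            "literature_probs": cfg.evidence.literature_probs,
            "maf_absent_prob": cfg.evidence.maf_absent_prob,
            "maf_common_prob": cfg.evidence.maf_common_prob,
            "maf_rare_range": list(cfg.evidence.maf_rare_range),
            "maf_common_range": list(cfg.evidence.maf_common_range),
            "alt_maf_absent_prob": cfg.evidence.alt_maf_absent_prob,
            "alt_maf_range": list(cfg.evidence.alt_maf_range),
        },
    }
    (outdir / "config_resolved.json").write_text(
        json.dumps(resolved, indent=2) + "\n"
    )
    return resolved


__all__ = [
    "RunManifest",
    "run_full_pipeline",
    "export_simulated_cohort",
    "read_variants_any",
    "write_classification_report",
    "write_burden_tsv",
    "write_frequency_tsv",
    "sha256_file",
]
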