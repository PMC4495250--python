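"""Readers and writers for the tab-separated exchange schemas, plus a
read-only VCF ingestion path.

Three TSV schemas are defined (UTF-8, header row, empty string = absent):

* variants:  gene, transcript, cdna_hgvs, protein_hgvs, consequence,
  splice_verdict, damaging_count, panel_size, conservation, dbsnp_id,
  maf_primary, mac_primary, maf_alt, literature_tier, truncation_frame,
  segregation.  ``conservation`` encodes the species count as a suffix,
  e.g. ``highly_conserved:13``.
* patients:  patient_id, status, twin_pair_id, genes_tested
  (semicolon-joined), variant_keys (semicolon-joined ``gene:cdna_hgvs``).
* genotype counts:  study, group, n_cc, n_ct, n_tt.

Extra columns are tolerated on input and ignored; output writes exactly the
schema columns, so a read-write-read cycle reproduces field-identical
records.

The VCF dialect is ingestion-only: one record per variant, genotype columns
ignored, with the annotation bundle carried in INFO keys AC_GENE, AC_CDNA,
AC_PHGVS, AC_CLASS (consequence), AC_SPLICE, AC_DMG, AC_PANEL, AC_MAF1,
AC_MAF2, AC_LIT, AC_TRUNC, AC_SEG.  When AC_CLASS is missing the consequence
is inferred from the HGVS texts.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .model import (
    Consequence,
    Conservation,
    GenotypeCounts,
    HgvsParseError,
    LiteratureTier,
    ModelError,
    PatientRecord,
    Segregation,
    SpliceVerdict,
    TruncationFrame,
    VariantAnnotation,
    infer_consequence,
)

VARIANT_COLUMNS = [
    "gene", "transcript", "cdna_hgvs", "protein_hgvs", "consequence",
    "splice_verdict", "damaging_count", "panel_size", "conservation",
    "dbsnp_id", "maf_primary", "mac_primary", "maf_alt", "literature_tier",
    "truncation_frame", "segregation",
]
PATIENT_COLUMNS = ["patient_id", "status", "twin_pair_id", "genes_tested", "variant_keys"]
GENOTYPE_COLUMNS = ["study", "group", "n_cc", "n_ct", "n_tt"]

_CONSERVATION_RE = re.compile(r"^([a-z_]+?)(?::(\d+))?$")


class SchemaError(ModelError):
    """A file does not conform to its TSV schema."""

    def __init__(self, path, line: int | None, message: str):
        self.path = str(path)
        self.line = line
        where = f"{path}" if line is None else f"{path}:{line}"
        super().__init__(f"{where}: {message}")


def _check_header(path, fieldnames, required: list[str]) -> None:
    missing = [c for c in required if c not in (fieldnames or [])]
    if missing:
        raise SchemaError(path, 1, f"missing columns: {', '.join(missing)}")


def _opt_float(row, col, path, line) -> float | None:
    raw = (row.get(col) or "").strip()
    if not raw:
        return None
    try:
        return float(raw)
    except ValueError:
        raise SchemaError(path, line, f"column {col}: not a number: {raw!r}")


def _opt_int(row, col, path, line, default=None) -> int | None:
    raw = (row.get(col) or "").strip()
    if not raw:
        return default
    try:
        return int(raw)
    except ValueError:
        raise SchemaError(path, line, f"column {col}: not an integer: {raw!r}")


def _enum(enum_cls, raw, col, path, line, default):
    raw = (raw or "").strip()
    if not raw:
        return default
    try:
        return enum_cls(raw)
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise SchemaError(path, line, f"column {col}: {raw!r} not one of {valid}")


def _variant_from_row(row: dict, path, line: int) -> VariantAnnotation:
    cons_raw = (row.get("conservation") or "").strip()
    conservation, conservation_species = Conservation.NOT_ASSESSED, None
    if cons_raw:
        m = _CONSERVATION_RE.match(cons_raw)
        if not m:
            raise SchemaError(path, line, f"column conservation: bad value {cons_raw!r}")
        conservation = _enum(Conservation, m.group(1), "conservation", path, line,
                             Conservation.NOT_ASSESSED)
        conservation_species = int(m.group(2)) if m.group(2) else None

    protein = (row.get("protein_hgvs") or "").strip()
    cdna = (row.get("cdna_hgvs") or "").strip()
    consequence_raw = (row.get("consequence") or "").strip()
    truncation_raw = (row.get("truncation_frame") or "").strip()
    if consequence_raw:
        consequence = _enum(Consequence, consequence_raw, "consequence", path, line, None)
        inferred_truncation = TruncationFrame.NOT_TRUNCATING
    else:
        # no explicit consequence: fall back to HGVS inference
        try:
            consequence, inferred_truncation = infer_consequence(protein, cdna)
        except HgvsParseError as exc:
            raise SchemaError(path, line, str(exc))
    truncation = (
        _enum(TruncationFrame, truncation_raw, "truncation_frame", path, line, None)
        if truncation_raw
        else inferred_truncation
    )

    v = VariantAnnotation(
        gene=(row.get("gene") or "").strip(),
        transcript=(row.get("transcript") or "").strip(),
        cdna_hgvs=cdna,
        protein_hgvs=protein,
        consequence=consequence,
        splice_verdict=_enum(SpliceVerdict, row.get("splice_verdict"),
                             "splice_verdict", path, line, SpliceVerdict.NOT_ASSESSED),
        damaging_count=_opt_int(row, "damaging_count", path, line, 0),
        panel_size=_opt_int(row, "panel_size", path, line, 0),
        conservation=conservation,
        conservation_species=conservation_species,
        dbsnp_id=(row.get("dbsnp_id") or "").strip() or None,
        maf_primary=_opt_float(row, "maf_primary", path, line),
        mac_primary=_opt_int(row, "mac_primary", path, line),
        maf_alt=_opt_float(row, "maf_alt", path, line),
        literature_tier=_enum(LiteratureTier, row.get("literature_tier"),
                              "literature_tier", path, line, LiteratureTier.NONE),
        truncation_frame=truncation,
        segregation=_enum(Segregation, row.get("segregation"), "segregation",
                          path, line, Segregation.NOT_DETERMINED),
    )
    try:
        v.validate()
    except ModelError as exc:
        raise SchemaError(path, line, str(exc))
    return v


def read_variants_tsv(path) -> list[VariantAnnotation]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        _check_header(path, reader.fieldnames, VARIANT_COLUMNS)
        return [_variant_from_row(row, path, i) for i, row in enumerate(reader, start=2)]


def write_variants_tsv(path, variants: Iterable[VariantAnnotation]) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for v in variants:
            conservation = v.conservation.value
            if v.conservation_species is not None:
                conservation += f":{v.conservation_species}"
            writer.writerow([
                v.gene, v.transcript, v.cdna_hgvs, v.protein_hgvs,
                v.consequence.value, v.splice_verdict.value,
                v.damaging_count, v.panel_size, conservation,
                v.dbsnp_id or "",
                _fmt_float(v.maf_primary),
                "" if v.mac_primary is None else v.mac_primary,
                _fmt_float(v.maf_alt),
                v.literature_tier.value, v.truncation_frame.value,
                v.segregation.value,
            ])


def _fmt_float(x: float | None) -> str:
    if x is None:
        return ""
    return repr(float(x))  # shortest exact round-trip representation


def read_patients_tsv(path) -> list[PatientRecord]:
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        _check_header(path, reader.fieldnames, PATIENT_COLUMNS)
        for i, row in enumerate(reader, start=2):
            genes = frozenset(
                g.strip() for g in (row.get("genes_tested") or "").split(";") if g.strip()
            )
            keys = tuple(
                k.strip() for k in (row.get("variant_keys") or "").split(";") if k.strip()
            )
            record = PatientRecord(
                patient_id=(row.get("patient_id") or "").strip(),
                status=(row.get("status") or "").strip(),
                genes_tested=genes,
                variant_keys=keys,
                twin_pair_id=(row.get("twin_pair_id") or "").strip() or None,
            )
            try:
                record.validate()
            except ModelError as exc:
                raise SchemaError(path, i, str(exc))
            records.append(record)
    return records


def write_patients_tsv(path, patients: Iterable[PatientRecord]) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PATIENT_COLUMNS)
        for p in patients:
            writer.writerow([
                p.patient_id, p.status, p.twin_pair_id or "",
                ";".join(sorted(p.genes_tested)), ";".join(p.variant_keys),
            ])


def read_genotype_counts_tsv(path) -> list[GenotypeCounts]:
    path = Path(path)
    out = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        _check_header(path, reader.fieldnames, GENOTYPE_COLUMNS)
        for i, row in enumerate(reader, start=2):
            g = GenotypeCounts(
                study=(row.get("study") or "").strip(),
                group=(row.get("group") or "").strip(),
                n_cc=_opt_int(row, "n_cc", path, i, 0),
                n_ct=_opt_int(row, "n_ct", path, i, 0),
                n_tt=_opt_int(row, "n_tt", path, i, 0),
            )
            try:
                g.validate()
            except ModelError as exc:
                raise SchemaError(path, i, str(exc))
            out.append(g)
    return out


def write_genotype_counts_tsv(path, groups: Iterable[GenotypeCounts]) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(GENOTYPE_COLUMNS)
        for g in groups:
            writer.writerow([g.study, g.group, g.n_cc, g.n_ct, g.n_tt])


def read_tested_tsv(path) -> dict[str, tuple[int, int]]:
    """Per-gene tested denominators: gene, n_familial, n_sporadic."""
    path = Path(path)
    tested: dict[str, tuple[int, int]] = {}
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        _check_header(path, reader.fieldnames, ["gene", "n_familial", "n_sporadic"])
        for i, row in enumerate(reader, start=2):
            gene = (row.get("gene") or "").strip()
            if not gene:
                raise SchemaError(path, i, "empty gene symbol")
            tested[gene] = (
                _opt_int(row, "n_familial", path, i, 0),
                _opt_int(row, "n_sporadic", path, i, 0),
            )
    return tested


# --- VCF ingestion -----------------------------------------------------------

_VCF_ENUMS = {
    "AC_CLASS": ("consequence", Consequence),
    "AC_SPLICE": ("splice_verdict", SpliceVerdict),
    "AC_LIT": ("literature_tier", LiteratureTier),
    "AC_TRUNC": ("truncation_frame", TruncationFrame),
    "AC_SEG": ("segregation", Segregation),
}


def read_variants_vcf(path) -> list[VariantAnnotation]:
    """Ingest annotated variants from the VCF dialect (read-only).

    Requires pysam.  Sample/genotype columns are ignored; one record per
    variant.
    """
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            gene = _vcf_str(info, "AC_GENE")
            cdna = _vcf_str(info, "AC_CDNA") or (rec.id or "")
            protein = _vcf_str(info, "AC_PHGVS")
            if not gene:
                raise SchemaError(path, None, f"record {rec.chrom}:{rec.pos}: AC_GENE missing")
            fields: dict = {}
            for key, (field_name, enum_cls) in _VCF_ENUMS.items():
                raw = _vcf_str(info, key)
                if raw:
                    try:
                        fields[field_name] = enum_cls(raw)
                    except ValueError:
                        raise SchemaError(
                            path, None,
                            f"record {gene}:{cdna}: {key}={raw!r} is not a valid "
                            f"{field_name}",
                        )
            if "consequence" not in fields:
                consequence, truncation = infer_consequence(protein, cdna)
                fields["consequence"] = consequence
                fields.setdefault("truncation_frame", truncation)
            v = VariantAnnotation(
                gene=gene,
                cdna_hgvs=cdna,
                protein_hgvs=protein,
                damaging_count=int(_vcf_get(info, "AC_DMG") or 0),
                panel_size=int(_vcf_get(info, "AC_PANEL") or 0),
                maf_primary=_vcf_float(info, "AC_MAF1"),
                maf_alt=_vcf_float(info, "AC_MAF2"),
                **fields,
            )
            v.validate()
            variants.append(v)
    return variants


def _vcf_get(info, key):
    # pysam raises rather than returning None for keys the header does not
    # declare; treat both cases as absent
    try:
        return info.get(key)
    except (KeyError, ValueError):
        return None


def _vcf_str(info, key) -> str:
    value = _vcf_get(info, key)
    if value is None:
        return ""
    if isinstance(value, tuple):
        value = value[0]
    return str(value)


def _vcf_float(info, key) -> float | None:
    value = _vcf_get(info, key)
    if value is None:
        return None
    if isinstance(value, tuple):
        value = value[0]
    return float(value)


# --- input validation --------------------------------------------------------

@dataclass
class ValidationReport:
    errors: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    variants_path=None, patients_path=None, genotype_path=None, tested_path=None
) -> ValidationReport:
    """Schema- and cross-reference-check a set of input files.

    Reports all problems found rather than stopping at the first; schema
    violations and broken cross-references are errors, unusual-but-legal
    content (e.g. a gene tested in no patient) is a warning.
    """
    errors: list[str] = []
    warnings: list[str] = []
    variants = patients = tested = None
    if variants_path is not None:
        try:
            variants = read_variants_tsv(variants_path)
        except ModelError as exc:
            errors.append(str(exc))
    if patients_path is not None:
        try:
            patients = read_patients_tsv(patients_path)
        except ModelError as exc:
            errors.append(str(exc))
    if genotype_path is not None:
        try:
            read_genotype_counts_tsv(genotype_path)
        except ModelError as exc:
            errors.append(str(exc))
    if tested_path is not None:
        try:
            tested = read_tested_tsv(tested_path)
        except ModelError as exc:
            errors.append(str(exc))

    if variants is not None:
        seen = set()
        for v in variants:
            if v.key in seen:
                warnings.append(f"duplicate variant key {v.key}")
            seen.add(v.key)
        if patients is not None:
            for p in patients:
                for key in p.variant_keys:
                    if key not in seen:
                        errors.append(
                            f"patient {p.patient_id}: variant key {key} not present "
                            "in the variant table"
                        )
    if patients is not None and tested is not None:
        genes_carried = {
            key.split(":", 1)[0] for p in patients for key in p.variant_keys
        }
        for gene in sorted(genes_carried - set(tested)):
            errors.append(f"gene {gene} carried by patients but missing from tested table")
        for gene in sorted(set(tested) - genes_carried):
            warnings.append(f"gene {gene} tested but carried by no patient")
    return ValidationReport(errors=errors, warnings=warnings)


__all__ = [
    "VARIANT_COLUMNS", "PATIENT_COLUMNS", "GENOTYPE_COLUMNS",
    "SchemaError", "ValidationReport",
    "read_variants_tsv", "write_variants_tsv",
    "read_patients_tsv", "write_patients_tsv",
    "read_genotype_counts_tsv", "write_genotype_counts_tsv",
    "read_tested_tsv", "read_variants_vcf", "validate_inputs",
]
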