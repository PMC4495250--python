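"""Domain types for annotated variants, patients and genotype counts.

The unit of analysis is a *variant annotation*: one rare variant found in an
aneurysm-gene panel screen, together with all the evidence the classification
rules consume — consequence class, splice-prediction verdict, the number of
in-silico protein predictors calling the change damaging, reference- and
alternate-population allele frequencies, curated literature evidence and
(annotation-only) segregation and conservation.

Absent evidence is represented as ``None``, never as a zero: a variant with
no population frequency on record is *unknown-frequency*, not frequency 0,
and can never satisfy a frequency threshold.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"


class SpliceVerdict(str, enum.Enum):
    EFFECT = "effect"
    NO_EFFECT = "no_effect"
    NOT_ASSESSED = "not_assessed"


class Conservation(str, enum.Enum):
    HIGHLY_CONSERVED = "highly_conserved"
    MODERATELY_CONSERVED = "moderately_conserved"
    NOT_ASSESSED = "not_assessed"


class LiteratureTier(str, enum.Enum):
    """Curated judgement of prior disease reports for a variant.

    ``REPORTED_SUPPORTED`` means a previous report linked the variant to
    disease *and* the supporting evidence (functional studies, expression
    assays) held up under review; ``REPORTED_INSUFFICIENT`` means the variant
    was described before but a single unreplicated patient report is not
    sufficient evidence of causation.
    """

    NONE = "none"
    REPORTED_INSUFFICIENT = "reported_insufficient"
    REPORTED_SUPPORTED = "reported_supported"


class TruncationFrame(str, enum.Enum):
    """Whether a truncating change precludes any in-frame protein."""

    NOT_TRUNCATING = "not_truncating"
    OUT_OF_FRAME = "out_of_frame"
    NEW_IN_FRAME = "new_in_frame"


class Segregation(str, enum.Enum):
    SEGREGATES = "segregates"
    DOES_NOT_SEGREGATE = "does_not_segregate"
    NOT_DETERMINED = "not_determined"
    TWINS = "twins"
    NOT_APPLICABLE = "not_applicable"


class Tier(str, enum.Enum):
    """Five-tier pathogenicity classification."""

    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    VUS = "vus"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"

    @property
    def rank(self) -> int:
        return _TIER_ORDER.index(self)


_TIER_ORDER = [
    Tier.BENIGN,
    Tier.LIKELY_BENIGN,
    Tier.VUS,
    Tier.LIKELY_PATHOGENIC,
    Tier.PATHOGENIC,
]

TRUNCATING = {Consequence.NONSENSE, Consequence.FRAMESHIFT}


class ModelError(ValueError):
    """An input record violates a domain invariant."""


class HgvsParseError(ModelError):
    """HGVS text could not be mapped onto a consequence class."""

    def __init__(self, field_name: str, text: str, reason: str):
        self.field_name = field_name
        self.text = text
        super().__init__(f"{field_name} {text!r}: {reason}")


@dataclass(frozen=True)
class VariantAnnotation:
    """One variant's full evidence bundle."""

    gene: str
    cdna_hgvs: str
    transcript: str = ""
    protein_hgvs: str = ""
    consequence: Consequence = Consequence.MISSENSE
    splice_verdict: SpliceVerdict = SpliceVerdict.NOT_ASSESSED
    damaging_count: int = 0
    panel_size: int = 0
    conservation: Conservation = Conservation.NOT_ASSESSED
    conservation_species: int | None = None
    dbsnp_id: str | None = None
    maf_primary: float | None = None
    mac_primary: int | None = None
    maf_alt: float | None = None
    literature_tier: LiteratureTier = LiteratureTier.NONE
    truncation_frame: TruncationFrame = TruncationFrame.NOT_TRUNCATING
    segregation: Segregation = Segregation.NOT_DETERMINED

    @property
    def key(self) -> str:
        """Stable identifier, ``gene:cdna_hgvs``."""
        return f"{self.gene}:{self.cdna_hgvs}"

    def validate(self) -> None:
        if not self.gene:
            raise ModelError("gene symbol is mandatory")
        if not self.cdna_hgvs:
            raise ModelError(f"{self.gene}: cdna_hgvs is mandatory")
        if self.damaging_count < 0 or self.panel_size < 0:
            raise ModelError(f"{self.key}: predictor counts must be non-negative")
        if self.damaging_count > self.panel_size:
            raise ModelError(
                f"{self.key}: damaging_count {self.damaging_count} exceeds "
                f"panel_size {self.panel_size}"
            )
        if self.consequence is Consequence.MISSENSE and self.panel_size == 0:
            raise ModelError(
                f"{self.key}: uninterpretable predictor panel "
                "(missense variant with panel_size = 0)"
            )
        if (
            self.consequence in (Consequence.SYNONYMOUS, Consequence.INTRONIC)
            and self.panel_size != 0
        ):
            raise ModelError(
                f"{self.key}: protein predictor panel is not applicable to "
                f"{self.consequence.value} variants"
            )
        truncating = self.consequence in TRUNCATING
        if truncating != (self.truncation_frame is not TruncationFrame.NOT_TRUNCATING):
            raise ModelError(
                f"{self.key}: truncation_frame {self.truncation_frame.value} is "
                f"inconsistent with consequence {self.consequence.value}"
            )
        for name, value in (("maf_primary", self.maf_primary), ("maf_alt", self.maf_alt)):
            if value is not None and not 0.0 <= value <= 1.0:
                raise ModelError(f"{self.key}: {name} {value} outside [0, 1]")
        if self.mac_primary is not None and self.mac_primary < 0:
            raise ModelError(f"{self.key}: mac_primary must be non-negative")

    def maf(self, source: str) -> float | None:
        """Selected-source minor allele frequency (``primary`` or ``alt``)."""
        if source == "primary":
            return self.maf_primary
        if source == "alt":
            return self.maf_alt
        raise ValueError(f"unknown frequency source {source!r}")


@dataclass(frozen=True)
class PatientRecord:
    """One study subject and the panel variants they carry."""

    patient_id: str
    status: str  # "familial" | "sporadic"
    genes_tested: frozenset[str] = frozenset()
    variant_keys: tuple[str, ...] = ()
    twin_pair_id: str | None = None

    def validate(self) -> None:
        if self.status not in ("familial", "sporadic"):
            raise ModelError(
                f"patient {self.patient_id}: status must be familial or sporadic, "
                f"got {self.status!r}"
            )
        for key in self.variant_keys:
            gene = key.split(":", 1)[0]
            if gene not in self.genes_tested:
                raise ModelError(
                    f"patient {self.patient_id}: carries {key} but {gene} is not "
                    "in genes_tested"
                )


@dataclass(frozen=True)
class GenotypeCounts:
    """CC/CT/TT tallies for one study group at a biallelic site.

    CC is the reference homozygote, CT the heterozygote, TT the
    variant-allele homozygote; ``n`` subjects carry ``2n`` alleles.
    """

    study: str
    group: str
    n_cc: int
    n_ct: int
    n_tt: int

    def validate(self) -> None:
        if min(self.n_cc, self.n_ct, self.n_tt) < 0:
            raise ModelError(
                f"{self.study}/{self.group}: genotype counts must be non-negative"
            )

    @property
    def n(self) -> int:
        return self.n_cc + self.n_ct + self.n_tt

    @property
    def n_alleles(self) -> int:
        return 2 * self.n

    @property
    def n_variant_alleles(self) -> int:
        return self.n_ct + 2 * self.n_tt


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Familial/sporadic x carrier/non-carrier counts for one gene."""

    a: int  # familial carriers
    b: int  # familial non-carriers
    c: int  # sporadic carriers
    d: int  # sporadic non-carriers

    def validate(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ModelError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


# --- consequence inference from HGVS text -----------------------------------

_INTRON_OFFSET = re.compile(r"c\.[0-9*]+[+-]\d+")
_SUBSTITUTION = re.compile(r"c\.[0-9+*-]+([ACGT])>([ACGT])$")
_PROTEIN_MISSENSE = re.compile(
    r"p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})\)?$"
)
_PROTEIN_NONSENSE = re.compile(r"p\.\(?[A-Z][a-z]{2}\d+(X|\*|Ter)\)?$")
_PROTEIN_INFRAME = re.compile(
    r"p\.\(?[A-Z][a-z]{2}\d+(_[A-Z][a-z]{2}\d+)?(del|dup|ins[A-Za-z]+)\)?$"
)
_CDNA_INDEL = re.compile(r"c\.[0-9+*_-]+(?:del[ACGT]*|dup[ACGT]*|ins[ACGT]+)+$")
_SYNONYMOUS_MARKERS = ("no-change", "p.=", "p.(=)")


def infer_consequence(
    protein_hgvs: str, cdna_hgvs: str
) -> tuple[Consequence, TruncationFrame]:
    """Map HGVS description texts onto a consequence class.

    The mapping is deliberately shallow — it recognises the notational
    signatures of frameshift (``fs``), nonsense (terminal ``X``/``*``/``Ter``),
    synonymous (``no-change``/``p.=``), intronic (offset positions such as
    ``c.898-14A>G``), in-frame indels and missense substitutions.  It is a
    convenience for free-form input; curated records carry an explicit
    consequence that takes precedence.
    """
    protein = (protein_hgvs or "").strip()
    cdna = (cdna_hgvs or "").strip()
    if not protein and not cdna:
        raise HgvsParseError("cdna_hgvs", cdna, "no HGVS text supplied")

    if protein:
        if "fs" in protein:
            return Consequence.FRAMESHIFT, TruncationFrame.OUT_OF_FRAME
        if _PROTEIN_NONSENSE.match(protein):
            return Consequence.NONSENSE, TruncationFrame.OUT_OF_FRAME
        if protein in _SYNONYMOUS_MARKERS:
            return Consequence.SYNONYMOUS, TruncationFrame.NOT_TRUNCATING
        if _PROTEIN_INFRAME.match(protein):
            return Consequence.INFRAME_INDEL, TruncationFrame.NOT_TRUNCATING
        m = _PROTEIN_MISSENSE.match(protein)
        if m:
            if m.group(1) == m.group(3):
                raise HgvsParseError(
                    "protein_hgvs", protein,
                    "identity substitution is not a missense change",
                )
            return Consequence.MISSENSE, TruncationFrame.NOT_TRUNCATING
        raise HgvsParseError("protein_hgvs", protein, "unrecognised protein HGVS")

    # intron-offset positions with no protein-level description
    if _INTRON_OFFSET.search(cdna):
        if _SUBSTITUTION.search(cdna) or _CDNA_INDEL.match(cdna):
            return Consequence.INTRONIC, TruncationFrame.NOT_TRUNCATING
        raise HgvsParseError("cdna_hgvs", cdna, "unrecognised intronic HGVS")

    m = _SUBSTITUTION.search(cdna)
    if m:
        if m.group(1) == m.group(2):
            raise HgvsParseError(
                "cdna_hgvs", cdna, "identity substitution (reference equals alternate)"
            )
        raise HgvsParseError(
            "cdna_hgvs", cdna,
            "exonic substitution without a protein-level description; "
            "a missense fallback would be unsafe",
        )

    if _CDNA_INDEL.match(cdna):
        span = _indel_span(cdna)
        if span is not None and span % 3 == 0:
            return Consequence.INFRAME_INDEL, TruncationFrame.NOT_TRUNCATING
        raise HgvsParseError(
            "cdna_hgvs", cdna,
            "indel without protein-level description and with no inferable frame",
        )
    raise HgvsParseError("cdna_hgvs", cdna, "unrecognised cDNA HGVS")


def _indel_span(cdna: str) -> int | None:
    """Length of a simple deleted/duplicated range, if the text states one."""
    m = re.match(r"c\.(\d+)(?:_(\d+))?(del|dup)(?:[ACGT]*)$", cdna)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return end - start + 1
    m = re.match(r"c\.\d+_\d+ins([ACGT]+)$", cdna)
    if m:
        return len(m.group(1))
    return None


__all__ = [
    "Consequence",
    "SpliceVerdict",
    "Conservation",
    "LiteratureTier",
    "TruncationFrame",
    "Segregation",
    "Tier",
    "TRUNCATING",
    "ModelError",
    "HgvsParseError",
    "VariantAnnotation",
    "PatientRecord",
    "GenotypeCounts",
    "ContingencyTable2x2",
    "infer_consequence",
]
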