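"""Core domain types for multi-compartment liquid-biopsy cohorts.

A cohort is a set of patients, each contributing samples from up to five
compartments: primary tumor tissue, metastatic tumor tissue, individual
whole-genome-amplified circulating tumor cells (CTCs), cell-free circulating
tumor DNA (ctDNA), and a buffy-coat germline control.  Every sample carries a
set of somatic variant calls (SNV/INDEL with variant allele frequency and
depth) and optionally gene-level copy-number events.

Variant identity throughout the package is the genomic key
``(chrom, pos, ref, alt)``; VAF and depth are observations attached to a key,
never part of its identity.  Coordinates are VCF-native (1-based, fully
closed) and inputs are assumed pre-normalized: alleles are uppercased and
multi-allelic records are split, but no left-alignment or trimming is
performed.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

__all__ = [
    "Compartment",
    "Stage",
    "VariantKind",
    "VariantKey",
    "Variant",
    "CnvDirection",
    "CnvEvent",
    "SampleProfile",
    "PatientBundle",
    "chrom_sort_key",
]

_ALLELE_RE = re.compile(r"^[ACGTN]+$")


class Compartment(str, enum.Enum):
    """Sample class within a patient."""

    TUMOR_PRIMARY = "tumor_primary"
    TUMOR_MET = "tumor_met"
    CTC = "ctc"
    CTDNA = "ctdna"
    GERMLINE = "germline"

    @property
    def is_tumor_tissue(self) -> bool:
        return self in (Compartment.TUMOR_PRIMARY, Compartment.TUMOR_MET)


class Stage(str, enum.Enum):
    """Clinical disease stage; UNKNOWN when the manifest says NA."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNKNOWN = "NA"


class VariantKind(str, enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"


class VariantKey(NamedTuple):
    """Genomic identity of a variant; sharing across samples is key equality."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, ref, alt = text.split(":")
        return cls(chrom, int(pos), ref, alt)


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Order chromosomes 1..22, X, Y, MT before anything else (lexical tail)."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (int(name), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if name.upper() in special:
        return (special[name.upper()], "")
    return (99, name)


@dataclass(frozen=True)
class Variant:
    """One normalized somatic SNV/INDEL call in one sample.

    ``vaf`` is the variant allele frequency (fraction of reads supporting the
    alternate allele) in [0, 1]; ``depth`` the total read depth at the site
    (0 when the caller did not report it — filtering uses VAF only).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    depth: int = 0
    gene: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"non-ACGTN allele {allele!r} at {self.chrom}:{self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0,1], got {self.vaf}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def kind(self) -> VariantKind:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantKind.SNV
        return VariantKind.INDEL


class CnvDirection(str, enum.Enum):
    AMP = "AMP"
    DEL = "DEL"


@dataclass(frozen=True)
class CnvEvent:
    """Gene-level copy-number event; direction follows the copy ratio.

    Ratio > 1 is an amplification, < 1 a deletion; a ratio of exactly 1.0 is
    not an event and is rejected.
    """

    gene: str
    copy_ratio: float

    def __post_init__(self) -> None:
        if self.copy_ratio <= 0:
            raise ValueError(f"copy_ratio must be positive, got {self.copy_ratio}")
        if self.copy_ratio == 1.0:
            raise ValueError(f"copy_ratio 1.0 for {self.gene} is copy-neutral, not an event")
        if not self.gene:
            raise ValueError("gene symbol required for a CNV event")

    @property
    def direction(self) -> CnvDirection:
        return CnvDirection.AMP if self.copy_ratio > 1.0 else CnvDirection.DEL

    @property
    def key(self) -> tuple[str, str]:
        """Sharing identity for CNVs: (gene, direction)."""
        return (self.gene, self.direction.value)


@dataclass
class SampleProfile:
    """One sample's variant calls, CNV events, and compartment metadata.

    ``variants`` is keyed by :class:`VariantKey`, which enforces the
    one-call-per-key invariant within a sample.  ``timepoint`` 0 denotes the
    pre-study tumor collection; circulating samples are collected at
    timepoints 1, 2, ...
    """

    sample_id: str
    patient_id: str
    compartment: Compartment
    timepoint: int = 0
    stage: Stage = Stage.UNKNOWN
    wga: bool = False
    variants: dict[VariantKey, Variant] = field(default_factory=dict)
    cnvs: frozenset[CnvEvent] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.timepoint < 0:
            raise ValueError(f"timepoint must be >= 0, got {self.timepoint}")
        if self.wga and self.compartment is not Compartment.CTC:
            raise ValueError(
                f"sample {self.sample_id}: wga flag is only valid for CTC samples"
            )
        self.cnvs = frozenset(self.cnvs)

    def add_variant(self, variant: Variant) -> None:
        if variant.key in self.variants:
            raise ValueError(
                f"sample {self.sample_id}: duplicate variant key {variant.key}"
            )
        self.variants[variant.key] = variant

    @property
    def keys(self) -> frozenset[VariantKey]:
        return frozenset(self.variants)

    def copy_with_variants(self, variants: dict[VariantKey, Variant]) -> "SampleProfile":
        return SampleProfile(
            sample_id=self.sample_id,
            patient_id=self.patient_id,
            compartment=self.compartment,
            timepoint=self.timepoint,
            stage=self.stage,
            wga=self.wga,
            variants=dict(variants),
            cnvs=self.cnvs,
        )


@dataclass
class PatientBundle:
    """All non-germline samples of one patient plus the optional germline."""

    patient_id: str
    samples: list[SampleProfile] = field(default_factory=list)
    germline: Optional[SampleProfile] = None

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.patient_id != self.patient_id:
                raise ValueError(
                    f"sample {s.sample_id} has patient {s.patient_id}, "
                    f"expected {self.patient_id}"
                )
            if s.compartment is Compartment.GERMLINE:
                raise ValueError(
                    f"germline sample {s.sample_id} must go in the germline slot"
                )
        if self.germline is not None and self.germline.compartment is not Compartment.GERMLINE:
            raise ValueError("germline slot holds a non-germline sample")
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate sample ids in patient {self.patient_id}")

    def by_compartment(self, *compartments: Compartment) -> list[SampleProfile]:
        return [s for s in self.samples if s.compartment in compartments]

    @property
    def tumor_samples(self) -> list[SampleProfile]:
        return self.by_compartment(Compartment.TUMOR_PRIMARY, Compartment.TUMOR_MET)

    @property
    def ctc_samples(self) -> list[SampleProfile]:
        return self.by_compartment(Compartment.CTC)

    @property
    def ctdna_samples(self) -> list[SampleProfile]:
        return self.by_compartment(Compartment.CTDNA)

    @property
    def timepoints(self) -> list[int]:
        return sorted({s.timepoint for s in self.samples})

    def sample_map(self) -> dict[str, SampleProfile]:
        return {s.sample_id: s for s in self.samples}

    def copy_with_samples(
        self, samples: list[SampleProfile], germline: Optional[SampleProfile] = None
    ) -> "PatientBundle":
        return PatientBundle(
            patient_id=self.patient_id,
            samples=list(samples),
            germline=self.germline if germline is None else germline,
        )
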