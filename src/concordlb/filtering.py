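"""Compartment-specific VAF thresholds and cross-compartment concordance retention.

This is the analytical core: after germline subtraction, each sample's calls
are filtered by a per-compartment minimum VAF — 10% for WGA-amplified single
CTCs (suppressing amplification-error false positives), 1% for ctDNA and
tumor tissue — and the surviving calls are then screened for cross-sample
concordance.  A variant observed in single CTCs is only believed when it is
corroborated: seen in any tumor sample, in any ctDNA sample, or in at least
two distinct CTCs of the same patient.

Two retention modes are provided.  ``circulating_guard`` (default) applies
the corroboration requirement to CTC-only variants and always keeps
tumor- and ctDNA-supported calls, labelling unshared ones TUMOR_ONLY /
CTDNA_ONLY.  ``literal`` retains a variant only when one of the three
sharing criteria holds (tumor∩CTC or tumor∩ctDNA; CTC∩ctDNA; ≥2 CTCs),
dropping compartment-private calls everywhere.  Sharing pools all time
points within a compartment.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

from .model import (
    Compartment,
    PatientBundle,
    SampleProfile,
    Variant,
    VariantKey,
    chrom_sort_key,
)

__all__ = [
    "DEFAULT_THRESHOLDS",
    "Evidence",
    "RetainedVariant",
    "RetentionMode",
    "apply_vaf_thresholds",
    "retain_concordant",
]

#: Published pipeline defaults: 10% VAF for amplified single CTCs, 1% for
#: ctDNA and tumor samples.  Thresholds are inclusive (vaf >= cutoff kept).
DEFAULT_THRESHOLDS: dict[Compartment, float] = {
    Compartment.CTC: 0.10,
    Compartment.CTDNA: 0.01,
    Compartment.TUMOR_PRIMARY: 0.01,
    Compartment.TUMOR_MET: 0.01,
}


class RetentionMode(str, enum.Enum):
    CIRCULATING_GUARD = "circulating_guard"
    LITERAL = "literal"


class Evidence(str, enum.Enum):
    """Why a retained variant was kept; labels are cumulative."""

    TUMOR_CTC = "TUMOR_CTC"
    TUMOR_CTDNA = "TUMOR_CTDNA"
    CTC_CTDNA = "CTC_CTDNA"
    MULTI_CTC = "MULTI_CTC"
    TUMOR_ONLY = "TUMOR_ONLY"
    CTDNA_ONLY = "CTDNA_ONLY"


#: Evidence labels that satisfy the sharing criteria on their own.
SHARED_EVIDENCE = frozenset(
    {Evidence.TUMOR_CTC, Evidence.TUMOR_CTDNA, Evidence.CTC_CTDNA, Evidence.MULTI_CTC}
)


@dataclass(frozen=True)
class RetainedVariant:
    key: VariantKey
    gene: str
    carriers: tuple[tuple[str, float], ...]  # (sample_id, vaf), sorted by sample
    evidence: frozenset[Evidence]

    def __post_init__(self) -> None:
        if not self.carriers:
            raise ValueError(f"retained variant {self.key} has no carriers")
        if not self.evidence:
            raise ValueError(f"retained variant {self.key} has empty evidence")

    @property
    def carrier_ids(self) -> frozenset[str]:
        return frozenset(sid for sid, _ in self.carriers)


def _normalize_thresholds(
    thresholds: Mapping[Union[Compartment, str], float]
) -> dict[Compartment, float]:
    out: dict[Compartment, float] = {}
    for comp, cutoff in thresholds.items():
        comp = Compartment(comp)
        if not 0.0 <= float(cutoff) <= 1.0:
            raise ValueError(f"threshold for {comp.value} must be in [0,1], got {cutoff}")
        out[comp] = float(cutoff)
    return out


def apply_vaf_thresholds(
    bundle: PatientBundle,
    thresholds: Mapping[Union[Compartment, str], float] = DEFAULT_THRESHOLDS,
    inclusive: bool = True,
) -> PatientBundle:
    """Keep a variant iff its VAF meets its compartment's minimum.

    The boundary is inclusive by default (a call at exactly the printed
    cutoff is kept); set ``inclusive=False`` for a strict boundary.  CNV
    events carry no VAF and pass through untouched.  A sample whose
    compartment has no threshold is a hard error.
    """
    cutoffs = _normalize_thresholds(thresholds)
    filtered: list[SampleProfile] = []
    for sample in bundle.samples:
        if sample.compartment not in cutoffs:
            raise KeyError(
                f"no VAF threshold configured for compartment "
                f"{sample.compartment.value} (sample {sample.sample_id})"
            )
        cutoff = cutoffs[sample.compartment]
        if inclusive:
            kept = {k: v for k, v in sample.variants.items() if v.vaf >= cutoff}
        else:
            kept = {k: v for k, v in sample.variants.items() if v.vaf > cutoff}
        filtered.append(sample.copy_with_variants(kept))
    return bundle.copy_with_samples(filtered)


def _evidence_for(
    in_tumor: bool, n_ctc: int, in_ctdna: bool
) -> frozenset[Evidence]:
    flags: set[Evidence] = set()
    if in_tumor and n_ctc >= 1:
        flags.add(Evidence.TUMOR_CTC)
    if in_tumor and in_ctdna:
        flags.add(Evidence.TUMOR_CTDNA)
    if n_ctc >= 1 and in_ctdna:
        flags.add(Evidence.CTC_CTDNA)
    if n_ctc >= 2:
        flags.add(Evidence.MULTI_CTC)
    if in_tumor and n_ctc == 0 and not in_ctdna:
        flags.add(Evidence.TUMOR_ONLY)
    if in_ctdna and not in_tumor and n_ctc == 0:
        flags.add(Evidence.CTDNA_ONLY)
    return frozenset(flags)


def retain_concordant(
    bundle: PatientBundle,
    mode: Union[RetentionMode, str] = RetentionMode.CIRCULATING_GUARD,
) -> list[RetainedVariant]:
    """Apply the cross-compartment concordance criteria to a thresholded bundle.

    Returns retained variants in genomic order with every satisfied evidence
    label.  Sharing pools all time points within a compartment; "tumor" means
    any tumor sample, primary or metastatic.
    """
    mode = RetentionMode(mode)
    carriers_by_key: dict[VariantKey, list[tuple[str, float]]] = {}
    tumor_by_key: dict[VariantKey, set[str]] = {}
    ctc_by_key: dict[VariantKey, set[str]] = {}
    ctdna_by_key: dict[VariantKey, set[str]] = {}
    gene_by_key: dict[VariantKey, str] = {}

    for sample in bundle.samples:
        for key, variant in sample.variants.items():
            carriers_by_key.setdefault(key, []).append((sample.sample_id, variant.vaf))
            if variant.gene:
                gene_by_key.setdefault(key, variant.gene)
            if sample.compartment.is_tumor_tissue:
                tumor_by_key.setdefault(key, set()).add(sample.sample_id)
            elif sample.compartment is Compartment.CTC:
                ctc_by_key.setdefault(key, set()).add(sample.sample_id)
            elif sample.compartment is Compartment.CTDNA:
                ctdna_by_key.setdefault(key, set()).add(sample.sample_id)

    retained: list[RetainedVariant] = []
    for key in sorted(
        carriers_by_key, key=lambda k: (chrom_sort_key(k.chrom), k.pos, k.ref, k.alt)
    ):
        in_tumor = bool(tumor_by_key.get(key))
        n_ctc = len(ctc_by_key.get(key, ()))
        in_ctdna = bool(ctdna_by_key.get(key))
        evidence = _evidence_for(in_tumor, n_ctc, in_ctdna)
        if mode is RetentionMode.LITERAL:
            keep = bool(evidence & SHARED_EVIDENCE)
        else:
            keep = in_tumor or in_ctdna or bool(evidence & SHARED_EVIDENCE)
        if not keep:
            continue
        retained.append(
            RetainedVariant(
                key=key,
                gene=gene_by_key.get(key, ""),
                carriers=tuple(sorted(carriers_by_key[key])),
                evidence=evidence,
            )
        )
    return retained
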