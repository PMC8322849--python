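"""Shared-mutation tabulation, occurrence classes, and resemblance metrics.

Quantifies how the retained mutation profiles of the three tumor-bearing
compartments relate within a patient: pairwise shared-mutation counts
(tumor∩CTC, tumor∩ctDNA, CTC∩ctDNA, ≥2 CTCs), a partition of retained keys
by the compartments they occur in, the fraction of CTC samples concordant
with the matched tumor, the resemblance of circulating compartments to the
primary versus metastatic tumor, and Jaccard-based within-compartment
heterogeneity summaries.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

from .filtering import RetainedVariant
from .model import Compartment, PatientBundle, SampleProfile, VariantKey

logger = logging.getLogger(__name__)

__all__ = [
    "ConcordanceTable",
    "OccurrenceClass",
    "ResemblanceScore",
    "shared_mutation_table",
    "shared_cnv_table",
    "classify_occurrence",
    "ctc_concordance_fraction",
    "resemblance_scores",
    "heterogeneity_summary",
    "jaccard",
]


def jaccard(a: Iterable, b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B|; 1.0 for two empty sets (identical profiles)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


@dataclass(frozen=True)
class ConcordanceTable:
    """Per-patient shared-mutation counts between compartments."""

    patient_id: str
    n_tumor_ctc: int
    n_tumor_ctdna: int
    n_multi_ctc: int
    n_ctc_ctdna: int
    tumor_available: bool

    def __post_init__(self) -> None:
        for name in ("n_tumor_ctc", "n_tumor_ctdna", "n_multi_ctc", "n_ctc_ctdna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class OccurrenceClass(str, enum.Enum):
    """Compartment-presence pattern of a retained key; a true partition."""

    TISSUE_ONLY = "TISSUE_ONLY"
    CTC_ONLY = "CTC_ONLY"
    CTDNA_ONLY = "CTDNA_ONLY"
    TISSUE_CTC = "TISSUE_CTC"
    TISSUE_CTDNA = "TISSUE_CTDNA"
    CTC_CTDNA = "CTC_CTDNA"
    ALL_THREE = "ALL_THREE"


_OCCURRENCE_BY_PATTERN: dict[tuple[bool, bool, bool], OccurrenceClass] = {
    (True, False, False): OccurrenceClass.TISSUE_ONLY,
    (False, True, False): OccurrenceClass.CTC_ONLY,
    (False, False, True): OccurrenceClass.CTDNA_ONLY,
    (True, True, False): OccurrenceClass.TISSUE_CTC,
    (True, False, True): OccurrenceClass.TISSUE_CTDNA,
    (False, True, True): OccurrenceClass.CTC_CTDNA,
    (True, True, True): OccurrenceClass.ALL_THREE,
}


@dataclass(frozen=True)
class ResemblanceScore:
    """How a circulating compartment's keys split between the two tumor sites.

    Fractions are over the compartment's retained keys found in the primary
    and/or metastatic tumor; keys in neither tumor are excluded.  All NaN
    when a tumor site is missing or the denominator is zero.
    """

    compartment: Compartment
    f_primary_only: float
    f_met_only: float
    f_both: float
    n_keys: int


def _compartment_carriers(
    bundle: PatientBundle, retained: Sequence[RetainedVariant]
) -> dict[VariantKey, dict[Compartment, set[str]]]:
    """Map retained key -> compartment -> carrying sample ids."""
    comp_of = {s.sample_id: s.compartment for s in bundle.samples}
    out: dict[VariantKey, dict[Compartment, set[str]]] = {}
    for rv in retained:
        slots: dict[Compartment, set[str]] = {}
        for sample_id, _vaf in rv.carriers:
            comp = comp_of.get(sample_id)
            if comp is None:
                continue
            slots.setdefault(comp, set()).add(sample_id)
        out[rv.key] = slots
    return out


def shared_mutation_table(
    bundle: PatientBundle, retained: Sequence[RetainedVariant]
) -> ConcordanceTable:
    """Count retained SNV/INDEL keys shared between compartment pools.

    Each key counts once per column; "≥2 CTCs" means present in at least two
    distinct CTC samples, pooling all time points.
    """
    carriers = _compartment_carriers(bundle, retained)
    n_tumor_ctc = n_tumor_ctdna = n_multi_ctc = n_ctc_ctdna = 0
    for slots in carriers.values():
        in_tumor = bool(
            slots.get(Compartment.TUMOR_PRIMARY) or slots.get(Compartment.TUMOR_MET)
        )
        n_ctc = len(slots.get(Compartment.CTC, ()))
        in_ctdna = bool(slots.get(Compartment.CTDNA))
        if in_tumor and n_ctc >= 1:
            n_tumor_ctc += 1
        if in_tumor and in_ctdna:
            n_tumor_ctdna += 1
        if n_ctc >= 2:
            n_multi_ctc += 1
        if n_ctc >= 1 and in_ctdna:
            n_ctc_ctdna += 1
    return ConcordanceTable(
        patient_id=bundle.patient_id,
        n_tumor_ctc=n_tumor_ctc,
        n_tumor_ctdna=n_tumor_ctdna,
        n_multi_ctc=n_multi_ctc,
        n_ctc_ctdna=n_ctc_ctdna,
        tumor_available=bool(bundle.tumor_samples),
    )


def shared_cnv_table(bundle: PatientBundle) -> ConcordanceTable:
    """Parallel shared-event counts for CNVs, keyed by (gene, direction)."""
    slots_by_key: dict[tuple[str, str], dict[Compartment, set[str]]] = {}
    for sample in bundle.samples:
        for event in sample.cnvs:
            slots_by_key.setdefault(event.key, {}).setdefault(
                sample.compartment, set()
            ).add(sample.sample_id)
    n_tumor_ctc = n_tumor_ctdna = n_multi_ctc = n_ctc_ctdna = 0
    for slots in slots_by_key.values():
        in_tumor = bool(
            slots.get(Compartment.TUMOR_PRIMARY) or slots.get(Compartment.TUMOR_MET)
        )
        n_ctc = len(slots.get(Compartment.CTC, ()))
        in_ctdna = bool(slots.get(Compartment.CTDNA))
        if in_tumor and n_ctc >= 1:
            n_tumor_ctc += 1
        if in_tumor and in_ctdna:
            n_tumor_ctdna += 1
        if n_ctc >= 2:
            n_multi_ctc += 1
        if n_ctc >= 1 and in_ctdna:
            n_ctc_ctdna += 1
    return ConcordanceTable(
        patient_id=bundle.patient_id,
        n_tumor_ctc=n_tumor_ctc,
        n_tumor_ctdna=n_tumor_ctdna,
        n_multi_ctc=n_multi_ctc,
        n_ctc_ctdna=n_ctc_ctdna,
        tumor_available=bool(bundle.tumor_samples),
    )


def classify_occurrence(
    bundle: PatientBundle, retained: Sequence[RetainedVariant]
) -> dict[VariantKey, OccurrenceClass]:
    """Partition retained keys by their presence over the three pools
    (tissue = all tumor samples; CTC = all CTCs; ctDNA = all plasma)."""
    carriers = _compartment_carriers(bundle, retained)
    out: dict[VariantKey, OccurrenceClass] = {}
    for key, slots in carriers.items():
        pattern = (
            bool(slots.get(Compartment.TUMOR_PRIMARY) or slots.get(Compartment.TUMOR_MET)),
            bool(slots.get(Compartment.CTC)),
            bool(slots.get(Compartment.CTDNA)),
        )
        if pattern == (False, False, False):
            # Retained keys always have at least one carrier in a known
            # compartment; anything else indicates inconsistent inputs.
            raise ValueError(f"retained key {key} has no compartment carriers")
        out[key] = _OCCURRENCE_BY_PATTERN[pattern]
    return out


def ctc_concordance_fraction(
    cohort: Sequence[PatientBundle],
    retained_by_patient: Mapping[str, Sequence[RetainedVariant]],
) -> tuple[float, list[dict]]:
    """Fraction of CTC samples sharing >= 1 retained key with the matched tumor.

    Patients without tumor samples are excluded from the denominator.
    Returns the fraction (NaN when no CTC is evaluable) and a per-CTC table
    of booleans.
    """
    rows: list[dict] = []
    for bundle in cohort:
        if not bundle.tumor_samples:
            continue
        tumor_keys: set[VariantKey] = set()
        retained_keys = {rv.key for rv in retained_by_patient.get(bundle.patient_id, ())}
        for sample in bundle.tumor_samples:
            tumor_keys |= sample.keys & retained_keys
        for ctc in bundle.ctc_samples:
            shared = ctc.keys & tumor_keys
            rows.append(
                {
                    "patient_id": bundle.patient_id,
                    "sample_id": ctc.sample_id,
                    "shares_with_tumor": bool(shared),
                    "n_shared": len(shared),
                }
            )
    if not rows:
        return float("nan"), rows
    fraction = sum(r["shares_with_tumor"] for r in rows) / len(rows)
    return fraction, rows


def resemblance_scores(
    bundle: PatientBundle, retained: Sequence[RetainedVariant]
) -> list[ResemblanceScore]:
    """Split each circulating compartment's keys by primary/met tumor origin.

    Requires both a primary and a metastatic tumor sample; otherwise returns
    NaN scores with a warning.
    """
    carriers = _compartment_carriers(bundle, retained)
    has_primary = bool(bundle.by_compartment(Compartment.TUMOR_PRIMARY))
    has_met = bool(bundle.by_compartment(Compartment.TUMOR_MET))
    scores: list[ResemblanceScore] = []
    for compartment in (Compartment.CTC, Compartment.CTDNA):
        if not (has_primary and has_met):
            logger.warning(
                "patient %s lacks a %s tumor sample; resemblance undefined",
                bundle.patient_id,
                "primary" if not has_primary else "metastatic",
            )
            scores.append(
                ResemblanceScore(compartment, float("nan"), float("nan"), float("nan"), 0)
            )
            continue
        n_primary_only = n_met_only = n_both = 0
        for slots in carriers.values():
            if not slots.get(compartment):
                continue
            in_primary = bool(slots.get(Compartment.TUMOR_PRIMARY))
            in_met = bool(slots.get(Compartment.TUMOR_MET))
            if in_primary and in_met:
                n_both += 1
            elif in_primary:
                n_primary_only += 1
            elif in_met:
                n_met_only += 1
        denom = n_primary_only + n_met_only + n_both
        if denom == 0:
            scores.append(
                ResemblanceScore(compartment, float("nan"), float("nan"), float("nan"), 0)
            )
            continue
        scores.append(
            ResemblanceScore(
                compartment,
                n_primary_only / denom,
                n_met_only / denom,
                n_both / denom,
                denom,
            )
        )
    return scores


def heterogeneity_summary(
    bundle: PatientBundle, retained: Sequence[RetainedVariant]
) -> dict[str, float]:
    """Private fraction and mean pairwise within-compartment Jaccard indexes.

    ``private_fraction`` is the share of retained keys confined to a single
    compartment pool.  Jaccard means are over all sample pairs within the
    compartment, restricted to retained keys; NaN with fewer than two
    samples.
    """
    classes = classify_occurrence(bundle, retained)
    retained_keys = set(classes)
    private = {
        OccurrenceClass.TISSUE_ONLY,
        OccurrenceClass.CTC_ONLY,
        OccurrenceClass.CTDNA_ONLY,
    }
    private_fraction = (
        sum(c in private for c in classes.values()) / len(classes)
        if classes
        else float("nan")
    )

    def mean_pairwise(samples: list[SampleProfile]) -> float:
        if len(samples) < 2:
            return float("nan")
        values = [
            jaccard(a.keys & retained_keys, b.keys & retained_keys)
            for a, b in combinations(samples, 2)
        ]
        return sum(values) / len(values)

    return {
        "private_fraction": private_fraction,
        "mean_ctc_jaccard": mean_pairwise(bundle.ctc_samples),
        "mean_ctdna_jaccard": mean_pairwise(bundle.ctdna_samples),
    }
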