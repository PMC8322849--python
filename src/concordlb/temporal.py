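"""Variant x time-point presence matrices and temporal classification.

For serially sampled patients, builds a boolean presence matrix of retained
variant keys (and CNV (gene, direction) keys) over time points, then labels
each key's trajectory: PERSISTENT (present at every observed time point),
EMERGENT (absent at first, present from some time point onward), LOST
(present at first, absent from some time point onward), or TRANSIENT
(any other pattern).

Presence is pooled across samples within a (time point, compartment) cell —
a single carrying CTC marks presence.  The default scope keeps compartments
separate so a tumor-only baseline time point does not force LOST calls in
the circulating compartments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Optional, Sequence, Union

from .filtering import RetainedVariant
from .model import Compartment, PatientBundle, VariantKey, chrom_sort_key

__all__ = [
    "MatrixScope",
    "PresenceMatrix",
    "TemporalKind",
    "TemporalClass",
    "presence_matrix",
    "classify_temporal",
    "classify_pattern",
]

#: Matrix row key: a somatic variant key or a ("CNV", gene, direction) tuple.
RowKey = Union[VariantKey, tuple[str, str, str]]


class MatrixScope(str, enum.Enum):
    POOLED = "pooled"
    PER_COMPARTMENT = "per_compartment"


class TemporalKind(str, enum.Enum):
    PERSISTENT = "PERSISTENT"
    EMERGENT = "EMERGENT"
    LOST = "LOST"
    TRANSIENT = "TRANSIENT"


@dataclass(frozen=True)
class TemporalClass:
    """Trajectory label; ``t`` is the transition time point for
    EMERGENT (first presence) and LOST (first absence)."""

    kind: TemporalKind
    t: Optional[int] = None

    def __str__(self) -> str:
        return f"{self.kind.value}(t={self.t})" if self.t is not None else self.kind.value


def _row_sort_key(key: RowKey):
    if isinstance(key, VariantKey):
        return (0, chrom_sort_key(key.chrom), key.pos, key.ref, key.alt)
    return (1, key[1], key[2], 0, "")


@dataclass
class PresenceMatrix:
    """Boolean presence of keys over (time point, compartment) cells."""

    patient_id: str
    keys: list[RowKey]
    timepoints: list[int]
    compartments: list[Compartment]
    scope: MatrixScope
    cells: dict[tuple[RowKey, int, Optional[Compartment]], bool] = field(
        default_factory=dict
    )
    #: time points at which each compartment actually has samples
    observed: dict[Optional[Compartment], list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sorted(self.timepoints) != self.timepoints or len(set(self.timepoints)) != len(
            self.timepoints
        ):
            raise ValueError("timepoints must be strictly increasing")

    def pattern(
        self, key: RowKey, compartment: Optional[Compartment] = None
    ) -> tuple[bool, ...]:
        """Presence pattern of a key over the observed time points of a
        compartment (or pooled when ``compartment`` is None)."""
        timepoints = self.observed.get(compartment, self.timepoints)
        return tuple(bool(self.cells.get((key, t, compartment), False)) for t in timepoints)


def presence_matrix(
    bundle: PatientBundle,
    retained: Sequence[RetainedVariant],
    scope: Union[MatrixScope, str] = MatrixScope.PER_COMPARTMENT,
    include_cnv: bool = True,
) -> PresenceMatrix:
    """Build the presence matrix for a serially sampled patient.

    Only retained variant keys enter the matrix; CNV (gene, direction) keys
    are included per-sample without retention (they carry no VAF).  Requires
    samples at >= 2 time points.
    """
    scope = MatrixScope(scope)
    timepoints = bundle.timepoints
    if len(timepoints) < 2:
        raise ValueError(
            f"patient {bundle.patient_id} has samples at {len(timepoints)} time "
            "point(s); temporal analysis requires >= 2 — use the single-timepoint "
            "concordance workflow instead"
        )
    retained_keys = {rv.key for rv in retained}
    samples_by = {}
    for s in bundle.samples:
        comp = s.compartment if scope is MatrixScope.PER_COMPARTMENT else None
        samples_by.setdefault((s.timepoint, comp), []).append(s)

    cells: dict[tuple[RowKey, int, Optional[Compartment]], bool] = {}
    keys: set[RowKey] = set()
    compartments: set[Compartment] = set()
    observed: dict[Optional[Compartment], set[int]] = {}
    for (t, comp), samples in samples_by.items():
        observed.setdefault(comp, set()).add(t)
        if comp is not None:
            compartments.add(comp)
        for s in samples:
            for key in s.keys & retained_keys:
                cells[(key, t, comp)] = True
                keys.add(key)
            if include_cnv:
                for event in s.cnvs:
                    row: RowKey = ("CNV", event.gene, event.direction.value)
                    cells[(row, t, comp)] = True
                    keys.add(row)
    return PresenceMatrix(
        patient_id=bundle.patient_id,
        keys=sorted(keys, key=_row_sort_key),
        timepoints=timepoints,
        compartments=sorted(compartments, key=lambda c: c.value),
        scope=scope,
        cells=cells,
        observed={comp: sorted(ts) for comp, ts in observed.items()},
    )


def classify_pattern(
    present: Sequence[bool], timepoints: Sequence[int]
) -> TemporalClass:
    """Label one presence pattern over ordered time points.

    PERSISTENT: present everywhere.  EMERGENT: absent at the first time
    point, then present from some time point onward without interruption.
    LOST: present at the first time point, then absent from some time point
    onward.  TRANSIENT: everything else (including never-present).
    """
    if len(present) != len(timepoints):
        raise ValueError("pattern and timepoints must have equal length")
    if not present:
        raise ValueError("empty pattern")
    present = [bool(p) for p in present]
    if all(present):
        return TemporalClass(TemporalKind.PERSISTENT)
    if any(present) and not present[0]:
        first_true = present.index(True)
        if all(present[first_true:]):
            return TemporalClass(TemporalKind.EMERGENT, timepoints[first_true])
    if present[0]:
        first_false = present.index(False)
        if not any(present[first_false:]):
            return TemporalClass(TemporalKind.LOST, timepoints[first_false])
    return TemporalClass(TemporalKind.TRANSIENT)


def classify_temporal(
    matrix: PresenceMatrix, compartment: Optional[Compartment] = None
) -> dict[RowKey, TemporalClass]:
    """Classify every matrix key over the observed time-point axis.

    With a per-compartment matrix, pass ``compartment`` to classify within
    that compartment's own observed time points (keys never present there
    are skipped); with ``compartment=None`` presence is pooled across the
    matrix's compartment cells at each time point.
    """
    if len(matrix.timepoints) < 2:
        raise ValueError("temporal classification requires >= 2 time points")
    out: dict[RowKey, TemporalClass] = {}
    if compartment is None and matrix.scope is MatrixScope.PER_COMPARTMENT:
        # pool across compartments: present at t if present in any cell at t
        for key in matrix.keys:
            pattern = tuple(
                any(
                    matrix.cells.get((key, t, comp), False)
                    for comp in matrix.compartments
                )
                for t in matrix.timepoints
            )
            out[key] = classify_pattern(pattern, matrix.timepoints)
        return out
    timepoints = matrix.observed.get(compartment, matrix.timepoints)
    if len(timepoints) < 2:
        raise ValueError(
            f"compartment {compartment} observed at {len(timepoints)} time point(s)"
        )
    for key in matrix.keys:
        pattern = matrix.pattern(key, compartment)
        if compartment is not None and not any(pattern):
            continue
        out[key] = classify_pattern(pattern, timepoints)
    return out
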