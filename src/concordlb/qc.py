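"""k-of-n quality gate for whole-genome-amplified single CTCs.

Before any sequencing analysis, each amplified single cell is screened with a
multi-region panel — either a qPCR panel where a region counts positive when
its Ct value is strictly below a threshold, or a binary amplicon panel.  A
cell passes when at least ``min_positive`` of ``n_regions`` regions are
positive.  Two presets ship: ``lung_ct_5of10`` (Ct < 35 in at least 5 of 10
regions) and ``breast_bin_2of4`` (at least 2 of 4 amplicons positive), both a
50% positive rate.

Only WGA-amplified CTC samples are gated; tumor, ctDNA and germline samples
pass through untouched.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .model import Compartment, PatientBundle

logger = logging.getLogger(__name__)

__all__ = [
    "QcMode",
    "QcPanelResult",
    "QcRule",
    "QcVerdict",
    "RetentionReport",
    "QC_PRESETS",
    "evaluate_qc",
    "apply_qc",
    "read_qc_table",
    "write_qc_table",
]


class QcMode(str, enum.Enum):
    CT = "CT"
    BINARY = "BINARY"


class QcVerdict(str, enum.Enum):
    PASS = "PASS"
    FAIL = "FAIL"


@dataclass(frozen=True)
class QcPanelResult:
    """QC panel readout for one sample: (region_id, Ct value or positivity)."""

    sample_id: str
    mode: QcMode
    values: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.mode is QcMode.CT and any(v < 0 for _, v in self.values):
            raise ValueError(f"negative Ct value in panel for {self.sample_id}")

    @property
    def n_regions(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class QcRule:
    """Pass iff >= min_positive of n_regions regions are positive.

    In CT mode a region is positive when its Ct is strictly below
    ``ct_threshold``; in binary mode when its value is truthy.
    """

    min_positive: int
    n_regions: int
    ct_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if not 1 <= self.min_positive <= self.n_regions:
            raise ValueError(
                f"need 1 <= min_positive <= n_regions, got "
                f"{self.min_positive}/{self.n_regions}"
            )


QC_PRESETS: dict[str, QcRule] = {
    "lung_ct_5of10": QcRule(min_positive=5, n_regions=10, ct_threshold=35.0),
    "breast_bin_2of4": QcRule(min_positive=2, n_regions=4, ct_threshold=None),
}


def region_positive(value: float, rule: QcRule, mode: QcMode) -> bool:
    if mode is QcMode.CT:
        if rule.ct_threshold is None:
            raise ValueError("CT-mode panel evaluated against a rule without ct_threshold")
        return value < rule.ct_threshold
    return bool(value)


def evaluate_qc(panel: QcPanelResult, rule: QcRule) -> QcVerdict:
    """Apply the k-of-n gate to one panel result."""
    if panel.n_regions != rule.n_regions:
        raise ValueError(
            f"panel for {panel.sample_id} has {panel.n_regions} regions, "
            f"rule expects {rule.n_regions}"
        )
    n_positive = sum(region_positive(v, rule, panel.mode) for _, v in panel.values)
    return QcVerdict.PASS if n_positive >= rule.min_positive else QcVerdict.FAIL


@dataclass
class RetentionReport:
    """Per-compartment isolated/passed tallies after QC gating."""

    isolated: dict[str, int] = field(default_factory=dict)
    passed: dict[str, int] = field(default_factory=dict)

    def fraction(self, compartment: Union[Compartment, str]) -> float:
        name = compartment.value if isinstance(compartment, Compartment) else compartment
        total = self.isolated.get(name, 0)
        return self.passed.get(name, 0) / total if total else float("nan")

    def as_dict(self) -> dict:
        return {
            "isolated": dict(self.isolated),
            "passed": dict(self.passed),
            "fractions": {
                c: self.fraction(c) for c, n in self.isolated.items() if n
            },
        }


def apply_qc(
    cohort: Sequence[PatientBundle],
    panels: Mapping[str, QcPanelResult],
    rule: QcRule,
    missing_panel: str = "fail",
) -> tuple[list[PatientBundle], RetentionReport]:
    """Gate WGA CTC samples across the cohort; other compartments pass freely.

    ``missing_panel`` controls a WGA sample without a panel result: ``fail``
    (default, with a warning) removes it, ``pass`` keeps it.
    Surviving samples are returned unmodified.
    """
    if missing_panel not in ("fail", "pass"):
        raise ValueError(f"missing_panel must be 'fail' or 'pass', got {missing_panel!r}")
    report = RetentionReport()
    filtered: list[PatientBundle] = []
    for bundle in cohort:
        kept = []
        for sample in bundle.samples:
            comp = sample.compartment.value
            report.isolated[comp] = report.isolated.get(comp, 0) + 1
            if not sample.wga:
                report.passed[comp] = report.passed.get(comp, 0) + 1
                kept.append(sample)
                continue
            panel = panels.get(sample.sample_id)
            if panel is None:
                logger.warning(
                    "WGA sample %s has no QC panel result; policy=%s",
                    sample.sample_id,
                    missing_panel,
                )
                verdict = QcVerdict.PASS if missing_panel == "pass" else QcVerdict.FAIL
            else:
                verdict = evaluate_qc(panel, rule)
            if verdict is QcVerdict.PASS:
                report.passed[comp] = report.passed.get(comp, 0) + 1
                kept.append(sample)
        filtered.append(bundle.copy_with_samples(kept))
    return filtered, report


def read_qc_table(path) -> dict[str, QcPanelResult]:
    """Read the QC TSV (sample_id, region_id, mode, value) into panel results."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "region_id": str})
    for col in ("sample_id", "region_id", "mode", "value"):
        if col not in table.columns:
            raise ValueError(f"QC table {path} missing column {col}")
    panels: dict[str, QcPanelResult] = {}
    for sample_id, group in table.groupby("sample_id", sort=True):
        modes = set(group["mode"])
        if len(modes) != 1:
            raise ValueError(f"QC panel for {sample_id} mixes modes {modes}")
        panels[str(sample_id)] = QcPanelResult(
            sample_id=str(sample_id),
            mode=QcMode(modes.pop()),
            values=tuple(
                (str(r.region_id), float(r.value)) for r in group.itertuples(index=False)
            ),
        )
    return panels


def write_qc_table(panels: Mapping[str, QcPanelResult], path) -> None:
    rows = [
        {"sample_id": p.sample_id, "region_id": region, "mode": p.mode.value, "value": value}
        for p in sorted(panels.values(), key=lambda p: p.sample_id)
        for region, value in p.values
    ]
    pd.DataFrame(rows, columns=["sample_id", "region_id", "mode", "value"]).to_csv(
        path, sep="\t", index=False
    )
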