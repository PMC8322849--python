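"""Per-sample CNV burden and two-group comparison by disease stage.

Burden is the number of gene-level copy-number events (amplifications plus
deletions) called in a sample.  Groups of samples — by default early
(II+III) versus advanced (IV) stage within one compartment — are compared
with Welch's unequal-variance two-sample t-test, two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from scipy import stats

from .model import Compartment, PatientBundle, SampleProfile, Stage

__all__ = [
    "BurdenComparison",
    "DEFAULT_STAGE_GROUPING",
    "cnv_count",
    "welch_t_test",
    "compare_burden_by_stage",
]

#: Default comparison: stage II+III versus stage IV.
DEFAULT_STAGE_GROUPING: tuple[frozenset[Stage], frozenset[Stage]] = (
    frozenset({Stage.II, Stage.III}),
    frozenset({Stage.IV}),
)


def cnv_count(profile: SampleProfile) -> int:
    """Number of CNV events (AMP + DEL) in one sample."""
    return len(profile.cnvs)


@dataclass(frozen=True)
class BurdenComparison:
    group_labels: tuple[str, str]
    group_counts: tuple[tuple[int, ...], tuple[int, ...]]
    mean_per_group: tuple[float, float]
    t_statistic: float
    p_value: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must be in [0,1], got {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha

    def as_dict(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "group_counts": [list(g) for g in self.group_counts],
            "mean_per_group": list(self.mean_per_group),
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
        }


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch's two-sample t-test (unequal variance), two-sided.

    Each group needs >= 2 observations.  When both groups are constant the
    test is degenerate: equal constants give (0, 1), unequal constants an
    infinite statistic with p = 0.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"each group needs >= 2 samples, got {len(a)} and {len(b)}")
    mean_a = sum(a) / len(a)
    mean_b = sum(b) / len(b)
    var_a = sum((x - mean_a) ** 2 for x in a) / (len(a) - 1)
    var_b = sum((x - mean_b) ** 2 for x in b) / (len(b) - 1)
    if var_a == 0.0 and var_b == 0.0:
        if mean_a == mean_b:
            return 0.0, 1.0
        return math.copysign(math.inf, mean_a - mean_b), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_burden_by_stage(
    cohort: Sequence[PatientBundle],
    compartment: Union[Compartment, str],
    grouping: tuple[Iterable[Stage], Iterable[Stage]] = DEFAULT_STAGE_GROUPING,
    alpha: float = 0.05,
) -> BurdenComparison:
    """Compare per-sample CNV counts between two stage groups in a compartment."""
    compartment = Compartment(compartment)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    group_a = frozenset(Stage(s) for s in grouping[0])
    group_b = frozenset(Stage(s) for s in grouping[1])
    if group_a & group_b:
        raise ValueError(f"stage groups overlap: {sorted(s.value for s in group_a & group_b)}")

    def counts(stages: frozenset[Stage]) -> tuple[int, ...]:
        return tuple(
            cnv_count(s)
            for bundle in cohort
            for s in bundle.by_compartment(compartment)
            if s.stage in stages
        )

    counts_a, counts_b = counts(group_a), counts(group_b)
    t, p = welch_t_test(counts_a, counts_b)
    label = lambda g: "+".join(sorted(s.value for s in g))
    return BurdenComparison(
        group_labels=(label(group_a), label(group_b)),
        group_counts=(counts_a, counts_b),
        mean_per_group=(
            sum(counts_a) / len(counts_a),
            sum(counts_b) / len(counts_b),
        ),
        t_statistic=t,
        p_value=p,
        alpha=alpha,
    )
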