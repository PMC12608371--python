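"""Evaluation metrics and group-comparison statistics for stage durations.

Two jobs live here.  First, confusion-count metrics for the segmentation
and classification networks (sensitivity, specificity, accuracy,
precision, F1, IoU from TP/FP/TN/FN pixel or image counts).  Second, the
comparative statistics applied to per-embryo stage durations: mean with
its standard error, the unpaired two-tailed Student's t-test (pooled
variance; a Welch option is exposed), the percent delay of a treated
group relative to control, and the conventional significance-star
coding.  Raw stage-wise p values are reported without multiple-testing
correction, matching common practice for small per-stage comparisons;
this is a reporting convention, not an endorsement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stages import StageLabel, EPIDERMAL_STAGES

__all__ = [
    "ConfusionCounts",
    "confusion_metrics",
    "multiclass_macro_metrics",
    "mean_sem",
    "unpaired_t_test",
    "percent_delay",
    "significance_stars",
    "GroupDurations",
    "ComparisonResult",
    "compare_groups",
    "comparison_table",
]

UNDEFINED = None  # marker for metrics whose denominator vanishes


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN counts (pixels for segmentation, items for classification)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: int, den: int) -> float | None:
    return UNDEFINED if den == 0 else num / den


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Six standard metrics from confusion counts.

    Returns fractions in [0, 1]; a metric whose denominator is zero is
    reported as ``None`` (undefined) rather than NaN.
    """
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    acc = _ratio(c.tp + c.tn, c.total)
    prec = _ratio(c.tp, c.tp + c.fp)
    if prec in (UNDEFINED, 0) or sens in (UNDEFINED, 0):
        f1 = UNDEFINED if (prec is UNDEFINED or sens is UNDEFINED) else 0.0
        if prec == 0 and sens == 0:
            f1 = UNDEFINED  # harmonic mean of two zeros
    else:
        f1 = 2 * prec * sens / (prec + sens)
    iou = _ratio(c.tp, c.tp + c.fp + c.fn)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "precision": prec,
        "f1": f1,
        "iou": iou,
    }


def multiclass_macro_metrics(cm: np.ndarray) -> dict[str, float]:
    """Macro-averaged precision/recall/F1 and accuracy from a confusion matrix.

    ``cm[i, j]`` counts items of true class i predicted as class j.
    Classes absent from the data (empty row and column) are skipped;
    per-class ratios with a zero denominator count as 0, the usual
    convention for macro averaging.
    """
    cm = np.asarray(cm, dtype=np.int64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    precisions, recalls, f1s = [], [], []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        row, col = cm[k].sum(), cm[:, k].sum()
        if row == 0 and col == 0:
            continue
        p = tp / col if col else 0.0
        r = tp / row if row else 0.0
        precisions.append(p)
        recalls.append(r)
        f1s.append(0.0 if p + r == 0 else 2 * p * r / (p + r))
    return {
        "accuracy": float(np.trace(cm) / cm.sum()),
        "precision": float(np.mean(precisions)),
        "recall": float(np.mean(recalls)),
        "f1": float(np.mean(f1s)),
    }


def mean_sem(values) -> tuple[float, float | None]:
    """Sample mean and standard error (sd with n-1 denominator over sqrt n)."""
    v = np.asarray(list(values), dtype=np.float64)
    if v.size == 0:
        raise ValueError("no values")
    mean = float(v.mean())
    if v.size < 2:
        return mean, UNDEFINED
    return mean, float(v.std(ddof=1) / math.sqrt(v.size))


def unpaired_t_test(
    group_a, group_b, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample two-tailed Student's t-test.

    Pooled-variance by default (df = n_a + n_b - 2); ``equal_var=False``
    switches to the Welch form.  Degenerate zero-variance inputs: equal
    means give (0, 1); unequal means give (+-inf, 0).
    """
    a = np.asarray(list(group_a), dtype=np.float64)
    b = np.asarray(list(group_b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    if equal_var:
        df = a.size + b.size - 2
        pooled = ((a.size - 1) * va + (b.size - 1) * vb) / df
        se = math.sqrt(pooled * (1 / a.size + 1 / b.size))
    else:
        se = math.sqrt(va / a.size + vb / b.size)
        df = (va / a.size + vb / b.size) ** 2 / (
            (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
        )
    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), p


def percent_delay(control_mean: float, treated_mean: float) -> float:
    """Percent change of the treated group mean relative to control."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (treated_mean - control_mean) / control_mean


def significance_stars(p: float) -> str:
    """Star coding with strict thresholds 0.05 / 0.01 / 0.001 / 0.0001."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p value out of range: {p}")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupDurations:
    """Per-embryo duration tables for one experimental group.

    ``tables`` is a list of :class:`embryostage.timeline.StageDurationTable`.
    An embryo whose table lists a stage in ``excluded_stages`` (because a
    consecutive misclassification made that stage's span unreliable) is
    dropped from that stage's sample only, reducing N for that stage.
    """

    label: str
    tables: list = field(default_factory=list)

    def stage_values(self, stage: StageLabel) -> np.ndarray:
        vals = [
            t.durations_min[stage]
            for t in self.tables
            if stage not in t.excluded_stages
        ]
        return np.asarray(vals, dtype=np.float64)

    def transition_values(self, boundary: tuple[StageLabel, StageLabel]) -> np.ndarray:
        vals = [t.transitions_min.get(boundary, 0.0) for t in self.tables]
        return np.asarray(vals, dtype=np.float64)

    def stage_n(self, stage: StageLabel) -> int:
        return len(self.stage_values(stage))


@dataclass
class ComparisonResult:
    """One stage's (or transition's) control-vs-treated comparison."""

    name: str
    control_mean: float | None
    control_sem: float | None
    control_n: int
    treated_mean: float | None
    treated_sem: float | None
    treated_n: int
    percent_delay: float | None
    t: float | None
    p: float | None
    stars: str
    testable: bool


def _compare_samples(name, a, b) -> ComparisonResult:
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        return ComparisonResult(
            name,
            float(np.mean(a)) if n_a else None,
            None,
            n_a,
            float(np.mean(b)) if n_b else None,
            None,
            n_b,
            None,
            None,
            None,
            "not-testable",
            False,
        )
    ma, sa = mean_sem(a)
    mb, sb = mean_sem(b)
    t, p = unpaired_t_test(a, b)
    delay = percent_delay(ma, mb) if ma > 0 else None
    return ComparisonResult(
        name, ma, sa, n_a, mb, sb, n_b, delay, t, p, significance_stars(p), True
    )


def compare_groups(
    control: GroupDurations, treated: GroupDurations
) -> list[ComparisonResult]:
    """Stage-wise and transition-wise comparison of two embryo groups.

    For each of the five epidermal stages, and for each adjacent-stage
    transition observed in either group, computes mean +- SEM per group,
    the unpaired t-test, the percent delay of treated relative to
    control, and significance stars.  Per stage, embryos whose table
    excludes that stage are dropped from that stage's sample only.
    """
    if not control.tables or not treated.tables:
        raise ValueError("both groups must contain at least one embryo")
    results = []
    for stage in EPIDERMAL_STAGES:
        results.append(
            _compare_samples(
                stage.display_name,
                control.stage_values(stage),
                treated.stage_values(stage),
            )
        )
    boundaries = sorted(
        {b for g in (control, treated) for t in g.tables for b in t.transitions_min},
        key=lambda b: (b[0].value, b[1].value),
    )
    for b in boundaries:
        name = f"transition {b[0].display_name} -> {b[1].display_name}"
        results.append(
            _compare_samples(
                name, control.transition_values(b), treated.transition_values(b)
            )
        )
    return results


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Comparison results as a DataFrame mirroring the duration-table layout."""
    return pd.DataFrame(
        [
            {
                "stage": r.name,
                "control_mean": r.control_mean,
                "control_sem": r.control_sem,
                "control_n": r.control_n,
                "treated_mean": r.treated_mean,
                "treated_sem": r.treated_sem,
                "treated_n": r.treated_n,
                "delay_pct": r.percent_delay,
                "t": r.t,
                "p": r.p,
                "stars": r.stars,
            }
            for r in results
        ]
    )
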