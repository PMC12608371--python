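"""Developmental timelines from per-frame stage probabilities.

The classifier emits one probability vector per frame; because epidermal
development visits its stages in a fixed order, the probability series
can be decoded into a timeline by simple rules:

* the *called* stage of a frame is the argmax of its probabilities (ties
  break toward the earlier stage, respecting monotone development);
* a frame whose call interrupts a continuous single-stage run is a
  *misclassification* — *isolated* when one frame is flanked on both
  sides by the same stage (it is corrected to that stage), *consecutive*
  when a run of two or more identical wrong calls interrupts a
  single-stage period (never auto-corrected; the interrupted stage is
  excluded from comparative statistics for that embryo);
* frames at a boundary between two adjacent stages may form a
  *transition period*, recognised either as an argmax oscillation
  between the two stages or as frames where the two stages share the
  probability mass with no stage reaching ``theta_mixed`` (default 0.6,
  from the 40-60% mixed-probability pattern);
* stage durations are the 5-minute frame interval times the number of
  that stage's non-transition frames, with transition spans reported
  separately per boundary.

Transition windows are detected on the original argmax calls: an
oscillation looks, frame by frame, exactly like a string of isolated
misclassifications, so any misclassification flags inside a recognised
transition window are revoked (transition takes precedence).  A window
only counts as an oscillation if it contains a *reversal* — a frame of
the earlier stage after a frame of the later one; a plain one-step stage
switch is not a transition.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stages import StageLabel, ALL_STAGES, EPIDERMAL_STAGES, N_STAGES

__all__ = [
    "TimeGrid",
    "Flag",
    "StageCall",
    "TimelineSeries",
    "BoundaryTag",
    "MisclassificationReport",
    "StageDurationTable",
    "call_stages",
    "detect_misclassifications",
    "apply_corrections",
    "identify_transitions",
    "compute_durations",
    "analyze_series",
    "series_to_frame",
    "read_probability_csv",
    "write_timeline_csv",
    "plot_timeline",
]


@dataclass(frozen=True)
class TimeGrid:
    """Acquisition grid: first frame at 150 min, one frame every 5 min."""

    time_origin_min: float = 150.0
    interval_min: float = 5.0

    def __post_init__(self) -> None:
        if self.interval_min <= 0:
            raise ValueError("interval_min must be positive")

    def time_of(self, index: int) -> float:
        return self.time_origin_min + self.interval_min * index


class Flag(enum.Enum):
    CLEAN = "clean"
    ISOLATED = "isolated_misclassification"
    CONSECUTIVE = "consecutive_misclassification"


@dataclass
class StageCall:
    """One frame's decoded state on the timeline."""

    index: int
    time_min: float
    probs: np.ndarray
    called_stage: StageLabel
    corrected_stage: StageLabel | None = None
    is_transition: bool = False
    transition_boundary: tuple[StageLabel, StageLabel] | None = None
    flag: Flag = Flag.CLEAN

    def effective_stage(self, use_corrections: bool = True) -> StageLabel:
        if use_corrections and self.corrected_stage is not None:
            return self.corrected_stage
        return self.called_stage


@dataclass
class BoundaryTag:
    """Pattern classification of one stage boundary."""

    left_index: int  # last frame of the earlier stable segment
    from_stage: StageLabel
    to_stage: StageLabel
    pattern: str  # mixed | oscillation | none | anomalous


@dataclass
class TimelineSeries:
    """Time-ordered stage calls for one embryo."""

    calls: list[StageCall]
    grid: TimeGrid = field(default_factory=TimeGrid)
    embryo_id: str = ""
    group: str = ""
    boundary_tags: list[BoundaryTag] = field(default_factory=list)
    excluded_stages: set[StageLabel] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.calls)

    def called(self) -> list[StageLabel]:
        return [c.called_stage for c in self.calls]

    def effective(self, use_corrections: bool = True) -> list[StageLabel]:
        return [c.effective_stage(use_corrections) for c in self.calls]


@dataclass
class MisclassificationReport:
    """Tally of flagged frames, by kind and by the stage they interrupt."""

    n_isolated: int = 0
    n_consecutive_runs: int = 0
    n_consecutive_frames: int = 0
    per_stage: dict[StageLabel, int] = field(default_factory=dict)
    total_frames: int = 0

    @property
    def n_misclassified(self) -> int:
        return self.n_isolated + self.n_consecutive_frames

    @property
    def rate(self) -> float:
        return self.n_misclassified / self.total_frames if self.total_frames else 0.0


@dataclass
class StageDurationTable:
    """Minutes spent per stage and per transition for one embryo."""

    embryo_id: str
    group: str
    durations_min: dict[StageLabel, float]
    transitions_min: dict[tuple[StageLabel, StageLabel], float]
    excluded_stages: set[StageLabel]
    interval_min: float
    n_frames: int

    def check_conservation(self) -> None:
        """Stage + transition spans must add up to the series length."""
        total = sum(self.durations_min.values()) + sum(self.transitions_min.values())
        expected = self.interval_min * self.n_frames
        if abs(total - expected) > 1e-9:
            raise AssertionError(
                f"frame conservation violated: {total} != {expected}"
            )

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "embryo_id": self.embryo_id,
            "group": self.group,
            "interval_min": self.interval_min,
            "n_frames": self.n_frames,
            "durations_min": {s.name: v for s, v in self.durations_min.items()},
            "transitions_min": {
                f"{a.name}->{b.name}": v for (a, b), v in self.transitions_min.items()
            },
            "excluded_stages": sorted(s.name for s in self.excluded_stages),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StageDurationTable":
        if isinstance(source, Path):
            text = source.read_text()
        elif source.lstrip().startswith("{"):
            text = source
        else:
            text = Path(source).read_text()
        doc = json.loads(text)
        return cls(
            embryo_id=doc["embryo_id"],
            group=doc["group"],
            durations_min={
                StageLabel[k]: v for k, v in doc["durations_min"].items()
            },
            transitions_min={
                (StageLabel[k.split("->")[0]], StageLabel[k.split("->")[1]]): v
                for k, v in doc["transitions_min"].items()
            },
            excluded_stages={StageLabel[s] for s in doc["excluded_stages"]},
            interval_min=doc["interval_min"],
            n_frames=doc["n_frames"],
        )


def _validate_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[1] != N_STAGES:
        raise ValueError(f"expected (n_frames, {N_STAGES}) probabilities")
    if probs.shape[0] == 0:
        raise ValueError("empty probability series")
    if (probs < -1e-12).any() or (probs > 1 + 1e-12).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("probability rows must sum to 1 within 1e-6")
    return probs


def call_stages(
    probs: np.ndarray,
    grid: TimeGrid | None = None,
    embryo_id: str = "",
    group: str = "",
) -> TimelineSeries:
    """Assign each frame its argmax stage; ties break to the earlier stage."""
    probs = _validate_probs(probs)
    grid = grid or TimeGrid()
    calls = [
        StageCall(
            index=i,
            time_min=grid.time_of(i),
            probs=probs[i],
            called_stage=StageLabel(int(np.argmax(probs[i]))),
        )
        for i in range(probs.shape[0])
    ]
    return TimelineSeries(calls=calls, grid=grid, embryo_id=embryo_id, group=group)


def detect_misclassifications(series: TimelineSeries) -> TimelineSeries:
    """Flag frames whose calls interrupt a continuous single-stage run.

    A frame is *isolated* when its two neighbours share a stage different
    from its own (the correction target is recorded immediately); a
    maximal run of >=2 identical calls flanked on both sides by one
    common different stage is *consecutive*.  The first and last frames
    have no two-sided context and are never flagged.
    """
    n = len(series)
    for c in series.calls:
        c.flag = Flag.CLEAN
        c.corrected_stage = None
    if n < 3:
        warnings.warn("series shorter than 3 frames: no flags set", stacklevel=2)
        return series
    s = series.called()
    # run-length encode the calls
    runs: list[tuple[StageLabel, int, int]] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or s[i] != s[i - 1]:
            runs.append((s[start], start, i - 1))
            start = i
    for k, (stage, a, b) in enumerate(runs):
        if k == 0 or k == len(runs) - 1:
            continue  # touches a series end: no two-sided context
        prev_stage = runs[k - 1][0]
        next_stage = runs[k + 1][0]
        if prev_stage != next_stage or prev_stage == stage:
            continue
        if a == b:
            series.calls[a].flag = Flag.ISOLATED
            series.calls[a].corrected_stage = prev_stage
        else:
            for i in range(a, b + 1):
                series.calls[i].flag = Flag.CONSECUTIVE
    return series


def apply_corrections(
    series: TimelineSeries, enabled: bool = True
) -> tuple[TimelineSeries, MisclassificationReport]:
    """Resolve flagged frames and tally them.

    Isolated misclassifications take the flanking stage (already recorded
    by detection).  Consecutive runs are never corrected; instead the
    stage they interrupt joins ``excluded_stages`` so that this embryo
    drops out of that stage's group statistics.  ``enabled=False``
    reproduces the no-correction sensitivity mode: the report is still
    computed but corrections are cleared, so downstream durations use the
    raw calls.
    """
    report, hosts = _tally_flags(series)
    series.excluded_stages |= hosts
    if not enabled:
        for c in series.calls:
            if c.flag is Flag.ISOLATED:
                c.flag = Flag.CLEAN
                c.corrected_stage = None
    return series, report


def _tally_flags(
    series: TimelineSeries,
) -> tuple[MisclassificationReport, set[StageLabel]]:
    """Tally current flags; returns the report and the stages hosting
    consecutive runs (candidates for exclusion from statistics)."""
    report = MisclassificationReport(total_frames=len(series))
    hosts: set[StageLabel] = set()
    s = series.called()
    i = 0
    n = len(series)
    while i < n:
        c = series.calls[i]
        if c.flag is Flag.ISOLATED:
            host = c.corrected_stage
            report.n_isolated += 1
            report.per_stage[host] = report.per_stage.get(host, 0) + 1
            i += 1
        elif c.flag is Flag.CONSECUTIVE:
            j = i
            while (
                j + 1 < n
                and series.calls[j + 1].flag is Flag.CONSECUTIVE
                and s[j + 1] == s[i]
            ):
                j += 1
            host = s[i - 1]  # run is interior by construction
            report.n_consecutive_runs += 1
            report.n_consecutive_frames += j - i + 1
            report.per_stage[host] = report.per_stage.get(host, 0) + (j - i + 1)
            hosts.add(host)
            i = j + 1
        else:
            i += 1
    return report, hosts


def _alternating_window(
    calls: list[StageLabel], left: int, pair: set[StageLabel]
) -> tuple[int, int] | None:
    """Maximal stretch around the boundary (left, left+1) where consecutive
    calls differ and all calls belong to ``pair``; None if the seed pair
    does not alternate."""
    n = len(calls)
    right = left + 1
    if calls[left] == calls[right]:
        return None
    if calls[left] not in pair or calls[right] not in pair:
        return None
    a, b = left, right
    while a - 1 >= 0 and calls[a - 1] in pair and calls[a - 1] != calls[a]:
        a -= 1
    while b + 1 < n and calls[b + 1] in pair and calls[b + 1] != calls[b]:
        b += 1
    return a, b


def identify_transitions(
    series: TimelineSeries, theta_mixed: float = 0.6, osc_min_len: int = 2
) -> TimelineSeries:
    """Mark transition frames at each boundary between adjacent stages.

    At each boundary from stage s to its developmental successor s', the
    frames around the boundary are checked first for the oscillation
    pattern (argmax alternating between s and s', with at least one
    reversal) on the *original* calls, then for the mixed pattern (no
    stage reaching ``theta_mixed`` and the top-two stages being exactly
    {s, s'}).  Misclassification flags inside a recognised window are
    revoked.  A jump to a non-successor stage is tagged anomalous and
    claims no frames.
    """
    if not (0.5 < theta_mixed <= 1.0):
        raise ValueError("theta_mixed must lie in (0.5, 1]")
    series.boundary_tags = []
    for c in series.calls:
        c.is_transition = False
        c.transition_boundary = None
    eff = series.effective(use_corrections=True)
    orig = series.called()
    n = len(series)
    # boundaries between effective-stage segments
    for i in range(n - 1):
        if eff[i] == eff[i + 1]:
            continue
        s, s2 = eff[i], eff[i + 1]
        if s.successor() is not s2:
            series.boundary_tags.append(BoundaryTag(i, s, s2, "anomalous"))
            continue
        pair = {s, s2}
        boundary = (s, s2)
        win = _alternating_window(orig, i, pair)
        tagged = False
        if win is not None:
            a, b = win
            seen_later = False
            reversal = False
            for k in range(a, b + 1):
                if orig[k] == s2:
                    seen_later = True
                elif orig[k] == s and seen_later:
                    reversal = True
                    break
            if reversal and (b - a + 1) >= osc_min_len:
                for k in range(a, b + 1):
                    c = series.calls[k]
                    c.is_transition = True
                    c.transition_boundary = boundary
                    if c.flag is not Flag.CLEAN:
                        c.flag = Flag.CLEAN
                        c.corrected_stage = None
                series.boundary_tags.append(BoundaryTag(i, s, s2, "oscillation"))
                tagged = True
        if not tagged:
            def is_mixed(k: int) -> bool:
                p = series.calls[k].probs
                top2 = np.argsort(p)[-2:]
                return float(p.max()) < theta_mixed and {
                    StageLabel(int(top2[0])), StageLabel(int(top2[1]))
                } == pair

            marked = []
            k = i
            while k >= 0 and is_mixed(k):
                marked.append(k)
                k -= 1
            k = i + 1
            while k < n and is_mixed(k):
                marked.append(k)
                k += 1
            if marked:
                for k in marked:
                    c = series.calls[k]
                    c.is_transition = True
                    c.transition_boundary = boundary
                series.boundary_tags.append(BoundaryTag(i, s, s2, "mixed"))
            else:
                series.boundary_tags.append(BoundaryTag(i, s, s2, "none"))
    return series


def compute_durations(
    series: TimelineSeries, use_corrections: bool = True, warn_missing: bool = False
) -> StageDurationTable:
    """Stage and transition durations in minutes for one embryo.

    A stage's duration counts its non-transition frames (corrected stage
    when set); each boundary's transition span counts the frames marked
    for it.  The table satisfies frame conservation: all stage spans plus
    all transition spans equal ``interval_min`` times the frame count.
    """
    dt = series.grid.interval_min
    durations = {stage: 0.0 for stage in ALL_STAGES}
    transitions: dict[tuple[StageLabel, StageLabel], float] = {}
    for c in series.calls:
        if c.is_transition:
            b = c.transition_boundary
            transitions[b] = transitions.get(b, 0.0) + dt
        else:
            durations[c.effective_stage(use_corrections)] += dt
    if warn_missing:
        for stage in EPIDERMAL_STAGES:
            if durations[stage] == 0.0:
                warnings.warn(
                    f"stage {stage.display_name!r} absent from series "
                    f"{series.embryo_id!r}: duration 0",
                    stacklevel=2,
                )
    table = StageDurationTable(
        embryo_id=series.embryo_id,
        group=series.group,
        durations_min=durations,
        transitions_min=transitions,
        excluded_stages=set(series.excluded_stages),
        interval_min=dt,
        n_frames=len(series),
    )
    table.check_conservation()
    return table


def analyze_series(
    probs: np.ndarray,
    grid: TimeGrid | None = None,
    embryo_id: str = "",
    group: str = "",
    theta_mixed: float = 0.6,
    osc_min_len: int = 2,
    correct: bool = True,
) -> tuple[TimelineSeries, StageDurationTable, MisclassificationReport]:
    """Full decoding chain: call -> flag -> correct -> transitions -> durations."""
    series = call_stages(probs, grid, embryo_id=embryo_id, group=group)
    if len(series) >= 3:
        detect_misclassifications(series)
    # corrections are always *recorded* so misclassifications stay countable;
    # correct=False only stops them from entering the durations
    series, _ = apply_corrections(series, enabled=True)
    identify_transitions(series, theta_mixed=theta_mixed, osc_min_len=osc_min_len)
    # transition windows may have revoked flags; re-tally for the final report
    report, hosts = _tally_flags(series)
    series.excluded_stages = hosts
    table = compute_durations(series, use_corrections=correct)
    return series, table, report


# ---------------------------------------------------------------------------
# I/O and plotting

_PROB_COLUMNS = [s.column_name for s in ALL_STAGES]


def series_to_frame(series: TimelineSeries) -> pd.DataFrame:
    """Timeline as a DataFrame (probabilities, calls, flags, transitions)."""
    rows = []
    for c in series.calls:
        row = {"frame": c.index, "time_min": c.time_min}
        row.update({col: c.probs[j] for j, col in enumerate(_PROB_COLUMNS)})
        row["called_stage"] = c.called_stage.name.lower()
        row["corrected_stage"] = (
            c.corrected_stage.name.lower() if c.corrected_stage is not None else ""
        )
        row["flag"] = c.flag.value
        row["is_transition"] = c.is_transition
        rows.append(row)
    return pd.DataFrame(rows)


def read_probability_csv(path: str | Path) -> tuple[np.ndarray, TimeGrid]:
    """Read a probability-table CSV (frame, time_min, p_before..p_fold2)."""
    df = pd.read_csv(path)
    missing = [c for c in _PROB_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing probability columns {missing}")
    probs = df[_PROB_COLUMNS].to_numpy(dtype=np.float64)
    if "time_min" in df.columns and len(df) >= 2:
        t = df["time_min"].to_numpy(dtype=np.float64)
        grid = TimeGrid(float(t[0]), float(t[1] - t[0]))
    else:
        grid = TimeGrid()
    return probs, grid


def write_timeline_csv(series: TimelineSeries, path: str | Path) -> Path:
    path = Path(path)
    series_to_frame(series).to_csv(path, index=False)
    return path


def plot_timeline(series: TimelineSeries, path: str | Path | None = None):
    """Stacked per-stage probability traces over developmental time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = ["black", "green", "gold", "deepskyblue", "purple", "navy"]
    t = [c.time_min for c in series.calls]
    fig, ax = plt.subplots(figsize=(9, 3))
    for stage, color in zip(ALL_STAGES, colors):
        ax.plot(
            t,
            [c.probs[stage.value] for c in series.calls],
            color=color,
            label=stage.display_name,
            lw=1.2,
        )
    for c in series.calls:
        if c.is_transition:
            ax.axvspan(
                c.time_min - series.grid.interval_min / 2,
                c.time_min + series.grid.interval_min / 2,
                color="grey",
                alpha=0.15,
                lw=0,
            )
    ax.set_xlabel("time post first cleavage (min)")
    ax.set_ylabel("stage probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7, ncol=3, loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
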