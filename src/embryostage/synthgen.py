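"""Seeded generators of synthetic embryo images and stage-probability series.

This module is the desk-scale test substrate for the whole pipeline: it
emulates the *structure* of the study data — an elliptical eggshell
containing a stage-distinctive embryo silhouette, the four background
noise categories seen around real embryos (neighbouring embryos, defocus
blur, bubbles, tissue debris), and per-frame stage-probability series
with stable runs, two transition patterns, and injected
misclassifications — without attempting photorealistic DIC rendering.
Stage motifs are geometric proxies; their only contract is inter-class
separability with intra-class variability.

Every output is reproducible byte-for-byte from its spec (which includes
a seed).  Probability rows are convex combinations of a clean target
distribution and a symmetric Dirichlet draw, giving realistic
non-degenerate softmax rows whose argmax and mixed/stable character are
preserved by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .stages import StageLabel, ALL_STAGES, N_STAGES, STAGE_DIR_NAMES
from .timeline import TimeGrid

__all__ = [
    "NOISE_CATEGORIES",
    "SynthImageSpec",
    "generate_embryo_image",
    "generate_seg_dataset",
    "generate_cls_dataset",
    "TransitionSpec",
    "SynthTimelineSpec",
    "SeriesTruth",
    "generate_probability_series",
    "random_timeline_spec",
    "write_probability_csv",
    "write_image_dataset",
    "manifest_hash",
]

NOISE_CATEGORIES = ("neighbor_embryo", "defocus_blur", "bubble", "debris")


# ---------------------------------------------------------------------------
# images


@dataclass(frozen=True)
class SynthImageSpec:
    """Recipe for one synthetic embryo frame.

    The eggshell is an ellipse (centre in pixels, semi-axes in pixels,
    rotation in degrees); the ground-truth mask is everything inside the
    eggshell's outer contour.  ``noise`` selects background-noise
    categories; ``intensity_noise_sd`` adds Gaussian texture inside the
    shell only.
    """

    size: int = 64
    stage: StageLabel = StageLabel.BEFORE_INTERCALATION
    center: tuple[float, float] | None = None  # (row, col); default frame centre
    axes: tuple[float, float] | None = None  # semi-axes (major, minor)
    rotation_deg: float = 0.0
    noise: frozenset[str] = frozenset()
    intensity_noise_sd: float = 0.02
    seed: int = 0

    def resolved(self) -> tuple[tuple[float, float], tuple[float, float]]:
        c = self.center or (self.size / 2.0, self.size / 2.0)
        a = self.axes or (0.42 * self.size, 0.30 * self.size)
        return c, a


def _ellipse_coords(spec: SynthImageSpec):
    """Ellipse-local coordinates: u along the major axis, v along the minor,
    both scaled so the shell contour is at radius r = 1."""
    (cy, cx), (a, b) = spec.resolved()
    yy, xx = np.mgrid[0 : spec.size, 0 : spec.size].astype(np.float64)
    th = np.deg2rad(spec.rotation_deg)
    dx, dy = xx - cx, yy - cy
    u = (np.cos(th) * dx + np.sin(th) * dy) / a
    v = (-np.sin(th) * dx + np.cos(th) * dy) / b
    r = np.hypot(u, v)
    return u, v, r


def _stage_motif(
    stage: StageLabel, u: np.ndarray, v: np.ndarray, r: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stage-distinctive interior texture in ellipse-local coordinates."""
    inner = r < 0.85
    tex = np.zeros_like(u)
    if stage is StageLabel.BEFORE_INTERCALATION:
        # granular field of undifferentiated cells
        noise = ndimage.gaussian_filter(rng.standard_normal(u.shape), 1.2)
        tex = np.where(inner & (noise > 0.25), 0.55, 0.0)
    elif stage is StageLabel.DORSAL_INTERCALATION:
        # interdigitating dorsal rows: bold stripes across the upper half
        stripes = np.sin(2 * np.pi * 3.0 * u) > 0.0
        tex = np.where(inner & (v < 0.1) & stripes, 0.68, 0.0)
    elif stage is StageLabel.VENTRAL_ENCLOSURE:
        # ventral pocket: bright arc hugging the lower interior edge
        tex = np.where((0.55 < r) & (r < 0.85) & (v > 0.15), 0.65, 0.0)
    elif stage is StageLabel.ROTATION:
        # comma silhouette: one thick curled tube with a prominent head blob
        r2 = np.hypot(u, v * 1.4)
        ring = (0.45 < r2) & (r2 < 0.78)
        gap = (np.arctan2(v, u) > 0.4) & (np.arctan2(v, u) < 1.4)
        head = np.hypot((u - 0.45) * 1.2, v - 0.35) < 0.3
        tex = np.where(inner & ((ring & ~gap) | head), 0.68, 0.0)
    elif stage is StageLabel.FOLD_1_5:
        # body folded once: two thick parallel tube segments
        bar1 = (np.abs(v - 0.4) < 0.2) & (np.abs(u) < 0.6)
        bar2 = (np.abs(v + 0.4) < 0.2) & (np.abs(u) < 0.6)
        tex = np.where(inner & (bar1 | bar2), 0.68, 0.0)
    elif stage is StageLabel.FOLD_2:
        # body folded twice and compacted: tube segments run across the
        # short axis, orthogonal to the 1.5-fold layout
        bar1 = (np.abs(u - 0.5) < 0.12) & (np.abs(v) < 0.75)
        bar2 = (np.abs(u) < 0.12) & (np.abs(v) < 0.85)
        bar3 = (np.abs(u + 0.5) < 0.12) & (np.abs(v) < 0.75)
        tex = np.where(inner & (bar1 | bar2 | bar3), 0.68, 0.0)
    return tex


def _add_noise_category(
    img: np.ndarray, category: str, mask: np.ndarray, spec: SynthImageSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    size = spec.size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    outside = mask == 0
    if category == "neighbor_embryo":
        # partial embryo poking in from a frame corner
        corner = rng.integers(4)
        cy = -0.1 * size if corner < 2 else 1.1 * size
        cx = -0.1 * size if corner % 2 == 0 else 1.1 * size
        a = 0.35 * size
        rr = np.hypot((yy - cy) / a, (xx - cx) / (0.7 * a))
        ring = np.exp(-(((rr - 1.0) / 0.08) ** 2)) * 0.7
        body = np.where(rr < 1.0, 0.3, 0.0)
        img = img + outside * (ring + body)
    elif category == "defocus_blur":
        img = ndimage.gaussian_filter(img, 1.5)
    elif category == "bubble":
        for _ in range(rng.integers(1, 3)):
            cy, cx = rng.uniform(0, size, 2)
            rad = rng.uniform(0.05, 0.12) * size
            rr = np.hypot(yy - cy, xx - cx) / rad
            ring = np.exp(-(((rr - 1.0) / 0.15) ** 2)) * 0.8
            img = img + outside * ring
    elif category == "debris":
        speck = rng.random(img.shape) > 0.995
        speck = ndimage.binary_dilation(speck, iterations=1)
        img = img + outside * speck * rng.uniform(0.4, 0.8)
    else:
        raise ValueError(f"unknown noise category {category!r}")
    return img


def generate_embryo_image(
    spec: SynthImageSpec,
) -> tuple[np.ndarray, np.ndarray, StageLabel]:
    """Render one synthetic frame; returns (image, ground-truth mask, stage).

    Deterministic: the same spec always yields bitwise-identical output.
    Raises if the eggshell ellipse does not fit inside the frame.
    """
    (cy, cx), (a, b) = spec.resolved()
    half_extent = max(a, b)
    if (
        cy - half_extent < -0.5
        or cx - half_extent < -0.5
        or cy + half_extent > spec.size - 0.5
        or cx + half_extent > spec.size - 0.5
    ):
        raise ValueError("eggshell ellipse exceeds the frame")
    rng = np.random.default_rng(spec.seed)
    u, v, r = _ellipse_coords(spec)
    mask = (r <= 1.0).astype(np.uint8)

    shell = np.exp(-(((r - 0.94) / 0.05) ** 2)) * 0.8
    interior = np.where(r < 0.9, 0.18, 0.0)
    img = np.where(mask > 0, shell + interior, 0.0)
    img = img + np.where(mask > 0, _stage_motif(spec.stage, u, v, r, rng), 0.0)
    if spec.intensity_noise_sd > 0:
        img = img + (mask > 0) * rng.normal(0.0, spec.intensity_noise_sd, img.shape)
    for category in sorted(spec.noise):
        img = _add_noise_category(img, category, mask, spec, rng)
    return np.clip(img, 0.0, 1.0), mask, spec.stage


#: Pose-jitter bound (degrees) for randomly generated specs.  Real embryos
#: are mounted in roughly consistent orientations but never perfectly, so
#: datasets jitter the eggshell rotation within this bound rather than
#: sampling arbitrary orientations.
ROTATION_JITTER_DEG = 25.0


def _random_spec(
    size: int, stage: StageLabel, noise: frozenset[str],
    rng: np.random.Generator,
) -> SynthImageSpec:
    a = rng.uniform(0.34, 0.42) * size
    b = rng.uniform(0.24, 0.30) * size
    margin = max(a, b)
    lo, hi = margin + 0.5, size - margin - 0.5
    if lo >= hi:
        cy = cx = size / 2.0
    else:
        cy, cx = rng.uniform(lo, hi, 2)
    return SynthImageSpec(
        size=size,
        stage=stage,
        center=(float(cy), float(cx)),
        axes=(float(a), float(b)),
        rotation_deg=float(rng.uniform(-ROTATION_JITTER_DEG, ROTATION_JITTER_DEG)),
        noise=noise,
        seed=int(rng.integers(2**31)),
    )


def generate_seg_dataset(
    n: int,
    size: int = 64,
    stage_mix: list[StageLabel] | None = None,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[np.ndarray, np.ndarray, StageLabel]], list[dict]]:
    """A reproducible segmentation dataset of n (image, mask, stage) items.

    Stages cycle through ``stage_mix`` (all six by default); each item
    independently receives one random noise category with probability
    ``noise_rate``.  The manifest records every spec.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    stage_mix = list(stage_mix or ALL_STAGES)
    rng = np.random.default_rng(seed)
    items, manifest = [], []
    for i in range(n):
        noise = (
            frozenset({str(rng.choice(NOISE_CATEGORIES))})
            if rng.random() < noise_rate
            else frozenset()
        )
        spec = _random_spec(size, stage_mix[i % len(stage_mix)], noise, rng)
        items.append(generate_embryo_image(spec))
        d = asdict(spec)
        d["stage"] = spec.stage.name
        d["noise"] = sorted(spec.noise)
        manifest.append(d)
    return items, manifest


def generate_cls_dataset(
    per_class: int,
    size: int = 64,
    noise_rate: float = 0.0,
    extracted: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Stage-labelled images for classifier training.

    With ``extracted=True`` (the pipeline's operating point) each image
    is multiplied by its ground-truth mask, emulating the segmentation
    step that zeroes the background before classification.
    Returns (images (N, size, size), labels (N,), manifest).
    """
    rng = np.random.default_rng(seed)
    images, labels, manifest = [], [], []
    for stage in ALL_STAGES:
        for _ in range(per_class):
            noise = (
                frozenset({str(rng.choice(NOISE_CATEGORIES))})
                if rng.random() < noise_rate
                else frozenset()
            )
            spec = _random_spec(size, stage, noise, rng)
            img, mask, _ = generate_embryo_image(spec)
            images.append(img * mask if extracted else img)
            labels.append(stage.value)
            d = asdict(spec)
            d["stage"] = spec.stage.name
            d["noise"] = sorted(spec.noise)
            manifest.append(d)
    return (
        np.stack(images),
        np.asarray(labels, dtype=np.int64),
        manifest,
    )


def manifest_hash(manifest: list[dict]) -> str:
    """Stable content hash of a dataset manifest."""
    return hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()


def write_image_dataset(
    items: list[tuple[np.ndarray, np.ndarray, StageLabel]],
    manifest: list[dict],
    out_dir: str | Path,
) -> Path:
    """Write a dataset in the stage-directory layout with LabelMe-style masks."""
    from .imaging import save_gray_image, save_mask_png

    out_dir = Path(out_dir)
    counters: dict[StageLabel, int] = {}
    for img, mask, stage in items:
        k = counters.get(stage, 0)
        counters[stage] = k + 1
        stage_dir = out_dir / STAGE_DIR_NAMES[stage]
        stage_dir.mkdir(parents=True, exist_ok=True)
        save_gray_image(img, stage_dir / f"{k:04d}.png")
        save_mask_png(mask, stage_dir / f"{k:04d}_mask.png")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"hash": manifest_hash(manifest), "items": manifest}, fh, indent=1)
    return out_dir


# ---------------------------------------------------------------------------
# probability series


@dataclass(frozen=True)
class TransitionSpec:
    """Transition period between two consecutive stage segments.

    ``pattern`` is ``none`` (hard switch, 0 frames), ``mixed`` (>=1
    frames where the two stages split the probability mass 40-60%), or
    ``oscillation`` (an even count >=4 of frames whose argmax alternates
    earlier, later, ..., ending on the later stage — the shortest shape
    that contains a reversal and hands the boundary over cleanly).
    """

    pattern: str = "none"
    n_frames: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in ("none", "mixed", "oscillation"):
            raise ValueError(f"unknown transition pattern {self.pattern!r}")
        if self.pattern == "none" and self.n_frames != 0:
            raise ValueError("'none' transitions have no frames")
        if self.pattern == "mixed" and self.n_frames < 1:
            raise ValueError("'mixed' transitions need >= 1 frame")
        if self.pattern == "oscillation" and (
            self.n_frames < 4 or self.n_frames % 2
        ):
            raise ValueError("'oscillation' transitions need an even count >= 4")


@dataclass(frozen=True)
class SynthTimelineSpec:
    """Recipe for one synthetic stage-probability series.

    ``segments`` lists (stage, n_frames) in strictly increasing stage
    order; ``transitions`` gives one TransitionSpec per inter-segment
    boundary (default: all hard switches).  ``isolated`` lists global
    frame indices to overwrite with a wrong high-confidence call;
    ``consecutive`` lists (start, length) runs.  ``kappa`` is the
    probability the true stage receives on stable frames;
    ``dirichlet_jitter`` is the weight of a symmetric Dirichlet draw
    mixed into every row.
    """

    segments: tuple[tuple[StageLabel, int], ...]
    transitions: tuple[TransitionSpec, ...] | None = None
    isolated: tuple[int, ...] = ()
    consecutive: tuple[tuple[int, int], ...] = ()
    kappa: float = 0.95
    dirichlet_jitter: float = 0.02
    seed: int = 0

    def resolved_transitions(self) -> tuple[TransitionSpec, ...]:
        n_b = len(self.segments) - 1
        if self.transitions is None:
            return tuple(TransitionSpec() for _ in range(n_b))
        if len(self.transitions) != n_b:
            raise ValueError(
                f"need {n_b} transition specs (one per boundary), "
                f"got {len(self.transitions)}"
            )
        return self.transitions

    @property
    def n_frames(self) -> int:
        return sum(n for _, n in self.segments) + sum(
            t.n_frames for t in self.resolved_transitions()
        )


@dataclass
class SeriesTruth:
    """Ground truth accompanying a generated probability series."""

    true_stage: list[StageLabel | None]  # None on transition frames
    is_transition: np.ndarray
    boundary_patterns: list[tuple[tuple[StageLabel, StageLabel], str]]
    isolated_indices: list[int]
    consecutive_runs: list[tuple[int, int]]
    durations_min: dict[StageLabel, float]
    transitions_min: dict[tuple[StageLabel, StageLabel], float]


def _clean_row(stage: StageLabel, kappa: float) -> np.ndarray:
    row = np.full(N_STAGES, (1.0 - kappa) / (N_STAGES - 1))
    row[stage.value] = kappa
    return row


def _mixed_row(s: StageLabel, s2: StageLabel, u: float) -> np.ndarray:
    """Two stages share 98% of the mass (u to s, rest to s2)."""
    row = np.full(N_STAGES, 0.02 / (N_STAGES - 2))
    row[s.value] = u
    row[s2.value] = 0.98 - u
    return row


def generate_probability_series(
    spec: SynthTimelineSpec, grid: TimeGrid | None = None
) -> tuple[np.ndarray, SeriesTruth]:
    """Build a probability table plus ground truth from a timeline recipe.

    Stable frames put ``kappa`` on the true stage; mixed-transition
    frames split 40-60% across the boundary stages with the argmax
    handed over monotonically; oscillation frames alternate a
    high-confidence argmax between the two stages.  Injected
    misclassifications replace a stable frame's argmax with a wrong
    high-confidence stage.  Every row sums to 1.
    """
    grid = grid or TimeGrid()
    stages = [s for s, _ in spec.segments]
    if any(b <= a for a, b in zip(stages, stages[1:])):
        raise ValueError("segment stages must be strictly increasing")
    if any(n < 1 for _, n in spec.segments):
        raise ValueError("segments need >= 1 frame")
    transitions = spec.resolved_transitions()
    rng = np.random.default_rng(spec.seed)

    rows: list[np.ndarray] = []
    true_stage: list[StageLabel | None] = []
    is_transition: list[bool] = []
    boundary_patterns = []
    seg_spans: list[tuple[int, int, StageLabel]] = []  # [start, end) stable spans
    trans_min: dict[tuple[StageLabel, StageLabel], float] = {}

    for k, (stage, n) in enumerate(spec.segments):
        start = len(rows)
        for _ in range(n):
            rows.append(_clean_row(stage, spec.kappa))
            true_stage.append(stage)
            is_transition.append(False)
        seg_spans.append((start, len(rows), stage))
        if k < len(transitions):
            t = transitions[k]
            s, s2 = stage, spec.segments[k + 1][0]
            boundary = (s, s2)
            if t.pattern != "none":
                boundary_patterns.append((boundary, t.pattern))
                trans_min[boundary] = grid.interval_min * t.n_frames
            if t.pattern == "mixed":
                us = np.linspace(0.55, 0.43, t.n_frames)
                for u in us:
                    rows.append(_mixed_row(s, s2, float(u)))
                    true_stage.append(None)
                    is_transition.append(True)
            elif t.pattern == "oscillation":
                for j in range(t.n_frames):
                    osc_stage = s if j % 2 == 0 else s2
                    rows.append(_clean_row(osc_stage, spec.kappa))
                    true_stage.append(None)
                    is_transition.append(True)

    n_total = len(rows)
    probs = np.stack(rows)

    # ---- injected misclassifications ------------------------------------
    def span_of(idx: int) -> tuple[int, int, StageLabel]:
        for a, b, stage in seg_spans:
            if a <= idx < b:
                return a, b, stage
        raise ValueError(f"index {idx} is not inside a stable segment")

    taken: set[int] = set()

    def claim(indices: list[int]) -> None:
        # injections keep >= 2 clean frames between each other so that
        # flanking runs stay unambiguous for the window rule
        for idx in indices:
            if taken & set(range(idx - 2, idx + 3)):
                raise ValueError("overlapping injection positions")
        taken.update(indices)

    isolated_sorted = sorted(spec.isolated)
    for idx in isolated_sorted:
        a, b, stage = span_of(idx)
        if idx < a + 2 or idx > b - 3:
            raise ValueError(
                f"isolated injection at {idx} needs two stable same-stage "
                "frames on both sides"
            )
        claim([idx])
        wrong = _wrong_stage(stage, rng)
        probs[idx] = _clean_row(wrong, spec.kappa)

    for start, length in spec.consecutive:
        if length < 2:
            raise ValueError("consecutive runs need length >= 2")
        a, b, stage = span_of(start)
        end = start + length - 1
        if start < a + 2 or end > b - 3:
            raise ValueError(
                f"consecutive run [{start}, {end}] needs two stable frames "
                "on both sides within its segment"
            )
        claim(list(range(start, end + 1)))
        wrong = _wrong_stage(stage, rng)
        for idx in range(start, end + 1):
            probs[idx] = _clean_row(wrong, spec.kappa)

    # ---- Dirichlet jitter ------------------------------------------------
    if spec.dirichlet_jitter > 0:
        lam = spec.dirichlet_jitter
        noise = rng.dirichlet(np.ones(N_STAGES), size=n_total)
        probs = (1.0 - lam) * probs + lam * noise
    probs /= probs.sum(axis=1, keepdims=True)

    durations = {
        stage: 0.0 for stage in ALL_STAGES
    }
    for stage, n in spec.segments:
        durations[stage] += grid.interval_min * n
    truth = SeriesTruth(
        true_stage=true_stage,
        is_transition=np.asarray(is_transition, dtype=bool),
        boundary_patterns=boundary_patterns,
        isolated_indices=isolated_sorted,
        consecutive_runs=sorted(spec.consecutive),
        durations_min=durations,
        transitions_min=trans_min,
    )
    return probs, truth


def random_timeline_spec(
    rng: np.random.Generator,
    p_isolated: float = 0.5,
    p_consecutive: float = 0.15,
) -> SynthTimelineSpec:
    """Draw a random valid timeline recipe (for property-style testing).

    Picks a run of consecutive stages with random segment lengths and
    transition patterns, then injects 0-2 isolated misclassifications
    (and occasionally one consecutive run) at positions satisfying the
    generator's spacing constraints.
    """
    k = int(rng.integers(2, 6))
    start = int(rng.integers(0, N_STAGES - k + 1))
    stages = [StageLabel(start + j) for j in range(k)]
    segments = tuple((s, int(rng.integers(4, 12))) for s in stages)
    transitions = []
    for _ in range(k - 1):
        pat = str(rng.choice(["none", "mixed", "oscillation"], p=[0.4, 0.4, 0.2]))
        if pat == "none":
            transitions.append(TransitionSpec())
        elif pat == "mixed":
            transitions.append(TransitionSpec("mixed", int(rng.integers(1, 4))))
        else:
            transitions.append(
                TransitionSpec("oscillation", int(rng.choice([4, 6])))
            )
    transitions = tuple(transitions)

    # stable-segment spans in the assembled series
    spans = []
    pos = 0
    for j, (s, n) in enumerate(segments):
        spans.append((pos, pos + n))
        pos += n
        if j < len(transitions):
            pos += transitions[j].n_frames
    total = pos

    taken: set[int] = set()
    isolated = []
    if rng.random() < p_isolated:
        for _ in range(int(rng.integers(1, 3))):
            a, b = spans[int(rng.integers(len(spans)))]
            lo, hi = a + 2, b - 3
            if hi < lo:
                continue
            idx = int(rng.integers(lo, hi + 1))
            if taken & set(range(idx - 2, idx + 3)):
                continue
            taken.add(idx)
            isolated.append(idx)
    consecutive = []
    if rng.random() < p_consecutive:
        a, b = spans[int(rng.integers(len(spans)))]
        lo, hi = a + 2, b - 4  # run of 2 must end by b - 3
        if hi >= lo:
            s0 = int(rng.integers(lo, hi + 1))
            if not taken & set(range(s0 - 2, s0 + 4)):
                consecutive.append((s0, 2))

    return SynthTimelineSpec(
        segments=segments and tuple(segments),
        transitions=transitions,
        isolated=tuple(sorted(isolated)),
        consecutive=tuple(consecutive),
        seed=int(rng.integers(2**31)),
    )


def _wrong_stage(stage: StageLabel, rng: np.random.Generator) -> StageLabel:
    choices = [s for s in ALL_STAGES if s is not stage]
    return choices[int(rng.integers(len(choices)))]


def write_probability_csv(
    probs: np.ndarray, path: str | Path, grid: TimeGrid | None = None
) -> Path:
    """Write a probability table in the timeline CSV schema."""
    import pandas as pd

    grid = grid or TimeGrid()
    n = probs.shape[0]
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_min": [grid.time_of(i) for i in range(n)],
        }
    )
    for stage in ALL_STAGES:
        df[stage.column_name] = probs[:, stage.value]
    path = Path(path)
    df.to_csv(path, index=False)
    return path
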