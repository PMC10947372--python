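"""Synthetic depth scenes and synthetic cohorts.

Every downstream stage of the pipeline (motion detection, event
featurization, classification, statistics) is testable without clinical
recordings through two generators:

* a *scene* generator that builds a hypnogram, plants ground-truth movement
  events inside REM sleep as per-region Poisson processes, renders a depth
  video of a sleeping body (bed plane, raised body silhouette, sinusoidal
  chest respiration, per-event patch displacement, sensor noise) and emits
  head/hand detector tracks with realistic dropouts;

* a *cohort* generator that draws per-subject movement-feature tables from
  zero-inflated log-normal distributions quantile-matched to group-level
  medians and interquartile ranges of a clinical v-PSG cohort (53 iRBD vs
  128 no-RBD subjects), including subgroup structure and a per-subject RWA
  (SINBAR) index.

The cohort path is the default desk-scale route for exercising the
classifier; the video path is exercised on short clips.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .depthio import DepthSequence, Hypnogram, ROILayout, TrackSet, rem_hours, rem_intervals

__all__ = [
    "SceneConfig",
    "PlantedEvent",
    "CellSpec",
    "GroupSpec",
    "CohortSpec",
    "default_layout",
    "generate_hypnogram",
    "plant_events",
    "render_depth_video",
    "sample_cohort_features",
    "default_cohort_spec",
    "FEATURE_COLUMNS",
    "IRBD_REFERENCE_CELLS",
    "NO_RBD_REFERENCE_CELLS",
]

DURATION_BIN_NAMES = ("short", "medium", "long")

#: wide-format feature column names: ``{roi}_{bin}_{rate|ratio}``
FEATURE_COLUMNS = tuple(
    f"{roi}_{b}_{feat}"
    for roi in ("HE", "HAs", "UB", "LB")
    for b in DURATION_BIN_NAMES
    for feat in ("rate", "ratio")
)


# ---------------------------------------------------------------------------
# scene configuration


def default_layout(width: int, height: int) -> ROILayout:
    """Static upper/lower-body polygons for a bed viewed from the ceiling.

    The body occupies the central column of the frame; the upper-body region
    spans shoulders to hip, the lower-body region hip to feet.
    """
    w, h = float(width), float(height)
    upper = np.array(
        [[0.25 * w, 0.08 * h], [0.75 * w, 0.08 * h], [0.75 * w, 0.50 * h], [0.25 * w, 0.50 * h]]
    )
    lower = np.array(
        [[0.30 * w, 0.55 * h], [0.70 * w, 0.55 * h], [0.70 * w, 0.95 * h], [0.30 * w, 0.95 * h]]
    )
    return ROILayout({"upper_body": upper, "lower_body": lower})


def _frac_box(width: int, height: int, fx0, fy0, fx1, fy1) -> tuple[int, int, int, int]:
    x0, y0 = int(round(fx0 * width)), int(round(fy0 * height))
    x1, y1 = int(round(fx1 * width)), int(round(fy1 * height))
    return x0, y0, max(x1 - x0, 1), max(y1 - y0, 1)


@dataclass
class SceneConfig:
    """Geometry and physics of the rendered depth scene.

    Depths are millimetres from the sensor; the body sits
    ``body_depth_offset`` closer to the camera than the bed plane, the chest
    patch oscillates sinusoidally with respiration and each planted movement
    raises its region patch by ``event_displacement`` for its duration.
    ``track_dropout_prob`` is the per-frame probability that the external
    head/hand detector misses a box (the default reproduces the ~41.6 %
    hands-detection coverage seen with the real detector).
    """

    frame_width: int = 512
    frame_height: int = 424
    fps: float = 30.0
    bed_depth: float = 2000.0
    body_depth_offset: float = 300.0
    respiration_amplitude: float = 4.0
    respiration_freq: float = 0.25
    noise_sigma: float = 5.0
    event_displacement: float = 50.0
    roi_geometry: ROILayout | None = None
    track_dropout_prob: float = 0.584

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0.05 < self.respiration_freq < 1.0:
            raise ValueError("respiration_freq must lie in (0.05, 1.0) Hz")
        if not 0.0 <= self.track_dropout_prob <= 1.0:
            raise ValueError("track_dropout_prob must lie in [0, 1]")
        if self.roi_geometry is None:
            self.roi_geometry = default_layout(self.frame_width, self.frame_height)

    # fixed scene anatomy, as (x, y, w, h) pixel boxes -----------------------

    @property
    def head_box(self) -> tuple[int, int, int, int]:
        return _frac_box(self.frame_width, self.frame_height, 0.42, 0.10, 0.58, 0.22)

    @property
    def hand_boxes(self) -> list[tuple[int, int, int, int]]:
        return [
            _frac_box(self.frame_width, self.frame_height, 0.26, 0.30, 0.36, 0.42),
            _frac_box(self.frame_width, self.frame_height, 0.64, 0.30, 0.74, 0.42),
        ]

    @property
    def chest_box(self) -> tuple[int, int, int, int]:
        return _frac_box(self.frame_width, self.frame_height, 0.40, 0.26, 0.60, 0.42)

    def event_patch(self, roi: str) -> tuple[int, int, int, int]:
        """Pixel box displaced when a movement event is active in ``roi``."""
        if roi == "HE":
            return self.head_box
        if roi == "HAs":
            return self.hand_boxes[0]
        if roi == "UB":
            # trunk area clear of head/hand boxes and the oscillating chest
            return _frac_box(self.frame_width, self.frame_height, 0.30, 0.43, 0.70, 0.50)
        if roi == "LB":
            return _frac_box(self.frame_width, self.frame_height, 0.34, 0.60, 0.66, 0.85)
        raise ValueError(f"unknown roi '{roi}'")


@dataclass
class PlantedEvent:
    """Ground truth for one simulated movement."""

    roi: str
    start_s: float
    end_s: float
    in_rem: bool = True
    bin: str | None = None

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# hypnogram generation


def generate_hypnogram(
    total_min: float,
    rem_fraction: float,
    n_rem_periods: int = 4,
    seed: int | np.random.Generator | None = 0,
) -> Hypnogram:
    """Generate a 30-s-epoch hypnogram with grouped REM periods.

    Total R time lands within one epoch of ``total_min * rem_fraction`` and
    the R epochs form ``n_rem_periods`` contiguous blocks separated by NREM
    (or wake).  NREM stages are drawn i.i.d. with plausible stage
    proportions.
    """
    if total_min < 30:
        raise ValueError("total_min must be at least 30 minutes")
    if not 0.0 <= rem_fraction <= 0.5:
        raise ValueError("rem_fraction must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    n_epochs = int(round(total_min * 2))
    n_rem = int(round(n_epochs * rem_fraction))
    if n_rem == 0:
        n_rem_periods = 0
    elif n_rem_periods < 1:
        raise ValueError("n_rem_periods must be >= 1 when rem_fraction > 0")
    n_nrem = n_epochs - n_rem
    # each REM block needs a preceding non-REM separator (blocks never touch)
    if n_rem_periods > 0 and n_nrem < n_rem_periods:
        raise ValueError(
            f"infeasible: {n_rem_periods} REM periods do not fit in a "
            f"{total_min:g}-min night at rem_fraction={rem_fraction:g}"
        )
    if n_rem_periods and n_rem < n_rem_periods:
        raise ValueError("fewer REM epochs than requested REM periods")

    nrem_stages = rng.choice(
        ["W", "N1", "N2", "N3"], size=n_nrem, p=[0.08, 0.10, 0.52, 0.30]
    )
    if n_rem_periods == 0:
        return Hypnogram(tuple(nrem_stages))

    base, extra = divmod(n_rem, n_rem_periods)
    block_sizes = [base + (1 if i < extra else 0) for i in range(n_rem_periods)]
    # split the NREM epochs into n_rem_periods leading gaps (each >= 1) plus
    # an optional tail after the final REM period
    cuts = rng.multinomial(n_nrem - n_rem_periods, np.ones(n_rem_periods + 1) / (n_rem_periods + 1))
    gaps = [int(c) + 1 for c in cuts[:-1]]
    stages: list[str] = []
    pos = 0
    for gap, size in zip(gaps, block_sizes):
        stages.extend(nrem_stages[pos : pos + gap])
        pos += gap
        stages.extend(["R"] * size)
    stages.extend(nrem_stages[pos:])
    return Hypnogram(tuple(stages))


# ---------------------------------------------------------------------------
# event planting

#: durations drawn for planted events, kept clear of the duration-bin edges
#: so a +/-1-frame detection jitter cannot flip an event into another bin
DEFAULT_DURATION_RANGES = {"short": (0.2, 1.5), "medium": (2.5, 10.0), "long": (16.0, 60.0)}


def plant_events(
    hypnogram: Hypnogram,
    roi_rates: dict[tuple[str, str], float],
    duration_ranges: dict[str, tuple[float, float]] | None = None,
    min_gap_s: float = 2.0,
    seed: int | np.random.Generator | None = 0,
) -> list[PlantedEvent]:
    """Plant movement events as homogeneous Poisson processes within REM.

    ``roi_rates`` maps ``(roi, duration_bin)`` to an intensity in events per
    hour of REM sleep.  Durations are drawn log-uniformly inside the bin's
    range; events of the same region are separated by more than
    ``min_gap_s`` so they can never be merged by the 1-s merge rule.
    """
    if min_gap_s <= 1.0:
        raise ValueError("min_gap_s must exceed the 1-s merge gap")
    if any(r < 0 for r in roi_rates.values()):
        raise ValueError("rates must be non-negative")
    duration_ranges = dict(DEFAULT_DURATION_RANGES, **(duration_ranges or {}))
    rng = np.random.default_rng(seed)
    intervals = rem_intervals(hypnogram)
    rem_s = sum(e - s for s, e in intervals)
    rem_h = rem_s / 3600.0
    if rem_h == 0 and any(r > 0 for r in roi_rates.values()):
        raise ValueError("hypnogram has no REM sleep to plant events in")

    events: list[PlantedEvent] = []
    rois = sorted({roi for roi, _ in roi_rates})
    for roi in rois:
        # feasibility: expected occupancy including gaps must leave headroom
        load = sum(
            roi_rates[(r, b)] * (np.mean(duration_ranges[b]) + min_gap_s)
            for r, b in roi_rates
            if r == roi
        )
        if load * rem_h > 0.8 * rem_s:
            raise ValueError(f"requested intensity for '{roi}' too high to respect min_gap")
        wanted: list[tuple[float, str]] = []
        for (r, b), rate in roi_rates.items():
            if r != roi or rate == 0:
                continue
            n = rng.poisson(rate * rem_h)
            lo, hi = duration_ranges[b]
            durs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
            wanted.extend((float(d), b) for d in durs)
        # place longest first: each event keeps the drawn Poisson count, only
        # its position is re-drawn on a min_gap collision
        wanted.sort(reverse=True)
        placed: list[tuple[float, float, str]] = []
        starts: list[float] = []
        for d, b in wanted:
            spans = np.array([max(e - s - d, 0.0) for s, e in intervals])
            if spans.sum() <= 0:
                raise ValueError(f"event of {d:.1f} s does not fit any REM interval")
            for _ in range(500):
                k = rng.choice(len(intervals), p=spans / spans.sum())
                s0 = float(rng.uniform(intervals[k][0], intervals[k][1] - d))
                j = bisect.bisect_left(starts, s0)
                left_ok = j == 0 or s0 - placed[j - 1][1] > min_gap_s
                right_ok = j == len(placed) or placed[j][0] - (s0 + d) > min_gap_s
                if left_ok and right_ok:
                    starts.insert(j, s0)
                    placed.insert(j, (s0, s0 + d, b))
                    break
            else:
                raise ValueError(
                    f"could not place events for '{roi}' with min_gap={min_gap_s}"
                )
        events.extend(PlantedEvent(roi, s, e, in_rem=True, bin=b) for s, e, b in placed)
    events.sort(key=lambda ev: (ev.start_s, ev.roi))
    return events


# ---------------------------------------------------------------------------
# rendering


def render_depth_video(
    planted: list[PlantedEvent],
    hypnogram: Hypnogram,
    scene: SceneConfig,
    seed: int | np.random.Generator | None = 0,
) -> tuple[DepthSequence, TrackSet]:
    """Render a depth video plus head/hand tracks for a planted-event night.

    The rendered scene is deterministic given the seed: the bed plane sits at
    ``bed_depth``, the body silhouette at ``bed_depth - body_depth_offset``,
    the chest patch oscillates sinusoidally, active events raise their
    region's patch by ``event_displacement`` and white sensor noise of
    ``noise_sigma`` mm is added per pixel.
    """
    rng = np.random.default_rng(seed)
    w, h = scene.frame_width, scene.frame_height
    fps = scene.fps
    n_frames = int(round(hypnogram.total_s * fps))
    layout = scene.roi_geometry

    base = np.full((h, w), scene.bed_depth, dtype=np.float64)
    body = layout.mask("upper_body", (h, w)) | layout.mask("lower_body", (h, w))
    base[body] = scene.bed_depth - scene.body_depth_offset
    for x, y, bw, bh in [scene.head_box, *scene.hand_boxes]:
        base[y : y + bh, x : x + bw] = scene.bed_depth - scene.body_depth_offset

    cx, cy, cw, ch = scene.chest_box
    # the chest is not a rigid plate: excursion peaks at the sternum and
    # tapers to the patch edge (raised-cosine profile), so pixels cross a
    # detector threshold at staggered times rather than all at once
    yy, xx = np.mgrid[0:ch, 0:cw]
    chest_profile = (
        np.sin(np.pi * (yy + 0.5) / ch) * np.sin(np.pi * (xx + 0.5) / cw)
    )
    patches: dict[str, tuple[int, int, int, int]] = {}
    for roi in ("HE", "HAs", "UB", "LB"):
        x, y, bw, bh = scene.event_patch(roi)
        if x < 0 or y < 0 or x + bw > w or y + bh > h:
            raise ValueError(f"event patch for '{roi}' lies outside the frame")
        patches[roi] = (x, y, bw, bh)

    # frame index ranges of active events, per roi
    active: dict[str, list[tuple[int, int]]] = {roi: [] for roi in patches}
    for ev in planted:
        if ev.roi not in patches:
            raise ValueError(f"unknown event roi '{ev.roi}'")
        f0, f1 = int(round(ev.start_s * fps)), int(round(ev.end_s * fps))
        if f0 < 0 or f1 > n_frames:
            raise ValueError("event lies outside the rendered time span")
        active[ev.roi].append((f0, f1))

    frames = np.empty((n_frames, h, w), dtype=np.uint16)
    t = np.arange(n_frames) / fps
    resp = scene.respiration_amplitude * np.sin(2 * np.pi * scene.respiration_freq * t)
    for i in range(n_frames):
        frame = base.copy()
        if scene.respiration_amplitude:
            frame[cy : cy + ch, cx : cx + cw] -= resp[i] * chest_profile
        for roi, spans in active.items():
            for f0, f1 in spans:
                if f0 <= i < f1:
                    # a moving limb keeps changing depth frame to frame: the
                    # patch wobbles between the full and half displacement so
                    # consecutive-frame differencing sees the whole event
                    disp = scene.event_displacement * (1.0 if (i - f0) % 2 == 0 else 0.5)
                    x, y, bw, bh = patches[roi]
                    frame[y : y + bh, x : x + bw] -= disp
                    break
        if scene.noise_sigma:
            frame += rng.normal(0.0, scene.noise_sigma, size=(h, w))
        np.clip(frame, 0, 8000, out=frame)
        frames[i] = np.rint(frame).astype(np.uint16)

    rows = []
    keep = 1.0 - scene.track_dropout_prob
    head_valid = rng.random(n_frames) < keep
    hand_valid = rng.random((n_frames, 2)) < keep
    hx, hy, hw_, hh = scene.head_box
    for i in range(n_frames):
        rows.append((i, "head", hx, hy, hw_, hh, bool(head_valid[i])))
        for j, (x, y, bw, bh) in enumerate(scene.hand_boxes):
            rows.append((i, "hand", x, y, bw, bh, bool(hand_valid[i, j])))
    tracks = TrackSet(pd.DataFrame(rows, columns=list(TrackSet.COLUMNS)))
    return DepthSequence(frames, fps=fps), tracks


# ---------------------------------------------------------------------------
# cohort sampling

_Z75 = norm.ppf(0.75)  # 0.67449, the 75th-percentile standard-normal quantile


@dataclass
class CellSpec:
    """Zero-inflated log-normal spec for one feature cell.

    A draw is exactly zero with probability ``zero_inflation`` and otherwise
    log-normal.  With no zero inflation the log-normal is quantile-matched to
    the printed median and quartiles: location ``ln(median)``, scale
    ``ln(q75/q25) / (2 * 0.67449)``.  Cells whose printed q25 or median is 0
    use the positive quantiles that remain (see docs/methods.md).
    """

    median: float
    q25: float
    q75: float
    zero_inflation: float | None = None

    def __post_init__(self) -> None:
        if not self.q25 <= self.median <= self.q75:
            raise ValueError("quartiles must satisfy q25 <= median <= q75")
        if self.zero_inflation is None:
            if self.median == 0:
                self.zero_inflation = 0.6
            elif self.q25 == 0:
                self.zero_inflation = 0.25
            else:
                self.zero_inflation = 0.0
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.median == 0 and self.zero_inflation < 0.5:
            raise ValueError(
                "a log-normal cannot reach median 0: cells with printed median 0 "
                "need zero_inflation >= 0.5"
            )

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the log-normal component."""
        z = self.zero_inflation
        if z >= 1.0:
            return 0.0, 0.0

        def cond_q(p: float) -> float:
            # quantile level of the log-normal component matching overall level p
            return (p - z) / (1.0 - z)

        qs = [(0.25, self.q25), (0.5, self.median), (0.75, self.q75)]
        pos = [(cond_q(p), v) for p, v in qs if v > 0 and cond_q(p) > 0]
        if len(pos) >= 2:
            (pl, vl), (ph, vh) = pos[0], pos[-1]
            sigma = math.log(vh / vl) / (norm.ppf(ph) - norm.ppf(pl)) if vh > vl else 0.5
            anchor = next(((p, v) for p, v in pos if v == self.median and self.median > 0), pos[0])
            mu = math.log(anchor[1]) - sigma * norm.ppf(anchor[0])
        elif len(pos) == 1:
            sigma = 1.0
            p, v = pos[0]
            mu = math.log(v) - sigma * norm.ppf(p)
        else:
            # an all-zero printed cell: small, essentially signal-free tail
            sigma = 1.0
            mu = math.log(0.5)
        return mu, sigma

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        mu, sigma = self.lognormal_params()
        vals = rng.lognormal(mu, sigma, size=n)
        if self.zero_inflation > 0:
            vals[rng.random(n) < self.zero_inflation] = 0.0
        return vals


#: reference medians [q25, q75] of the movement features in a clinical
#: v-PSG cohort, per ROI x duration bin x feature — iRBD group (n=53)
IRBD_REFERENCE_CELLS: dict[str, tuple[float, float, float]] = {
    "HE_short_rate": (15.85, 9.17, 30.17),
    "HE_short_ratio": (12.02, 8.0, 19.91),
    "HE_medium_rate": (5.43, 3.18, 8.01),
    "HE_medium_ratio": (25.8, 13.27, 34.59),
    "HE_long_rate": (0.0, 0.0, 0.0),
    "HE_long_ratio": (0.0, 0.0, 0.0),
    "HAs_short_rate": (17.38, 6.63, 33.32),
    "HAs_short_ratio": (13.52, 4.77, 27.41),
    "HAs_medium_rate": (3.96, 1.37, 11.97),
    "HAs_medium_ratio": (14.43, 4.64, 41.96),
    "HAs_long_rate": (0.0, 0.0, 0.0),
    "HAs_long_ratio": (0.0, 0.0, 0.0),
    "UB_short_rate": (31.88, 18.65, 82.1),
    "UB_short_ratio": (26.67, 12.34, 53.09),
    "UB_medium_rate": (9.8, 5.6, 16.49),
    "UB_medium_ratio": (50.19, 28.69, 75.82),
    "UB_long_rate": (0.47, 0.0, 1.69),
    "UB_long_ratio": (9.72, 0.0, 32.37),
    "LB_short_rate": (44.12, 32.93, 63.73),
    "LB_short_ratio": (50.03, 38.43, 77.06),
    "LB_medium_rate": (51.75, 34.57, 82.24),
    "LB_medium_ratio": (247.5, 154.8, 379.59),
    "LB_long_rate": (2.23, 0.38, 4.34),
    "LB_long_ratio": (45.34, 7.38, 98.07),
}

#: same cells for the pooled no-RBD group (n=128)
NO_RBD_REFERENCE_CELLS: dict[str, tuple[float, float, float]] = {
    "HE_short_rate": (7.46, 2.91, 11.71),
    "HE_short_ratio": (6.17, 2.51, 9.9),
    "HE_medium_rate": (4.05, 1.43, 6.48),
    "HE_medium_ratio": (21.1, 5.31, 33.76),
    "HE_long_rate": (0.0, 0.0, 0.0),
    "HE_long_ratio": (0.0, 0.0, 0.0),
    "HAs_short_rate": (7.19, 2.37, 15.33),
    "HAs_short_ratio": (5.01, 1.52, 11.82),
    "HAs_medium_rate": (1.55, 0.0, 5.86),
    "HAs_medium_ratio": (5.03, 0.0, 21.81),
    "HAs_long_rate": (0.0, 0.0, 0.0),
    "HAs_long_ratio": (0.0, 0.0, 0.0),
    "UB_short_rate": (9.64, 4.44, 14.96),
    "UB_short_ratio": (7.69, 3.26, 11.63),
    "UB_medium_rate": (5.11, 2.37, 9.85),
    "UB_medium_ratio": (30.28, 12.31, 56.79),
    "UB_long_rate": (0.0, 0.0, 1.14),
    "UB_long_ratio": (0.0, 0.0, 19.36),
    "LB_short_rate": (10.90, 5.94, 19.17),
    "LB_short_ratio": (12.45, 6.54, 21.24),
    "LB_medium_rate": (16.01, 10.10, 25.01),
    "LB_medium_ratio": (81.71, 45.67, 124.39),
    "LB_long_rate": (0.94, 0.0, 2.23),
    "LB_long_ratio": (17.88, 0.0, 49.0),
}

#: SINBAR RWA index (% of REM) median [q25, q75] per group
SINBAR_REFERENCE = {"iRBD": (61.4, 48.4, 74.4), "no-RBD": (15.2, 10.7, 23.9)}

#: REM duration (minutes) mean +/- SD per group
REM_MINUTES_REFERENCE = {"iRBD": (66.1, 31.4), "no-RBD": (71.3, 31.8)}

#: no-RBD subgroup sizes in the reference cohort
SUBGROUP_SIZES = {"SRBD": 51, "RLS": 20, "INS": 20, "PLMS": 12, "NREMP": 6, "NRSD": 19}

#: movement-rate multipliers applied to the no-RBD cells per subgroup: the
#: breathing-disorder group moves most among the negatives (apnea-arousal
#: movements), insomnia / no-relevant-disorder sleepers are quietest
SUBGROUP_MULTIPLIERS = {"SRBD": 1.2, "RLS": 1.0, "PLMS": 1.0, "NREMP": 1.0, "INS": 0.55, "NRSD": 0.55}


@dataclass
class GroupSpec:
    """One cohort group: size, per-cell feature specs, SINBAR and REM time."""

    name: str
    n: int
    cells: dict[str, CellSpec]
    sinbar: CellSpec | None = None
    rem_minutes: tuple[float, float] = (70.0, 30.0)


@dataclass
class CohortSpec:
    """A cohort as a list of groups plus an optional shared severity factor.

    ``severity_sigma > 0`` multiplies all of a subject's cells by a common
    log-normal factor (median 1), inducing positive cross-cell correlation;
    by default draws are independent across cells.
    """

    groups: list[GroupSpec] = field(default_factory=list)
    severity_sigma: float = 0.0


def _cells_from_reference(
    ref: dict[str, tuple[float, float, float]], multiplier: float = 1.0
) -> dict[str, CellSpec]:
    return {
        col: CellSpec(m * multiplier, q25 * multiplier, q75 * multiplier)
        for col, (m, q25, q75) in ref.items()
    }


def default_cohort_spec(subgroups: bool = True) -> CohortSpec:
    """The reference 53-iRBD vs 128-no-RBD cohort.

    With ``subgroups=False`` the negatives form a single pooled "no-RBD"
    group drawn directly from the pooled reference cells.
    """
    irbd = GroupSpec(
        "iRBD",
        53,
        _cells_from_reference(IRBD_REFERENCE_CELLS),
        sinbar=CellSpec(*SINBAR_REFERENCE["iRBD"]),
        rem_minutes=REM_MINUTES_REFERENCE["iRBD"],
    )
    groups = [irbd]
    if subgroups:
        for name, n in SUBGROUP_SIZES.items():
            groups.append(
                GroupSpec(
                    name,
                    n,
                    _cells_from_reference(NO_RBD_REFERENCE_CELLS, SUBGROUP_MULTIPLIERS[name]),
                    sinbar=CellSpec(*SINBAR_REFERENCE["no-RBD"]),
                    rem_minutes=REM_MINUTES_REFERENCE["no-RBD"],
                )
            )
    else:
        groups.append(
            GroupSpec(
                "NRSD",
                128,
                _cells_from_reference(NO_RBD_REFERENCE_CELLS),
                sinbar=CellSpec(*SINBAR_REFERENCE["no-RBD"]),
                rem_minutes=REM_MINUTES_REFERENCE["no-RBD"],
            )
        )
    return CohortSpec(groups)


def sample_cohort_features(
    spec: CohortSpec, seed: int | np.random.Generator | None = 0
) -> pd.DataFrame:
    """Draw a per-subject feature table from a cohort spec.

    Returns a wide-format DataFrame indexed by ``subject_id`` with a
    ``group`` column, the 24 ``{roi}_{bin}_{rate|ratio}`` feature columns,
    ``rem_hours`` and (when the spec provides it) ``sinbar_index``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for g in spec.groups:
        for _ in range(g.n):
            row: dict[str, object] = {"subject_id": f"S{sid:04d}", "group": g.name}
            sid += 1
            sev = rng.lognormal(0.0, spec.severity_sigma) if spec.severity_sigma > 0 else 1.0
            for col, cell in g.cells.items():
                row[col] = float(cell.sample(1, rng)[0]) * sev
            rem_min = max(rng.normal(*g.rem_minutes), 10.0)
            row["rem_hours"] = rem_min / 60.0
            if g.sinbar is not None:
                row["sinbar_index"] = float(np.clip(g.sinbar.sample(1, rng)[0], 0.0, 100.0))
            rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
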