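"""Containers and on-disk formats for depth-video sleep recordings.

Conventions used throughout the package:

* all times are in seconds and all intervals are half-open ``[start, end)``;
* frame ``i`` of a sequence recorded at ``fps`` covers
  ``[start_time + i/fps, start_time + (i+1)/fps)`` on the hypnogram clock;
* depth values are millimetres from the ceiling-mounted time-of-flight
  sensor, stored as 16-bit unsigned integers in ``[0, 8000]``;
* sleep stages are scored in 30-s epochs with codes ``W, N1, N2, N3, R``.

A depth sequence on disk is a directory of zero-padded 16-bit grayscale PNG
frames plus a ``meta.json`` sidecar (fps, width, height, start_time) — a
lossless, inspectable, language-neutral layout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.draw import polygon2mask

__all__ = [
    "DepthSequence",
    "Hypnogram",
    "ROILayout",
    "TrackSet",
    "SubjectRecord",
    "DepthIOError",
    "GROUPS",
    "ROI_CODES",
    "read_depth_dir",
    "write_depth_dir",
    "read_hypnogram",
    "write_hypnogram",
    "rem_hours",
    "rem_intervals",
    "read_roi_layout",
    "write_roi_layout",
    "read_tracks",
    "write_tracks",
    "read_labels",
    "write_labels",
]

#: short codes for the four regions of interest
ROI_CODES = ("HE", "HAs", "UB", "LB")

#: diagnostic groups: isolated RBD, sleep-related breathing disorder,
#: restless legs syndrome, periodic limb movements during sleep, insomnia,
#: NREM parasomnia, no relevant sleep disorder.
GROUPS = ("iRBD", "SRBD", "RLS", "PLMS", "INS", "NREMP", "NRSD")

STAGES = ("W", "N1", "N2", "N3", "R")

MAX_DEPTH_MM = 8000


class DepthIOError(ValueError):
    """Raised for malformed or inconsistent on-disk artifacts."""


@dataclass
class DepthSequence:
    """A night (or clip) of depth frames with timing metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width), uint16
        Per-pixel distance from the sensor in millimetres.
    fps : float
        Frame rate in frames per second.
    start_time : float
        Offset of frame 0 on the hypnogram clock, in seconds.
    """

    frames: np.ndarray
    fps: float = 30.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DepthIOError("frames must be a (n, height, width) array")
        if self.fps <= 0:
            raise DepthIOError("fps must be positive")
        if self.frames.size and int(self.frames.max()) > MAX_DEPTH_MM:
            raise DepthIOError(f"depth values must lie in [0, {MAX_DEPTH_MM}] mm")
        if self.frames.dtype != np.uint16:
            if not np.issubdtype(self.frames.dtype, np.integer):
                raise DepthIOError("frames must be 16-bit unsigned integers")
            self.frames = self.frames.astype(np.uint16)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def frame_time(self, i: int) -> float:
        """Start of frame ``i``'s interval on the hypnogram clock."""
        return self.start_time + i / self.fps


@dataclass
class Hypnogram:
    """Epoch-coded sleep stages (30-s epochs, codes W/N1/N2/N3/R)."""

    stages: tuple[str, ...]
    epoch_len_s: float = 30.0

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if not self.stages:
            raise DepthIOError("hypnogram must contain at least one epoch")
        if self.epoch_len_s != 30.0:
            raise DepthIOError("sleep stages are scored in 30-s epochs")
        bad = sorted(set(self.stages) - set(STAGES))
        if bad:
            raise DepthIOError(f"unknown stage code(s): {bad}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def total_s(self) -> float:
        return self.n_epochs * self.epoch_len_s


def rem_hours(h: Hypnogram) -> float:
    """Total REM time in hours: 30 s per ``R`` epoch."""
    return sum(s == "R" for s in h.stages) * h.epoch_len_s / 3600.0


def rem_intervals(h: Hypnogram) -> list[tuple[float, float]]:
    """Maximal runs of R epochs as half-open ``[start_s, end_s)`` intervals.

    Interval lengths always sum to ``3600 * rem_hours(h)``.
    """
    out: list[tuple[float, float]] = []
    start = None
    for i, s in enumerate(h.stages):
        if s == "R" and start is None:
            start = i
        elif s != "R" and start is not None:
            out.append((start * h.epoch_len_s, i * h.epoch_len_s))
            start = None
    if start is not None:
        out.append((start * h.epoch_len_s, h.n_epochs * h.epoch_len_s))
    return out


@dataclass
class ROILayout:
    """Static polygons (pixel coordinates, (x, y) vertices) for the manually
    delineated upper-body and lower-body regions.

    Head and hand regions are dynamic (per-frame boxes in a :class:`TrackSet`)
    and are not part of the static layout.
    """

    polygons: dict[str, np.ndarray] = field(default_factory=dict)

    REQUIRED = ("upper_body", "lower_body")

    def __post_init__(self) -> None:
        self.polygons = {k: np.asarray(v, dtype=float) for k, v in self.polygons.items()}
        for name in self.REQUIRED:
            if name not in self.polygons:
                raise DepthIOError(f"layout is missing the '{name}' polygon")
        shapes = {}
        for name, verts in self.polygons.items():
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise DepthIOError(f"polygon '{name}' must be an (n>=3, 2) vertex array")
            poly = _ShapelyPolygon(verts)
            if not poly.is_valid:
                raise DepthIOError(f"polygon '{name}' is self-intersecting or degenerate")
            shapes[name] = poly
        inter = shapes["upper_body"].intersection(shapes["lower_body"])
        if inter.area > 1e-9:
            raise DepthIOError("upper_body and lower_body polygons must be disjoint")

    def mask(self, name: str, frame_shape: tuple[int, int]) -> np.ndarray:
        """Rasterize polygon ``name`` to a boolean mask of ``frame_shape`` (h, w)."""
        verts = self.polygons[name]
        h, w = frame_shape
        if verts[:, 0].min() < 0 or verts[:, 1].min() < 0 or \
           verts[:, 0].max() > w or verts[:, 1].max() > h:
            raise DepthIOError(f"polygon '{name}' extends outside the {w}x{h} frame")
        # polygon2mask expects (row, col) = (y, x)
        return polygon2mask((h, w), verts[:, ::-1])


@dataclass
class TrackSet:
    """Per-frame head/hand bounding boxes from the external body-part detector.

    ``boxes`` is a DataFrame with columns ``frame, roi, x, y, w, h, valid``
    where ``roi`` is ``"head"`` or ``"hand"`` (zero or one head and up to two
    hand boxes per frame) and ``valid`` marks frames where the detector
    produced a usable box.
    """

    boxes: pd.DataFrame

    COLUMNS = ("frame", "roi", "x", "y", "w", "h", "valid")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.boxes)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise DepthIOError(f"track table is missing columns: {sorted(missing)}")
        bad = sorted(set(df["roi"].unique()) - {"head", "hand"})
        if bad:
            raise DepthIOError(f"unknown track roi(s): {bad}")
        df = df.sort_values("frame", kind="stable").reset_index(drop=True)
        df["valid"] = df["valid"].astype(bool)
        self.boxes = df

    @classmethod
    def empty(cls) -> "TrackSet":
        return cls(pd.DataFrame({c: [] for c in cls.COLUMNS}))

    def valid_boxes(self, frame: int) -> list[tuple[str, int, int, int, int]]:
        """Valid ``(roi, x, y, w, h)`` boxes for a frame index."""
        df = self.boxes
        sel = df[(df["frame"] == frame) & df["valid"]]
        return [
            (r.roi, int(r.x), int(r.y), int(r.w), int(r.h))
            for r in sel.itertuples()
        ]

    def coverage(self, roi: str, n_frames: int) -> float:
        """Fraction of frames with at least one valid box for ``roi``."""
        df = self.boxes
        frames = df[(df["roi"] == roi) & df["valid"]]["frame"].unique()
        return len(frames) / n_frames if n_frames else 0.0


@dataclass
class SubjectRecord:
    """Diagnostic label (and optional RWA severity) for one subject.

    ``sinbar_index`` is the SINBAR REM-sleep-without-atonia index: the
    percentage of REM sleep with qualifying EMG activity, in [0, 100].
    """

    subject_id: str
    group: str
    sinbar_index: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DepthIOError(f"unknown group '{self.group}' (expected one of {GROUPS})")
        if self.sinbar_index is not None and not 0 <= self.sinbar_index <= 100:
            raise DepthIOError("sinbar_index must lie in [0, 100]")


# ---------------------------------------------------------------------------
# depth sequence directory IO


def write_depth_dir(seq: DepthSequence, path: str | Path) -> None:
    """Write ``seq`` as zero-padded 16-bit PNG frames plus a meta.json sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    h, w = seq.frame_shape
    meta = {
        "fps": seq.fps,
        "width": w,
        "height": h,
        "start_time": seq.start_time,
        "n_frames": seq.n_frames,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    for i in range(seq.n_frames):
        iio.imwrite(path / f"frame_{i:06d}.png", seq.frames[i])


def read_depth_dir(path: str | Path) -> DepthSequence:
    """Read a depth-sequence directory written by :func:`write_depth_dir`.

    Round-trips are lossless: ``read_depth_dir(write_depth_dir(seq))`` equals
    ``seq`` bit for bit.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise DepthIOError(f"missing sidecar meta.json in {path}")
    meta = json.loads(meta_path.read_text())
    files = sorted(path.glob("frame_*.png"))
    if not files:
        raise DepthIOError(f"no frames found in {path}")
    expected = (meta["height"], meta["width"])
    frames = np.empty((len(files), *expected), dtype=np.uint16)
    for i, f in enumerate(files):
        img = iio.imread(f)
        if img.dtype != np.uint16:
            raise DepthIOError(f"{f.name}: expected 16-bit grayscale PNG, got {img.dtype}")
        if img.shape != expected:
            raise DepthIOError(
                f"{f.name}: frame shape {img.shape} inconsistent with sidecar {expected}"
            )
        frames[i] = img
    return DepthSequence(frames, fps=meta["fps"], start_time=meta.get("start_time", 0.0))


# ---------------------------------------------------------------------------
# hypnogram IO


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    lines = ["epoch\tstage"] + [f"{i}\t{s}" for i, s in enumerate(h.stages)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a TSV of ``epoch<TAB>stage`` rows (header optional)."""
    stages = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.lower().startswith("epoch"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DepthIOError(f"malformed hypnogram line: {line!r}")
        stages.append(parts[1])
    return Hypnogram(tuple(stages))


# ---------------------------------------------------------------------------
# ROI layout, tracks, labels


def write_roi_layout(layout: ROILayout, path: str | Path) -> None:
    obj = {name: verts.tolist() for name, verts in layout.polygons.items()}
    Path(path).write_text(json.dumps(obj, indent=1))


def read_roi_layout(path: str | Path) -> ROILayout:
    obj = json.loads(Path(path).read_text())
    return ROILayout({name: np.asarray(v, dtype=float) for name, v in obj.items()})


def write_tracks(tracks: TrackSet, path: str | Path) -> None:
    tracks.boxes.to_csv(path, index=False)


def read_tracks(path: str | Path) -> TrackSet:
    return TrackSet(pd.read_csv(path))


def write_labels(records: list[SubjectRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "sinbar_index": [r.sinbar_index for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_labels(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    records = []
    for r in df.itertuples():
        sinbar = getattr(r, "sinbar_index", None)
        if sinbar is not None and pd.isna(sinbar):
            sinbar = None
        records.append(SubjectRecord(str(r.subject_id), r.group, sinbar))
    return records


def check_clock_alignment(seq: DepthSequence, h: Hypnogram) -> None:
    """Warn when video and hypnogram clocks disagree by more than one epoch."""
    drift = abs(seq.start_time + seq.duration_s - h.total_s)
    if drift > h.epoch_len_s:
        warnings.warn(
            f"video span and hypnogram span differ by {drift:.1f} s "
            "(more than one epoch); check start_time",
            stacklevel=2,
        )
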