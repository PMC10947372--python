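"""Per-ROI motion detection from depth sequences.

The detector turns a depth sequence into four binary motion traces (head,
hands, upper body, lower body) by

1. frame differencing — a pixel counts as *changed* between consecutive
   frames when its depth moves by more than ``pixel_delta_mm``;
2. region masking with the head/hands-over-upper-body precedence rule:
   when the external detector provides a valid head or hand box, those
   pixels are removed from the upper-body region so a head/hand movement is
   never double-counted; when the box is missing, the pixels fall back to
   the upper-body region;
3. respiration suppression of the per-region changed-area signal
   (adaptive spectral notch, see :func:`respiration_suppress`);
4. an area threshold — a frame is flagged for a region when the
   (suppressed) changed-pixel count reaches ``min_area_px``.

Thresholds are configurable; the defaults target the nominal 512x424 frame
and should be scaled with pixel count for other resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .depthio import DepthSequence, ROILayout, TrackSet, ROI_CODES

__all__ = [
    "DetectorParams",
    "MotionTrace",
    "frame_difference",
    "effective_masks",
    "respiration_suppress",
    "detect_motion",
    "trace_to_frame",
    "trace_from_frame",
]

_CHUNK = 2000  # frames per differencing chunk, bounds peak memory


@dataclass
class DetectorParams:
    """Tunable thresholds of the motion detector.

    ``min_area_px`` maps each region code to the minimum changed-pixel count
    per frame; the body regions are large and need a bigger footprint than
    the head/hand boxes.  ``resp_band_hz`` is the frequency band searched for
    respiration oscillation in the area signal.
    """

    pixel_delta_mm: float = 10.0
    min_area_px: dict[str, int] = field(
        default_factory=lambda: {"HE": 20, "HAs": 20, "UB": 50, "LB": 50}
    )
    resp_band_hz: tuple[float, float] = (0.15, 0.5)
    resp_suppress: bool = True

    def __post_init__(self) -> None:
        if self.pixel_delta_mm <= 0:
            raise ValueError("pixel_delta_mm must be positive")
        if any(v < 1 for v in self.min_area_px.values()):
            raise ValueError("min_area_px must be >= 1")
        lo, hi = self.resp_band_hz
        if not 0 < lo < hi:
            raise ValueError("resp_band_hz must satisfy 0 < low < high")


@dataclass
class MotionTrace:
    """Per-region motion flags and changed-area magnitudes.

    Arrays have length ``n_frames - 1``: entry ``t`` describes the change
    between frames ``t`` and ``t+1``.
    """

    fps: float
    area: dict[str, np.ndarray]
    flag: dict[str, np.ndarray]

    @property
    def n_steps(self) -> int:
        return len(next(iter(self.area.values())))


def frame_difference(seq: DepthSequence, pixel_delta_mm: float) -> np.ndarray:
    """Binary change rasters between consecutive frames.

    Returns a boolean array of shape ``(n_frames - 1, h, w)`` where entry
    ``t`` marks pixels with ``|depth(t+1) - depth(t)| > pixel_delta_mm``.
    """
    if seq.n_frames < 2:
        raise ValueError("frame differencing needs at least 2 frames")
    n = seq.n_frames - 1
    out = np.empty((n, *seq.frames.shape[1:]), dtype=bool)
    for s in range(0, n, _CHUNK):
        e = min(s + _CHUNK, n)
        d = seq.frames[s + 1 : e + 1].astype(np.int32) - seq.frames[s:e].astype(np.int32)
        out[s:e] = np.abs(d) > pixel_delta_mm
    return out


def effective_masks(
    layout: ROILayout,
    tracks: TrackSet | None,
    frame: int,
    frame_shape: tuple[int, int],
    _static: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Region masks for one frame under the precedence rule.

    Head and hand masks are the valid detector boxes for that frame (empty
    when the detector dropped out); the upper-body mask is the static upper
    polygon minus any valid boxes, so movements under a recognised head/hand
    stay out of the upper-body count but fall back into it when the detector
    misses.  Masks are pairwise disjoint: a changed pixel contributes to
    exactly one region.
    """
    if _static is None:
        _static = {
            "UB": layout.mask("upper_body", frame_shape),
            "LB": layout.mask("lower_body", frame_shape),
        }
    h, w = frame_shape
    head = np.zeros((h, w), dtype=bool)
    hands = np.zeros((h, w), dtype=bool)
    if tracks is not None:
        for roi, x, y, bw, bh in tracks.valid_boxes(frame):
            target = head if roi == "head" else hands
            target[max(y, 0) : y + bh, max(x, 0) : x + bw] = True
    hands &= ~head  # head takes precedence where boxes overlap
    boxes = head | hands
    return {
        "HE": head,
        "HAs": hands,
        "UB": _static["UB"] & ~boxes,
        "LB": _static["LB"] & ~boxes,
    }


def respiration_suppress(
    area_signal: np.ndarray,
    fps: float,
    resp_band_hz: tuple[float, float] = (0.15, 0.5),
    peak_factor: float = 4.0,
    tonal_share: float = 0.05,
    notch_halfwidth_hz: float = 0.03,
    n_harmonics: int = 4,
    max_peaks: int = 3,
) -> np.ndarray:
    """Remove respiration oscillation from a changed-area signal.

    Respiration shows up as a sustained narrowband tone (plus harmonics and
    a baseline pedestal) in the area signal, while genuine movements are
    broadband transients.  The filter therefore looks for a dominant tonal
    peak inside ``resp_band_hz`` — a spectral line exceeding ``peak_factor``
    times the median in-band magnitude *and* carrying at least
    ``tonal_share`` of the signal's AC spectral power (a sparse train of
    movement pulses has prominent but individually weak lines and must not
    trigger) — and, only when one is found, removes it together with its
    harmonics and the DC pedestal via spectral notching.  Signals with no
    in-band tone (pulses, noise, silence) pass through unchanged, which is
    what preserves transient peaks that a linear band-stop would gut.
    """
    x = np.asarray(area_signal, dtype=float)
    lo, hi = resp_band_hz
    if not 0 < lo < hi < fps / 2:
        raise ValueError("resp_band_hz must lie strictly inside (0, Nyquist)")
    if len(x) < 4 * fps:
        raise ValueError("signal must cover at least 4 s")
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fps)
    # frame differencing rectifies an oscillation at f into an area signature
    # at 2f, so the tonal search extends to twice the band's upper edge
    search_hi = min(2.0 * hi, 0.95 * fps / 2.0)
    in_band = (freqs >= lo) & (freqs <= search_hi)
    if not in_band.any():
        return x.copy()
    detected = False
    ac_power0 = float((np.abs(X[1:]) ** 2).sum())
    for _ in range(max_peaks):
        mags = np.abs(X)
        band_mags = mags[in_band]
        med = np.median(band_mags)
        k = np.flatnonzero(in_band)[np.argmax(band_mags)]
        if med <= 0 or mags[k] <= peak_factor * med:
            break
        if not detected and mags[k] ** 2 < tonal_share * ac_power0:
            break
        detected = True
        f0 = freqs[k]
        halfwidth = max(notch_halfwidth_hz, 2.0 * freqs[1])  # >= 2 bins per side
        for harm in range(1, n_harmonics + 1):
            sel = np.abs(freqs - harm * f0) <= halfwidth
            X[sel] = 0.0
    if not detected:
        return x.copy()
    X[0] = 0.0  # sustained oscillation rides on a baseline pedestal
    return np.fft.irfft(X, n=len(x))


def detect_motion(
    seq: DepthSequence,
    layout: ROILayout,
    tracks: TrackSet | None,
    params: DetectorParams | None = None,
) -> MotionTrace:
    """Run the full per-region motion detector on a depth sequence."""
    params = params or DetectorParams()
    shape = seq.frame_shape
    static = {
        "UB": layout.mask("upper_body", shape),
        "LB": layout.mask("lower_body", shape),
    }
    n = seq.n_frames - 1
    if n < 1:
        raise ValueError("need at least 2 frames")
    area = {roi: np.zeros(n, dtype=float) for roi in ROI_CODES}

    # per-frame signature of valid boxes; box geometry repeats, so the
    # effective masks are cached per signature and applied as matrix products
    sig_by_frame: dict[int, tuple] = {}
    if tracks is not None and len(tracks.boxes):
        valid = tracks.boxes[tracks.boxes["valid"]]
        lists: dict[int, list] = {}
        for f, roi, x, y, bw, bh in zip(
            valid["frame"].to_numpy(),
            valid["roi"].to_numpy(),
            valid["x"].to_numpy(),
            valid["y"].to_numpy(),
            valid["w"].to_numpy(),
            valid["h"].to_numpy(),
        ):
            lists.setdefault(int(f), []).append((roi, int(x), int(y), int(bw), int(bh)))
        sig_by_frame = {f: tuple(sorted(v)) for f, v in lists.items()}

    def masks_for(sig: tuple) -> np.ndarray:
        h, w = shape
        head = np.zeros((h, w), dtype=bool)
        hands = np.zeros((h, w), dtype=bool)
        for roi, x, y, bw, bh in sig:
            target = head if roi == "head" else hands
            target[max(y, 0) : y + bh, max(x, 0) : x + bw] = True
        hands &= ~head
        boxes = head | hands
        stack = np.stack(
            [head, hands, static["UB"] & ~boxes, static["LB"] & ~boxes]
        )  # order: HE, HAs, UB, LB
        return stack.reshape(4, -1).T.astype(np.float64)

    mask_cache: dict[tuple, np.ndarray] = {}

    for s in range(0, n, _CHUNK):
        e = min(s + _CHUNK, n)
        d = seq.frames[s + 1 : e + 1].astype(np.int32) - seq.frames[s:e].astype(np.int32)
        changed = (np.abs(d) > params.pixel_delta_mm).reshape(e - s, -1)
        sigs = [sig_by_frame.get(t, ()) for t in range(s, e)]
        for sig in set(sigs):
            if sig not in mask_cache:
                mask_cache[sig] = masks_for(sig)
            idx = np.array([i for i, sg in enumerate(sigs) if sg == sig])
            counts = changed[idx].astype(np.float64) @ mask_cache[sig]
            for j, roi in enumerate(ROI_CODES):
                area[roi][s + idx] = counts[:, j]

    flag = {}
    for roi in ROI_CODES:
        sig = area[roi]
        if params.resp_suppress and len(sig) >= 4 * seq.fps:
            sig = respiration_suppress(sig, seq.fps, params.resp_band_hz)
        flag[roi] = sig >= params.min_area_px[roi]
    return MotionTrace(fps=seq.fps, area=area, flag=flag)


def trace_to_frame(trace: MotionTrace):
    """Long-format ``frame,roi,flag,area_px`` table of a motion trace."""
    import pandas as pd

    rows = []
    for roi in trace.area:
        for t in range(trace.n_steps):
            rows.append((t, roi, bool(trace.flag[roi][t]), float(trace.area[roi][t])))
    return pd.DataFrame(rows, columns=["frame", "roi", "flag", "area_px"])


def trace_from_frame(df, fps: float) -> MotionTrace:
    """Rebuild a :class:`MotionTrace` from its long-format table."""
    area = {}
    flag = {}
    for roi, g in df.groupby("roi"):
        g = g.sort_values("frame")
        area[str(roi)] = g["area_px"].to_numpy(dtype=float)
        flag[str(roi)] = g["flag"].to_numpy(dtype=bool)
    return MotionTrace(fps=fps, area=area, flag=flag)
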