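"""Movement events and the 3D rate / 3D ratio features.

A motion trace is converted to movement events by run-length extraction;
events closer than the 1-s merge gap are fused; events are restricted to
REM sleep (an event belongs to REM when its onset falls inside a REM
interval; durations are not clipped at REM boundaries); surviving events
are assigned a duration category — short [0.1, 2) s, medium [2, 15) s,
long [15, 300] s — and events outside [0.1, 300] s are dropped.

Two features summarise each region x duration bin:

* **3D rate** — movements in REM per hour of REM sleep;
* **3D ratio** — seconds of movement in REM per hour of REM sleep, i.e. the
  fraction of REM time spent moving scaled by 3600, so full occupancy
  equals 3600.

The pipeline order is fixed: extract -> merge -> REM-restrict -> bin.
Merging before the REM restriction avoids fragmenting movements that
straddle a REM boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .depthio import ROI_CODES
from .motion import MotionTrace

__all__ = [
    "DurationBins",
    "MovementEvent",
    "trace_to_events",
    "merge_events",
    "restrict_to_rem",
    "bin_by_duration",
    "compute_features",
    "features_from_trace",
    "events_to_frame",
]

RATIO_SCALE = 3600.0  # full occupancy of REM time maps to 3600


@dataclass(frozen=True)
class DurationBins:
    """Half-open duration categories and the inter-movement merge gap.

    ``short`` covers [0.1, 2) s, ``medium`` [2, 15) s and ``long``
    [15, 300] s (closed at the top); movements are separate only when the
    interval between them exceeds ``merge_gap_s``.
    """

    short: tuple[float, float] = (0.1, 2.0)
    medium: tuple[float, float] = (2.0, 15.0)
    long: tuple[float, float] = (15.0, 300.0)
    merge_gap_s: float = 1.0

    def assign(self, duration_s: float) -> str | None:
        """Bin name for a duration, or ``None`` for dropped events."""
        if duration_s < self.short[0] or duration_s > self.long[1]:
            return None
        if duration_s < self.short[1]:
            return "short"
        if duration_s < self.medium[1]:
            return "medium"
        return "long"

    @property
    def names(self) -> tuple[str, ...]:
        return ("short", "medium", "long")


@dataclass(frozen=True)
class MovementEvent:
    """One detected movement: region, half-open [start_s, end_s), bin."""

    roi: str
    start_s: float
    end_s: float
    bin: str | None = None

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def trace_to_events(trace: MotionTrace, roi: str | None = None) -> list[MovementEvent]:
    """Maximal runs of flagged frames as raw events.

    A run of flags from frame ``a`` through ``b`` becomes the event
    ``[a/fps, (b+1)/fps)``.  With ``roi=None`` all regions are extracted.
    """
    rois = [roi] if roi is not None else [r for r in ROI_CODES if r in trace.flag]
    events: list[MovementEvent] = []
    for r in rois:
        flags = trace.flag[r]
        start = None
        for i, f in enumerate(flags):
            if f and start is None:
                start = i
            elif not f and start is not None:
                events.append(MovementEvent(r, start / trace.fps, i / trace.fps))
                start = None
        if start is not None:
            events.append(MovementEvent(r, start / trace.fps, len(flags) / trace.fps))
    return events


def _check_sorted(events: list[MovementEvent]) -> None:
    for a, b in zip(events, events[1:]):
        if b.start_s < a.end_s:
            raise ValueError("events must be sorted and non-overlapping")


def merge_events(
    events: list[MovementEvent], merge_gap_s: float = 1.0
) -> list[MovementEvent]:
    """Fuse same-region events separated by at most ``merge_gap_s``.

    Movements count as separate only when the inter-movement interval
    exceeds the gap, so a gap of exactly ``merge_gap_s`` merges.  The
    operation is idempotent and requires sorted, non-overlapping input of a
    single region.
    """
    if not events:
        return []
    if len({e.roi for e in events}) > 1:
        raise ValueError("merge_events operates on a single region at a time")
    _check_sorted(events)
    out = [events[0]]
    for ev in events[1:]:
        prev = out[-1]
        if ev.start_s - prev.end_s <= merge_gap_s:
            out[-1] = MovementEvent(prev.roi, prev.start_s, max(prev.end_s, ev.end_s))
        else:
            out.append(ev)
    return out


def restrict_to_rem(
    events: list[MovementEvent], rem_intervals: list[tuple[float, float]]
) -> list[MovementEvent]:
    """Keep events whose onset falls inside a REM interval.

    Kept events retain their full duration (no clipping at the REM
    boundary); intervals must be half-open and disjoint.
    """
    out = []
    for ev in events:
        if any(s <= ev.start_s < e for s, e in rem_intervals):
            out.append(ev)
    return out


def bin_by_duration(
    events: list[MovementEvent], bins: DurationBins | None = None
) -> list[MovementEvent]:
    """Assign duration bins; events outside [0.1, 300] s are dropped."""
    bins = bins or DurationBins()
    out = []
    for ev in events:
        b = bins.assign(ev.duration_s)
        if b is not None:
            out.append(MovementEvent(ev.roi, ev.start_s, ev.end_s, bin=b))
    return out


def compute_features(
    events: list[MovementEvent],
    rem_hours: float,
    bins: DurationBins | None = None,
) -> pd.Series:
    """3D rate and 3D ratio per region x duration bin.

    rate = events / h REM; ratio = total event seconds / h REM (equal to the
    fraction of REM time spent moving times 3600).  Events must already be
    binned.  Raises when ``rem_hours`` is zero.
    """
    if rem_hours <= 0:
        raise ValueError("no REM sleep: features are undefined")
    bins = bins or DurationBins()
    vals: dict[str, float] = {}
    for roi in ROI_CODES:
        for b in bins.names:
            sel = [ev for ev in events if ev.roi == roi and ev.bin == b]
            vals[f"{roi}_{b}_rate"] = len(sel) / rem_hours
            vals[f"{roi}_{b}_ratio"] = sum(ev.duration_s for ev in sel) / rem_hours
    return pd.Series(vals)


def features_from_trace(
    trace: MotionTrace,
    rem_intervals: list[tuple[float, float]],
    rem_hours: float,
    bins: DurationBins | None = None,
) -> pd.Series:
    """Full pipeline from a motion trace to one subject's feature row."""
    bins = bins or DurationBins()
    binned: list[MovementEvent] = []
    for roi in ROI_CODES:
        if roi not in trace.flag:
            continue
        evs = trace_to_events(trace, roi)
        evs = merge_events(evs, bins.merge_gap_s)
        evs = restrict_to_rem(evs, rem_intervals)
        binned.extend(bin_by_duration(evs, bins))
    return compute_features(binned, rem_hours, bins)


def events_to_frame(events: list[MovementEvent]) -> pd.DataFrame:
    """Events as a ``roi,start_s,end_s,bin`` DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "roi": [e.roi for e in events],
            "start_s": [e.start_s for e in events],
            "end_s": [e.end_s for e in events],
            "bin": [e.bin for e in events],
        }
    )
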