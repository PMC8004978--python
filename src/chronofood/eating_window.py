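"""Percentile-based eating windows from timestamped ingestion events.

A participant's eating window is summarised by the central band of their
ingestion-event clock times: the window runs from the 2.5th to the 97.5th
percentile of all event times in a phase, which trims outlier entries
(special days, entry errors).  Clock times are measured from a 04:00 anchor
— the overnight nadir of ingestion — so that late-evening and early-morning
events sort correctly around midnight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EatingWindow",
    "WindowChange",
    "parse_anchor",
    "hours_since_anchor",
    "eating_window",
    "tre_eligibility",
    "window_change",
    "assign_phase",
    "window_table",
]

DEFAULT_ANCHOR = 4.0  # 04:00 local time


def parse_anchor(anchor: float | str) -> float:
    """Accept an anchor as fractional hours (4.0) or clock text ('04:00')."""
    if isinstance(anchor, str):
        parts = anchor.split(":")
        h = float(parts[0])
        if len(parts) > 1:
            h += float(parts[1]) / 60.0
        if len(parts) > 2:
            h += float(parts[2]) / 3600.0
        anchor = h
    anchor = float(anchor)
    if not 0.0 <= anchor < 24.0:
        raise ValueError(f"anchor {anchor} outside [0, 24)")
    return anchor


@dataclass(frozen=True)
class EatingWindow:
    """Start / midpoint / end (clock hours) and duration of daily intake."""

    start: float
    midpoint: float
    end: float
    duration: float
    n_events: int
    anchor: float = DEFAULT_ANCHOR
    percentile_band: tuple[float, float] = (2.5, 97.5)

    def anchored(self, clock: float) -> float:
        return (clock - self.anchor) % 24.0


@dataclass(frozen=True)
class WindowChange:
    """Signed intervention-minus-observation shifts, in fractional hours."""

    d_duration: float
    d_start: float
    d_mid: float
    d_end: float


def _clock_hours(ts: pd.Timestamp, default_tz: str | None) -> float:
    ts = pd.Timestamp(ts)
    if ts.tzinfo is None:
        if default_tz is None:
            raise ValueError(
                "naive timestamp without timezone; pass default_tz to assume one"
            )
        ts = ts.tz_localize(default_tz)
    return ts.hour + ts.minute / 60.0 + ts.second / 3600.0 + ts.microsecond / 3.6e9


def hours_since_anchor(
    timestamp, anchor: float | str = DEFAULT_ANCHOR, default_tz: str | None = None
) -> float:
    """Fractional hours in [0, 24) between the anchor and the local clock time."""
    return (_clock_hours(timestamp, default_tz) - parse_anchor(anchor)) % 24.0


def _anchored_hours(
    events, anchor: float, default_tz: str | None
) -> np.ndarray:
    if isinstance(events, pd.DataFrame):
        frame = events
        if "special" in frame.columns:
            frame = frame[~frame["special"].isin(("water", "medication"))]
        stamps = frame["timestamp"]
    else:
        stamps = pd.Series(list(events))
    return np.array([hours_since_anchor(ts, anchor, default_tz) for ts in stamps])


def eating_window(
    events,
    lo: float = 2.5,
    hi: float = 97.5,
    anchor: float | str = DEFAULT_ANCHOR,
    default_tz: str | None = None,
) -> EatingWindow:
    """Percentile eating window over all events of a phase.

    ``events`` is a sequence of timezone-aware timestamps or a DataFrame with
    a ``timestamp`` column; rows labelled water or medication (``special``
    column, if present) are dropped, matching the definition of an ingestion
    event.  Event times are pooled across days, anchored, and the window
    start/end taken as the ``lo``/``hi`` percentiles (linear interpolation
    between order statistics); the midpoint is the median.
    """
    if lo >= hi:
        raise ValueError(f"lo percentile {lo} must be below hi {hi}")
    anchor = parse_anchor(anchor)
    h = _anchored_hours(events, anchor, default_tz)
    if h.size < 2:
        raise ValueError(f"need at least 2 ingestion events, got {h.size}")
    start_h, mid_h, end_h = np.percentile(h, [lo, 50.0, hi])
    return EatingWindow(
        start=(anchor + start_h) % 24.0,
        midpoint=(anchor + mid_h) % 24.0,
        end=(anchor + end_h) % 24.0,
        duration=float(end_h - start_h),
        n_events=int(h.size),
        anchor=anchor,
        percentile_band=(lo, hi),
    )


def tre_eligibility(window: EatingWindow, ms_component_count: int) -> bool:
    """Intervention-phase eligibility: eating duration strictly above 14 h
    and at least one metabolic-syndrome component."""
    return window.duration > 14.0 and ms_component_count >= 1


def window_change(observation: EatingWindow, intervention: EatingWindow) -> WindowChange:
    """Signed window shifts (intervention − observation) on the anchored scale."""
    if observation.anchor != intervention.anchor:
        raise ValueError("windows computed with different anchors are not comparable")
    if observation.percentile_band != intervention.percentile_band:
        raise ValueError("windows computed with different percentile bands")
    d_start = intervention.anchored(intervention.start) - observation.anchored(observation.start)
    d_mid = intervention.anchored(intervention.midpoint) - observation.anchored(observation.midpoint)
    d_end = intervention.anchored(intervention.end) - observation.anchored(observation.end)
    return WindowChange(
        d_duration=intervention.duration - observation.duration,
        d_start=d_start,
        d_mid=d_mid,
        d_end=d_end,
    )


def assign_phase(events: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """Split events into observation / intervention by randomisation date.

    ``visits`` columns: participant_id, randomisation_date, closeout_date.
    Events strictly before the randomisation date belong to the observation
    phase; events from randomisation to closeout (inclusive) to the
    intervention phase; later events are dropped.  Participants without a
    visits row keep all events in the observation phase.
    """
    out = events.copy()
    vis = visits.set_index("participant_id")
    rand = pd.to_datetime(vis["randomisation_date"])
    close = pd.to_datetime(vis["closeout_date"])
    phases = []
    keep = []
    for pid, ts in zip(out["participant_id"], out["timestamp"]):
        ts = pd.Timestamp(ts)
        if pid not in vis.index:
            phases.append("observation")
            keep.append(True)
            continue
        r, c = rand.loc[pid], close.loc[pid]
        naive = ts.tz_localize(None) if ts.tzinfo is not None else ts
        if naive < r:
            phases.append("observation")
            keep.append(True)
        elif naive <= c:
            phases.append("intervention")
            keep.append(True)
        else:
            phases.append("post")
            keep.append(False)
    out["phase"] = phases
    return out[np.array(keep)].reset_index(drop=True)


def window_table(
    events: pd.DataFrame,
    lo: float = 2.5,
    hi: float = 97.5,
    anchor: float | str = DEFAULT_ANCHOR,
    default_tz: str | None = None,
) -> pd.DataFrame:
    """Per-participant, per-phase eating-window summary table.

    Participants/phases with fewer than two ingestion events are skipped.
    """
    rows = []
    group_cols = ["participant_id"]
    if "phase" in events.columns:
        group_cols.append("phase")
    for key, grp in events.groupby(group_cols, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        try:
            w = eating_window(grp, lo=lo, hi=hi, anchor=anchor, default_tz=default_tz)
        except ValueError:
            continue
        row = dict(zip(group_cols, key))
        row.update(
            start=w.start,
            midpoint=w.midpoint,
            end=w.end,
            duration=w.duration,
            n_events=w.n_events,
        )
        rows.append(row)
    return pd.DataFrame(rows)
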