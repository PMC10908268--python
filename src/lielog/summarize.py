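"""Bout and interval summaries of lying behavior and activity.

Bout summaries report duration, side and mean activity per bout.
Interval summaries aggregate over regular, half-open intervals (e.g. an
hour or a day): total lying/standing durations, side-specific lying
durations, and fractional-overlap-weighted bout counts and mean bout
durations — a bout lying 30% inside an interval contributes 0.3 of a
bout there and 0.7 to the adjacent interval, so totals are not inflated
by bouts straddling interval boundaries.

Quantities that depend on the unknown true duration of an edge bout
(one truncated by the start or end of the recording) are suppressed to
missing values unless ``calc_for_incomplete`` is set, in which case edge
bouts are simply assumed complete.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AccelSeries
from .laterality import LEFT, RIGHT
from .posture import LYING, STANDING, Bout

__all__ = ["overlap_weight", "summarize_bouts", "summarize_intervals"]


def _overlap_seconds(b_start, b_end, i_start, i_end) -> float:
    lo = max(b_start, i_start)
    hi = min(b_end, i_end)
    return max((hi - lo).total_seconds(), 0.0)


def overlap_weight(bout: Bout, interval: tuple[pd.Timestamp, pd.Timestamp]) -> float:
    """Fraction of the bout's duration falling inside the interval.

    weight = duration(bout ∩ interval) / duration(bout); a bout fully
    inside the interval has weight 1, a disjoint one 0.
    """
    i_start, i_end = interval
    if i_end < i_start:
        raise ValueError("interval end before start")
    dur = bout.duration
    if dur <= 0:
        raise ValueError("bout has non-positive duration")
    return _overlap_seconds(bout.start, bout.end, i_start, i_end) / dur


def _bout_activity_means(
    series: AccelSeries | None, activity: pd.DataFrame | None, n_bouts: int
) -> pd.DataFrame | None:
    if activity is None or series is None:
        return None
    if "bout_index" not in series.data.columns:
        raise ValueError("series lacks bout annotation; run add_lying first")
    grp = activity.groupby(series.data["bout_index"].to_numpy())
    means = grp.mean()
    return means.reindex(range(n_bouts))


def summarize_bouts(
    bouts: list[Bout],
    series: AccelSeries | None = None,
    activity: pd.DataFrame | None = None,
    calc_for_incomplete: bool = False,
) -> pd.DataFrame:
    """One summary row per bout.

    Duration is missing for bouts not bounded by observed transitions on
    both sides, unless ``calc_for_incomplete`` forces them to be treated
    as complete.  When a per-sample activity table is supplied (with its
    parent series, for the sample-to-bout mapping), a ``mean_<measure>``
    column is added per measure.
    """
    rows = {
        "id": [b.cow_id for b in bouts],
        "bout": [b.index for b in bouts],
        "posture": [b.posture for b in bouts],
        "start": [b.start for b in bouts],
        "end": [b.end for b in bouts],
        "duration_s": [
            b.duration if (b.complete or calc_for_incomplete) else np.nan for b in bouts
        ],
        "side": [b.side for b in bouts],
        "complete_start": [b.complete_start for b in bouts],
        "complete_end": [b.complete_end for b in bouts],
    }
    out = pd.DataFrame(rows)
    means = _bout_activity_means(series, activity, len(bouts))
    if means is not None:
        for m in means.columns:
            out[f"mean_{m}"] = means[m].to_numpy()
    return out


def _regular_intervals(
    rec_start: pd.Timestamp,
    rec_end: pd.Timestamp,
    interval_seconds: float,
    anchor: pd.Timestamp | None,
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    if interval_seconds <= 0:
        raise ValueError("interval duration must be positive")
    step = pd.Timedelta(seconds=interval_seconds)
    if anchor is None:
        anchor = rec_start.normalize()  # midnight of the first day present
    k = int(np.floor((rec_start - anchor) / step))
    start = anchor + k * step
    intervals = []
    while start < rec_end:
        intervals.append((start, start + step))
        start = start + step
    if not intervals:  # zero-span recording still gets its interval
        intervals.append((start, start + step))
    return intervals


def summarize_intervals(
    series: AccelSeries,
    bouts: list[Bout],
    activity: pd.DataFrame | None = None,
    interval_seconds: float = 86400.0,
    anchor: pd.Timestamp | None = None,
    calc_for_incomplete: bool = False,
) -> pd.DataFrame:
    """Summaries over consecutive half-open intervals [start, end).

    Intervals are anchored at ``anchor`` (default: midnight of the first
    day in the recording) and cover the recording span.  Durations are
    exact bout-interval overlaps; bout counts and mean bout durations are
    weighted by :func:`overlap_weight`.  Any weighted quantity touching
    an edge-incomplete bout is missing unless ``calc_for_incomplete``.
    Mean activity is the plain mean over samples in the interval.
    """
    rec_start = bouts[0].start if bouts else series.data["time"].iloc[0]
    rec_end = bouts[-1].end if bouts else series.data["time"].iloc[-1]
    intervals = _regular_intervals(rec_start, rec_end, interval_seconds, anchor)

    times = series.data["time"].to_numpy()
    rows = []
    for i_start, i_end in intervals:
        row: dict[str, object] = {
            "id": series.cow_id,
            "interval_start": i_start,
            "interval_end": i_end,
        }
        for posture in (LYING, STANDING):
            sel = [b for b in bouts if b.posture == posture
                   and _overlap_seconds(b.start, b.end, i_start, i_end) > 0]
            total = sum(_overlap_seconds(b.start, b.end, i_start, i_end) for b in sel)
            row[f"duration_{posture}_s"] = total
            if posture == LYING:
                for side, name in ((LEFT, "duration_lying_left_s"),
                                   (RIGHT, "duration_lying_right_s")):
                    row[name] = sum(
                        _overlap_seconds(b.start, b.end, i_start, i_end)
                        for b in sel if b.side == side
                    )
            suppressed = any(not b.complete for b in sel) and not calc_for_incomplete
            if suppressed:
                row[f"n_bouts_{posture}"] = np.nan
                row[f"mean_duration_{posture}_s"] = np.nan
            else:
                weights = np.array([overlap_weight(b, (i_start, i_end)) for b in sel])
                durs = np.array([b.duration for b in sel])
                wsum = float(weights.sum())
                row[f"n_bouts_{posture}"] = wsum
                row[f"mean_duration_{posture}_s"] = (
                    float((weights * durs).sum() / wsum) if wsum > 0 else np.nan
                )
        if activity is not None:
            in_iv = (times >= i_start.to_datetime64()) & (times < i_end.to_datetime64())
            for m in activity.columns:
                vals = activity.loc[in_iv, m]
                row[f"mean_{m}"] = float(vals.mean()) if in_iv.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
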