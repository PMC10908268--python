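"""Extraction of raw-data windows around posture transitions.

Lie-down (standing-to-lying) and stand-up (lying-to-standing) movements
are of interest in their own right, e.g. as regions of interest for
downstream movement-pattern analysis.  The transition time is the first
sample of the new posture, the same convention the bout segmentation
uses; recording edges are not transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import AccelSeries
from .posture import LYING, Bout

__all__ = ["TransitionWindow", "extract_liedown", "extract_standup"]

LIEDOWN = "liedown"
STANDUP = "standup"


@dataclass
class TransitionWindow:
    """Samples of the annotated series within [time - sec_before,
    time + sec_after] (closed bounds) around one transition.
    ``truncated`` flags windows clipped by the recording edges."""

    cow_id: str
    kind: str
    time: pd.Timestamp
    data: pd.DataFrame
    truncated: bool


def _extract(
    series: AccelSeries,
    bouts: list[Bout],
    kind: str,
    sec_before: float,
    sec_after: float,
) -> list[TransitionWindow]:
    if sec_before < 0 or sec_after < 0:
        raise ValueError("sec_before and sec_after must be >= 0")
    times = series.data["time"]
    rec_start, rec_end = times.iloc[0], times.iloc[-1]
    windows = []
    for b in bouts:
        if b.posture != LYING:
            continue
        if kind == LIEDOWN:
            if not b.complete_start:
                continue
            t = b.start
        else:
            if not b.complete_end:
                continue
            t = b.end
        lo = t - pd.Timedelta(seconds=sec_before)
        hi = t + pd.Timedelta(seconds=sec_after)
        mask = (times >= lo) & (times <= hi)
        windows.append(
            TransitionWindow(
                cow_id=series.cow_id,
                kind=kind,
                time=t,
                data=series.data.loc[mask].copy(),
                truncated=bool(lo < rec_start or hi > rec_end),
            )
        )
    return windows


def extract_liedown(
    series: AccelSeries, bouts: list[Bout], sec_before: float = 60.0, sec_after: float = 60.0
) -> list[TransitionWindow]:
    """One window per observed standing-to-lying transition."""
    return _extract(series, bouts, LIEDOWN, sec_before, sec_after)


def extract_standup(
    series: AccelSeries, bouts: list[Bout], sec_before: float = 60.0, sec_after: float = 60.0
) -> list[TransitionWindow]:
    """One window per observed lying-to-standing transition."""
    return _extract(series, bouts, STANDUP, sec_before, sec_after)


def windows_to_frame(windows: list[TransitionWindow]) -> pd.DataFrame:
    """Long-format table of all windows with a window id column."""
    frames = []
    for i, w in enumerate(windows):
        df = w.data.copy()
        df.insert(0, "window", i)
        df.insert(1, "kind", w.kind)
        df.insert(2, "transition_time", w.time)
        df.insert(3, "truncated", w.truncated)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["window", "kind", "transition_time", "truncated", "time",
                     "acc_fwd", "acc_up", "acc_right"]
        )
    return pd.concat(frames, ignore_index=True)
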