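"""Lying/standing classification and bout segmentation.

A standing cow's metatarsus is near-vertical, so the gravity component
loads ~1 g on the body-upward axis; lying rotates the leg toward the
horizontal and the upward loading drops toward 0.  Classification is a
three-step rule: (1) filter the upward channel to its gravity component,
(2) threshold it at ``crit_lie`` (default 0.5 g, i.e. a leg angle of
arccos(0.5) = 60 deg from vertical), (3) remove lying bouts shorter than
a minimum duration (default 30 s) by reclassifying them as standing,
which rejects brief leg-lift artifacts during grooming.

Standing is defined as "not lying": the two postures are mutually
exclusive and collectively exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .filters import FilterParams, gravity_component
from .io import AccelSeries

__all__ = [
    "PostureParams",
    "Bout",
    "classify_samples",
    "segment_bouts",
    "enforce_min_duration",
    "add_lying",
    "bouts_to_frame",
]

LYING = "lying"
STANDING = "standing"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class PostureParams:
    """Parameters of the posture classifier.

    crit_lie : threshold on the filtered upward gravity component (g).
        Values below it are lying, at or above it standing.
    minimum_duration_lying : lying bouts shorter than this (seconds) are
        reclassified as standing.  Default 30 s.
    minimum_duration_standing : optional analogous minimum for standing
        bouts; off by default (short standing bouts are real — they occur
        when the cow changes lying side — and reliably detected).
    filter : gravity-filter configuration.
    """

    crit_lie: float = 0.5
    minimum_duration_lying: float = 30.0
    minimum_duration_standing: float | None = None
    filter: FilterParams = field(default_factory=FilterParams)

    def __post_init__(self) -> None:
        if not 0 < self.crit_lie <= 1:
            raise ValueError("crit_lie must be in (0, 1] g")
        if self.minimum_duration_lying < 0:
            raise ValueError("minimum_duration_lying must be >= 0")
        if self.minimum_duration_standing is not None and self.minimum_duration_standing < 0:
            raise ValueError("minimum_duration_standing must be >= 0")


@dataclass
class Bout:
    """A maximal run of one posture.

    ``end`` is the start of the next bout (the recording's last timestamp
    for the final bout); bouts therefore tile the recording without gaps
    or overlaps.  ``complete_start``/``complete_end`` record whether the
    boundary is an observed posture transition rather than the edge of
    the recording; edge bouts have unknown true duration.
    """

    cow_id: str
    index: int
    posture: str
    start: pd.Timestamp
    end: pd.Timestamp
    complete_start: bool
    complete_end: bool
    side: str = UNASSIGNED

    @property
    def duration(self) -> float:
        """Duration in seconds, from timestamps."""
        return (self.end - self.start).total_seconds()

    @property
    def complete(self) -> bool:
        return self.complete_start and self.complete_end


def classify_samples(gravity_up: np.ndarray, crit_lie: float) -> np.ndarray:
    """Boolean per-sample lying flag: lying iff filtered upward < crit_lie.

    A value exactly at the threshold is standing (the defined complement
    of lying).
    """
    g = np.asarray(gravity_up, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("gravity trace contains non-finite values")
    return g < crit_lie


def segment_bouts(
    lying: np.ndarray,
    times: pd.Series | np.ndarray,
    cow_id: str = "unknown",
) -> list[Bout]:
    """Run-length encode a per-sample posture sequence into bouts.

    A bout starts at the timestamp of its first sample and ends at the
    first sample of the next bout; the last bout ends at the recording's
    final timestamp.  The first bout's start and the last bout's end are
    flagged incomplete.
    """
    lying = np.asarray(lying, dtype=bool)
    t = pd.to_datetime(pd.Series(np.asarray(times))).reset_index(drop=True)
    if lying.size == 0:
        raise ValueError("cannot segment an empty posture sequence")
    if lying.size != len(t):
        raise ValueError("posture sequence and times differ in length")

    change = np.nonzero(np.diff(lying))[0] + 1
    starts = np.concatenate(([0], change))
    bouts: list[Bout] = []
    for k, s in enumerate(starts):
        nxt = starts[k + 1] if k + 1 < len(starts) else None
        end = t.iloc[nxt] if nxt is not None else t.iloc[len(t) - 1]
        bouts.append(
            Bout(
                cow_id=cow_id,
                index=k,
                posture=LYING if lying[s] else STANDING,
                start=t.iloc[s],
                end=end,
                complete_start=k > 0,
                complete_end=nxt is not None,
            )
        )
    return bouts


def _merge_runs(bouts: list[Bout]) -> list[Bout]:
    """Merge consecutive equal-posture bouts into maximal runs."""
    merged: list[Bout] = []
    for b in bouts:
        if merged and merged[-1].posture == b.posture:
            last = merged[-1]
            merged[-1] = Bout(
                cow_id=last.cow_id,
                index=last.index,
                posture=last.posture,
                start=last.start,
                end=b.end,
                complete_start=last.complete_start,
                complete_end=b.complete_end,
            )
        else:
            merged.append(
                Bout(
                    cow_id=b.cow_id,
                    index=len(merged),
                    posture=b.posture,
                    start=b.start,
                    end=b.end,
                    complete_start=b.complete_start,
                    complete_end=b.complete_end,
                )
            )
    for i, b in enumerate(merged):
        b.index = i
    return merged


def _remove_short(bouts: list[Bout], posture: str, minimum: float) -> list[Bout]:
    relabeled = []
    other = STANDING if posture == LYING else LYING
    for b in bouts:
        p = b.posture
        # Edge bouts are exempt: their observed duration is only a lower
        # bound on the true one.
        if p == posture and b.complete and b.duration < minimum:
            p = other
        relabeled.append(
            Bout(
                cow_id=b.cow_id,
                index=b.index,
                posture=p,
                start=b.start,
                end=b.end,
                complete_start=b.complete_start,
                complete_end=b.complete_end,
            )
        )
    return _merge_runs(relabeled)


def enforce_min_duration(bouts: list[Bout], params: PostureParams) -> list[Bout]:
    """Minimum-duration correction of a bout list.

    One pass relabels interior lying bouts shorter than
    ``minimum_duration_lying`` as standing and merges the result; if
    ``minimum_duration_standing`` is set, a second pass does the same for
    standing bouts.  Passes are applied once each, not iterated.
    """
    if not bouts:
        return []
    out = _remove_short(bouts, LYING, params.minimum_duration_lying)
    if params.minimum_duration_standing is not None:
        out = _remove_short(out, STANDING, params.minimum_duration_standing)
    return out


def _sample_bout_index(times: pd.Series, bouts: list[Bout]) -> np.ndarray:
    starts = np.array([b.start.to_datetime64() for b in bouts])
    idx = np.searchsorted(starts, times.to_numpy(), side="right") - 1
    return np.clip(idx, 0, len(bouts) - 1)


def add_lying(series: AccelSeries, params: PostureParams | None = None) -> list[Bout]:
    """Classify a series into lying/standing and segment it into bouts.

    Runs gravity filtering, thresholding, run-length segmentation and
    minimum-duration correction, then annotates ``series.data`` in place
    with boolean ``lying`` and integer ``bout_index`` columns consistent
    with the corrected bout list.  Returns the bouts.
    """
    if params is None:
        params = PostureParams()
    g_up = gravity_component(series, "upward", params.filter)
    lying = classify_samples(g_up, params.crit_lie)
    bouts = segment_bouts(lying, series.data["time"], series.cow_id)
    bouts = enforce_min_duration(bouts, params)
    bout_idx = _sample_bout_index(series.data["time"], bouts)
    series.data["lying"] = np.array([b.posture == LYING for b in bouts])[bout_idx]
    series.data["bout_index"] = bout_idx
    return bouts


def bouts_to_frame(bouts: Sequence[Bout]) -> pd.DataFrame:
    """Tabular view of a bout list."""
    return pd.DataFrame(
        {
            "id": [b.cow_id for b in bouts],
            "bout": [b.index for b in bouts],
            "posture": [b.posture for b in bouts],
            "start": [b.start for b in bouts],
            "end": [b.end for b in bouts],
            "duration_s": [b.duration for b in bouts],
            "side": [b.side for b in bouts],
            "complete_start": [b.complete_start for b in bouts],
            "complete_end": [b.complete_end for b in bouts],
        }
    )
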