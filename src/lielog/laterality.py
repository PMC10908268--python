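"""Lying-side (laterality) assignment.

When the cow lies on the leg carrying the sensor, the body-right axis
loads close to +1 g (left hind leg) or -1 g (right hind leg).  On the
opposite side the free leg can bend toward the head, shifting gravity
loading onto the forward axis, so right-axis values range from about
-1 g up to about 0 (left-leg sensor).  The threshold ``crit_left`` is
therefore shifted toward the sensor side: +0.5 g for a left-leg sensor,
-0.5 g for a right-leg one.  A bout is assigned "left" when the majority
of its raw right-axis samples exceed the threshold — equivalently, when
their median does — and one side covers the whole bout, because a side
change passes through a short standing bout that splits the lying bout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import AccelSeries
from .posture import LYING, UNASSIGNED, Bout, _sample_bout_index

__all__ = ["LateralityParams", "assign_side", "LEFT", "RIGHT"]

LEFT = "left"
RIGHT = "right"


@dataclass(frozen=True)
class LateralityParams:
    """left_leg: sensor on the left hind leg; crit_left: threshold in g
    (default +0.5 if left_leg else -0.5)."""

    left_leg: bool | None = None
    crit_left: float | None = None

    def __post_init__(self) -> None:
        if self.crit_left is None and self.left_leg is None:
            raise ValueError(
                "specify left_leg (which hind leg carries the sensor) or an "
                "explicit crit_left threshold"
            )
        if self.crit_left is not None and not -1 <= self.crit_left <= 1:
            raise ValueError("crit_left must be in [-1, 1] g")

    @property
    def threshold(self) -> float:
        if self.crit_left is not None:
            return self.crit_left
        return 0.5 if self.left_leg else -0.5


def assign_side(
    series: AccelSeries,
    bouts: list[Bout],
    params: LateralityParams,
) -> list[Bout]:
    """Set ``side`` on every lying bout from the raw right-axis median.

    Mutates the bouts in place (and adds a per-sample ``side`` column to
    ``series.data``); standing bouts keep side "unassigned".  An exact
    tie between median and threshold is resolved to the side away from
    the sensor, with a warning.
    """
    if not bouts:
        return bouts
    right = series.data["acc_right"].to_numpy(float)
    if "bout_index" in series.data.columns:
        idx = series.data["bout_index"].to_numpy()
    else:
        idx = _sample_bout_index(series.data["time"], bouts)
    crit = params.threshold
    for b in bouts:
        if b.posture != LYING:
            b.side = UNASSIGNED
            continue
        vals = right[idx == b.index]
        if vals.size == 0:
            raise ValueError(f"lying bout {b.index} contains no samples")
        med = float(np.median(vals))
        if med > crit:
            b.side = LEFT
        elif med < crit:
            b.side = RIGHT
        else:
            away = RIGHT if (params.left_leg is None or params.left_leg) else LEFT
            warnings.warn(
                f"cow {b.cow_id!r} bout {b.index}: right-axis median exactly at "
                f"crit_left={crit} g; assigning side {away!r} (away from sensor)",
                stacklevel=2,
            )
            b.side = away
    sides = np.array([b.side for b in bouts], dtype=object)
    series.data["side"] = sides[idx]
    return bouts
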