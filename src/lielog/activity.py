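"""Physical-activity proxies from the triaxial signal.

Dynamic body acceleration (DBA) is the measured acceleration minus its
static gravity component (same filter defaults and options as posture
detection).  Jerk, the time derivative of acceleration, is approximated
by backward finite differences of the raw signal.  Either vector is
aggregated per sample into its L1 norm (sum of absolute components; the
classic ODBA when applied to DBA) or L2 norm (Euclidean magnitude,
VeDBA), which is rotation invariant and hence unaffected by sensor
orientation.

By default activity is "adjusted": samples inside lying bouts are set
to 0, treating lying as inactive by definition.  Unadjusted values
during lying carry a laterality bias (the leg under the cow is pinned,
the free leg moves) and should be interpreted with caution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import FilterParams, gravity_component
from .io import AccelSeries
from .posture import Bout

__all__ = [
    "ActivityParams",
    "MEASURES",
    "dynamic_body_acceleration",
    "jerk",
    "norm_l1",
    "norm_l2",
    "add_activity",
]

log = logging.getLogger(__name__)

MEASURES = ("L1DBA", "L2DBA", "L1Jerk", "L2Jerk")
_ACC_COLS = ["acc_fwd", "acc_up", "acc_right"]


@dataclass(frozen=True)
class ActivityParams:
    """measures: subset of L1DBA/L2DBA/L1Jerk/L2Jerk (default L2DBA);
    adjust: zero activity inside lying bouts; filter: gravity filter for
    the DBA estimate."""

    measures: tuple[str, ...] = ("L2DBA",)
    adjust: bool = True
    filter: FilterParams = field(default_factory=FilterParams)

    def __post_init__(self) -> None:
        if not self.measures:
            raise ValueError("at least one activity measure must be requested")
        unknown = [m for m in self.measures if m not in MEASURES]
        if unknown:
            raise ValueError(f"unknown measure(s) {unknown}; choose from {MEASURES}")


def dynamic_body_acceleration(
    series: AccelSeries, filter_params: FilterParams | None = None
) -> pd.DataFrame:
    """Per-sample DBA 3-vector: raw acceleration minus gravity, per axis (g)."""
    if filter_params is None:
        filter_params = FilterParams()
    out = {}
    for axis, col in zip(("forward", "upward", "right"), _ACC_COLS):
        grav = gravity_component(series, axis, filter_params)
        out[col.replace("acc", "dba")] = series.data[col].to_numpy(float) - grav
    return pd.DataFrame(out)


def jerk(series: AccelSeries) -> pd.DataFrame:
    """Backward-difference jerk 3-vector (g/s), computed on raw acceleration.

    j(t_i) = (a(t_i) - a(t_{i-1})) / (t_i - t_{i-1}); the first sample
    has no predecessor and is missing (NaN), not zero.
    """
    if len(series) < 2:
        raise ValueError("jerk needs at least 2 samples")
    t = series.data["time"].to_numpy().astype("datetime64[ns]").astype(np.int64) / 1e9
    dt = np.diff(t)
    out = {}
    for col in _ACC_COLS:
        a = series.data[col].to_numpy(float)
        j = np.empty_like(a)
        j[0] = np.nan
        j[1:] = np.diff(a) / dt
        out[col.replace("acc", "jerk")] = j
    return pd.DataFrame(out)


def norm_l1(vectors: pd.DataFrame | np.ndarray) -> np.ndarray:
    """L1 norm per sample: |v_fwd| + |v_up| + |v_right|."""
    return np.abs(np.asarray(vectors, dtype=float)).sum(axis=-1)


def norm_l2(vectors: pd.DataFrame | np.ndarray) -> np.ndarray:
    """L2 norm per sample: sqrt(v_fwd^2 + v_up^2 + v_right^2)."""
    v = np.asarray(vectors, dtype=float)
    return np.sqrt((v * v).sum(axis=-1))


def add_activity(
    series: AccelSeries,
    bouts: list[Bout] | None = None,
    params: ActivityParams | None = None,
) -> pd.DataFrame:
    """Compute the requested activity measures per sample.

    Returns a DataFrame aligned with ``series.data`` holding one column
    per requested measure, and adds the same columns to ``series.data``
    in place.  With ``adjust=True`` (default) samples inside lying bouts
    are set to exactly 0, which requires posture annotation first; the
    unadjusted values are preserved in the result's
    ``attrs["unadjusted"]`` so a rerun with ``adjust=False`` needs no
    recomputation.
    """
    if params is None:
        params = ActivityParams()
    if params.adjust:
        if "lying" not in series.data.columns:
            raise ValueError(
                "adjust=True requires posture annotation; run add_lying first "
                "or pass adjust=False"
            )
        lying_mask = series.data["lying"].to_numpy(bool)
    else:
        log.warning(
            "adjust=False: non-zero activity during lying bouts is biased by "
            "lying side and should be interpreted with caution"
        )
        lying_mask = None

    need_dba = any(m.endswith("DBA") for m in params.measures)
    need_jerk = any(m.endswith("Jerk") for m in params.measures)
    dba = dynamic_body_acceleration(series, params.filter) if need_dba else None
    jrk = jerk(series) if need_jerk else None

    raw = pd.DataFrame(index=series.data.index)
    for m in params.measures:
        vec = dba if m.endswith("DBA") else jrk
        raw[m] = norm_l1(vec) if m.startswith("L1") else norm_l2(vec)

    out = raw.copy()
    if lying_mask is not None:
        out.loc[lying_mask, :] = 0.0
    out.attrs["adjusted"] = bool(params.adjust)
    out.attrs["unadjusted"] = raw
    for m in params.measures:
        series.data[m] = out[m].to_numpy()
    return out
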