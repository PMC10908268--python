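"""Static-gravity extraction from an acceleration channel.

A leg-mounted accelerometer measures the vector sum of the static
gravitational component (orientation of the leg in the gravity field)
and the dynamic body acceleration from movement.  Posture analysis needs
the static part only, obtained by low-pass filtering in the time domain
(moving median, the default) or the frequency domain (zero-phase
Butterworth low-pass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io import AccelSeries

__all__ = ["FilterParams", "moving_median", "butter_zerophase", "gravity_component"]

_AXIS_COLUMNS = {"forward": "acc_fwd", "upward": "acc_up", "right": "acc_right"}


@dataclass(frozen=True)
class FilterParams:
    """Gravity-filter configuration.

    method : ``"median"`` (moving median, window in seconds) or
        ``"butterworth"`` (bidirectional low-pass).
    window_size : median window in seconds (default 10 s).
    cutoff : Butterworth cutoff frequency in Hz (default 0.1 Hz).
    order : Butterworth order (default 1).
    """

    method: str = "median"
    window_size: float = 10.0
    cutoff: float = 0.1
    order: int = 1

    def __post_init__(self) -> None:
        if self.method not in ("median", "butterworth"):
            raise ValueError(f"unknown filter method {self.method!r}")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def _odd_window_samples(window_size: float, sampling_interval: float) -> int:
    if window_size <= 0 or sampling_interval <= 0:
        raise ValueError("window_size and sampling_interval must be positive")
    n = int(round(window_size / sampling_interval))
    if n < 1:
        raise ValueError(
            f"window of {window_size} s is shorter than one sample at "
            f"{sampling_interval} s intervals"
        )
    return n + 1 if n % 2 == 0 else n


def moving_median(
    values: np.ndarray | pd.Series,
    window_size: float,
    sampling_interval: float,
) -> np.ndarray:
    """Centered moving median over a window of ``window_size`` seconds.

    The window length in samples is ``round(window_size / interval)``,
    bumped to the next odd count so the center is unambiguous.  At the
    series edges the window shrinks to the available samples, keeping the
    output aligned 1:1 with the input.
    """
    x = pd.Series(np.asarray(values, dtype=float))
    if x.empty:
        raise ValueError("cannot filter an empty series")
    n = _odd_window_samples(window_size, sampling_interval)
    return x.rolling(n, center=True, min_periods=1).median().to_numpy()


def butter_zerophase(
    values: np.ndarray | pd.Series,
    cutoff: float,
    order: int,
    sampling_rate: float,
) -> np.ndarray:
    """Bidirectional (zero-lag) Butterworth low-pass.

    The filter is applied forward then backward, cancelling the phase
    shift.  Edge transients are damped with odd-symmetric signal
    extension of 3*(order+1) samples per end; very short inputs fall
    back to the longest feasible extension.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot filter an empty series")
    nyq = sampling_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below the Nyquist frequency {nyq} Hz")
    if x.size == 1:
        return x.copy()
    b, a = signal.butter(order, cutoff / nyq, btype="low")
    padlen = min(3 * (order + 1), x.size - 1)
    return signal.filtfilt(b, a, x, padtype="odd", padlen=padlen)


def gravity_component(
    series: AccelSeries,
    axis: str,
    params: FilterParams | None = None,
) -> np.ndarray:
    """Gravity estimate on one body axis of a series.

    Dispatches to :func:`moving_median` or :func:`butter_zerophase`
    using the series' inferred sampling interval.  A single-sample series
    is its own gravity estimate.
    """
    if params is None:
        params = FilterParams()
    if axis not in _AXIS_COLUMNS:
        raise ValueError(f"axis must be one of {sorted(_AXIS_COLUMNS)}, got {axis!r}")
    values = series.data[_AXIS_COLUMNS[axis]].to_numpy(float)
    if len(values) == 1:
        return values.copy()
    interval = series.sampling_interval()
    if params.method == "median":
        return moving_median(values, params.window_size, interval)
    return butter_zerophase(values, params.cutoff, params.order, 1.0 / interval)
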