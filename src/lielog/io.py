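"""Reading raw accelerometer logs and prepared tables.

Hind-leg accelerometer loggers emit one delimiter-separated text file per
animal: a timestamp column plus three acceleration channels (X, Y, Z) in
units of g.  Depending on the manufacturer and how the housing is strapped
to the metatarsus, the sensor's XYZ axes point in arbitrary body
directions, so after parsing, the channels are renamed to body-relative
axes (*forward*, *upward*, *right*, defined for a standing cow) via a
signed axis permutation (:class:`AxisMap`).

The in-memory container is :class:`AccelSeries`: one cow, strictly
increasing timestamps, finite accelerations in g.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "AxisMap",
    "FileFormatSpec",
    "AccelSeries",
    "parse_file",
    "map_axes",
    "load_files",
    "load_table",
    "infer_sampling_interval",
]

#: required column names for prepared tables
TABLE_COLUMNS = ("id", "time", "acc_fwd", "acc_up", "acc_right")

_SENSOR_CHANNELS = ("X", "Y", "Z")
_BODY_AXES = ("forward", "upward", "right")
_BODY_COLUMNS = {"forward": "acc_fwd", "upward": "acc_up", "right": "acc_right"}


@dataclass(frozen=True)
class AxisMap:
    """Signed bijection from sensor channels (X/Y/Z) to body axes.

    Each body axis is assigned a ``(channel, sign)`` pair, e.g.
    ``AxisMap(forward=("X", 1), upward=("Z", -1), right=("Y", 1))`` means
    the body-upward acceleration is minus the sensor's Z channel.
    """

    forward: tuple[str, int] = ("X", 1)
    upward: tuple[str, int] = ("Y", 1)
    right: tuple[str, int] = ("Z", 1)

    def __post_init__(self) -> None:
        channels = [self.forward[0], self.upward[0], self.right[0]]
        if sorted(channels) != sorted(_SENSOR_CHANNELS):
            raise ValueError(
                f"axis map must use each of X, Y, Z exactly once, got {channels}"
            )
        for axis in (self.forward, self.upward, self.right):
            if axis[1] not in (1, -1):
                raise ValueError(f"axis sign must be +1 or -1, got {axis[1]}")

    def as_dict(self) -> dict[str, tuple[str, int]]:
        return {"forward": self.forward, "upward": self.upward, "right": self.right}

    def inverse(self) -> dict[str, tuple[str, int]]:
        """Mapping sensor channel -> (body axis, sign), the inverse bijection."""
        return {ch: (axis, sign) for axis, (ch, sign) in self.as_dict().items()}


@dataclass(frozen=True)
class FileFormatSpec:
    """Layout of a raw delimiter-separated accelerometer file.

    Attributes
    ----------
    sep : single-character separator or regex.
    skip_header : number of leading non-data lines.
    timestamp_col : zero-based column index of the timestamp.
    timestamp_format : strptime-style format string.
    col_x, col_y, col_z : zero-based indices of the acceleration channels.
    decimal : decimal mark used in the file.
    cow_id_pattern : optional regex with one group, applied to the file's
        base name to extract the cow id; when ``None`` the base name
        (without extension) is the id.
    """

    sep: str = ","
    skip_header: int = 0
    timestamp_col: int = 0
    timestamp_format: str = "%Y-%m-%d %H:%M:%S.%f"
    col_x: int = 1
    col_y: int = 2
    col_z: int = 3
    decimal: str = "."
    cow_id_pattern: str | None = None

    def __post_init__(self) -> None:
        idx = [self.timestamp_col, self.col_x, self.col_y, self.col_z]
        if len(set(idx)) != 4:
            raise ValueError(f"timestamp and channel column indices must be distinct, got {idx}")
        if any(i < 0 for i in idx):
            raise ValueError("column indices must be non-negative")

    def cow_id_from_path(self, path: str | os.PathLike) -> str:
        base = os.path.basename(os.fspath(path))
        if self.cow_id_pattern is None:
            return os.path.splitext(base)[0]
        m = re.search(self.cow_id_pattern, base)
        if m is None or not m.groups():
            raise ValueError(
                f"cow id pattern {self.cow_id_pattern!r} did not match file name {base!r}"
            )
        return m.group(1)


@dataclass
class AccelSeries:
    """Per-cow time series of body-relative acceleration.

    ``data`` holds at least columns ``time`` (timezone-naive datetime),
    ``acc_fwd``, ``acc_up``, ``acc_right`` (floats, units g).  Analysis
    steps append columns (``lying``, ``bout_index``, ``side``, activity
    measures) in place, mirroring a sequential annotate-as-you-go
    workflow.
    """

    cow_id: str
    data: pd.DataFrame
    _sampling_interval: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        for col in ("time", "acc_fwd", "acc_up", "acc_right"):
            if col not in df.columns:
                raise ValueError(f"AccelSeries data lacks required column {col!r}")
        if len(df) == 0:
            raise ValueError(f"cow {self.cow_id!r}: empty series")
        t = df["time"].to_numpy()
        dt = np.diff(t.astype("datetime64[ns]").astype(np.int64))
        if np.any(dt == 0):
            raise ValueError(f"cow {self.cow_id!r}: duplicate timestamps")
        if np.any(dt < 0):
            i = int(np.argmax(dt < 0))
            raise ValueError(
                f"cow {self.cow_id!r}: non-monotonic time at row {i + 1} "
                f"({df['time'].iloc[i + 1]} after {df['time'].iloc[i]})"
            )
        acc = df[["acc_fwd", "acc_up", "acc_right"]].to_numpy(float)
        if not np.all(np.isfinite(acc)):
            bad = int(np.argwhere(~np.isfinite(acc))[0, 0])
            raise ValueError(f"cow {self.cow_id!r}: non-finite acceleration at row {bad}")
        if len(df) >= 3:
            med = float(np.median(dt)) / 1e9
            gaps = np.nonzero(dt / 1e9 > 10.0 * med)[0]
            if gaps.size:
                locs = ", ".join(str(df["time"].iloc[i]) for i in gaps[:5])
                warnings.warn(
                    f"cow {self.cow_id!r}: {gaps.size} gap(s) exceeding 10x the nominal "
                    f"sampling interval (first at {locs}); samples are treated as "
                    f"contiguous for filtering",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def times(self) -> pd.Series:
        return self.data["time"]

    def sampling_interval(self) -> float:
        """Nominal sampling interval in seconds (cached median of diffs)."""
        if self._sampling_interval is None:
            self._sampling_interval = infer_sampling_interval(self)
        return self._sampling_interval

    def to_frame(self) -> pd.DataFrame:
        """Export with the prepared-table column layout (id first)."""
        out = self.data.copy()
        out.insert(0, "id", self.cow_id)
        return out


def parse_file(path: str | os.PathLike, spec: FileFormatSpec) -> pd.DataFrame:
    """Parse one raw logger file into a table with columns time, X, Y, Z.

    Timestamps are parsed with ``spec.timestamp_format``; any line that
    fails to parse is reported with its 1-based line number.  The cow id
    derived from the file name is stored in ``DataFrame.attrs['cow_id']``.
    """
    path = os.fspath(path)
    try:
        raw = pd.read_csv(
            path,
            sep=spec.sep,
            skiprows=spec.skip_header,
            header=None,
            decimal=spec.decimal,
            dtype=str,
            skip_blank_lines=True,
            engine="python",
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data lines after skipping {spec.skip_header} header line(s)")
    width = raw.shape[1]
    for name, idx in (("timestamp", spec.timestamp_col), ("X", spec.col_x),
                      ("Y", spec.col_y), ("Z", spec.col_z)):
        if idx >= width:
            raise ValueError(
                f"{path}: {name} column index {idx} out of range for {width}-column file"
            )

    times = pd.to_datetime(raw.iloc[:, spec.timestamp_col],
                           format=spec.timestamp_format, errors="coerce")
    if times.isna().any():
        bad = np.nonzero(times.isna().to_numpy())[0]
        lines = [int(i) + spec.skip_header + 1 for i in bad[:5]]
        raise ValueError(
            f"{path}: {len(bad)} timestamp(s) do not match format "
            f"{spec.timestamp_format!r} (line(s) {lines})"
        )
    dt_ns = np.diff(times.to_numpy().astype("datetime64[ns]").astype(np.int64))
    if np.any(dt_ns <= 0):
        i = int(np.argmax(dt_ns <= 0))
        line = i + 1 + spec.skip_header + 1
        kind = "duplicate" if dt_ns[i] == 0 else "non-monotonic"
        raise ValueError(f"{path}: {kind} timestamp at line {line}")

    out = pd.DataFrame({"time": times.to_numpy()})
    for name, idx in (("X", spec.col_x), ("Y", spec.col_y), ("Z", spec.col_z)):
        col = raw.iloc[:, idx]
        if spec.decimal != ".":
            col = col.str.replace(spec.decimal, ".", regex=False)
        vals = pd.to_numeric(col, errors="coerce")
        if vals.isna().any():
            bad = int(np.nonzero(vals.isna().to_numpy())[0][0])
            raise ValueError(
                f"{path}: unparseable {name} value {col.iloc[bad]!r} at line "
                f"{bad + spec.skip_header + 1}"
            )
        out[name] = vals.to_numpy(float)
    out.attrs["cow_id"] = spec.cow_id_from_path(path)
    return out


def map_axes(raw: pd.DataFrame, axis_map: AxisMap, cow_id: str | None = None) -> AccelSeries:
    """Rename sensor XYZ channels to body-relative axes.

    Per sample ``acc_<axis> = sign * channel``; time is untouched.  The
    mapping is an isometry: the L2 magnitude of each sample is preserved.
    """
    if cow_id is None:
        cow_id = raw.attrs.get("cow_id", "unknown")
    data = pd.DataFrame({"time": raw["time"].to_numpy()})
    for axis, (channel, sign) in axis_map.as_dict().items():
        data[_BODY_COLUMNS[axis]] = sign * raw[channel].to_numpy(float)
    return AccelSeries(cow_id=str(cow_id), data=data)


def load_files(
    paths: Iterable[str | os.PathLike],
    spec: FileFormatSpec,
    axis_map: AxisMap,
) -> list[AccelSeries]:
    """Parse several raw files (one per cow) and map their axes."""
    series = [map_axes(parse_file(p, spec), axis_map) for p in paths]
    ids = [s.cow_id for s in series]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate cow ids across files: {ids}")
    return series


def load_table(table: pd.DataFrame) -> list[AccelSeries]:
    """Import an already-prepared table with exact column names.

    The table must contain columns ``id, time, acc_fwd, acc_up,
    acc_right``.  Rows are grouped by ``id`` (input order preserved) and
    each per-cow series is validated (strictly increasing time, finite
    accelerations).
    """
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"prepared table is missing column(s) {missing}; "
            f"expected exactly {list(TABLE_COLUMNS)}"
        )
    df = table.loc[:, list(TABLE_COLUMNS)].copy()
    df["time"] = pd.to_datetime(df["time"])
    for c in ("acc_fwd", "acc_up", "acc_right"):
        df[c] = pd.to_numeric(df[c])
    out: list[AccelSeries] = []
    for cow_id, grp in df.groupby("id", sort=False):
        out.append(AccelSeries(cow_id=str(cow_id),
                               data=grp.drop(columns="id").reset_index(drop=True)))
    return out


def infer_sampling_interval(series: AccelSeries) -> float:
    """Median of successive time differences, in seconds.

    Robust to isolated gaps.  Warns when more than 1% of the differences
    deviate from the median by more than 10%, which indicates drifting or
    mixed sampling rates.
    """
    t = series.data["time"].to_numpy().astype("datetime64[ns]").astype(np.int64)
    if t.size < 2:
        raise ValueError("need at least 2 samples to infer a sampling interval")
    dt = np.diff(t) / 1e9
    med = float(np.median(dt))
    if med <= 0:
        raise ValueError("non-positive median sampling interval")
    frac = np.mean(np.abs(dt - med) > 0.1 * med)
    if frac > 0.01:
        warnings.warn(
            f"cow {series.cow_id!r}: {frac:.1%} of sampling intervals deviate "
            f"from the nominal {med:g} s by more than 10%",
            stacklevel=2,
        )
    return med
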