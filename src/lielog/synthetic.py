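"""Synthetic hind-leg accelerometer data with known ground truth.

The simulator emulates the daily lying behavior of an adult dairy cow —
total lying time around 8–13 h per day spread over roughly 9–11 lying
bouts of 60–100 min — and renders it as a triaxial acceleration signal:

* standing: gravity ~ (0, 1, 0) g (leg vertical) plus band-limited
  gait noise;
* lying on the sensor side: gravity fully on the right axis (+1 g for a
  left-leg sensor, -1 g for a right-leg one);
* lying on the opposite side: the free leg bends toward the head to a
  per-bout random degree, so gravity loads on an arc between the right
  axis (magnitude 1) and the forward axis (right-axis reading near 0);
* posture transitions: short smooth rotations (spherical interpolation)
  of the gravity vector;
* optional confounders: standing leg-lift artifacts (gravity tilted
  toward horizontal for seconds to half a minute, as in self-grooming),
  true lying micro-bouts (~8 s), and side switches via a brief standing
  bout.

Every rendered series comes with per-sample ground-truth posture/side
labels and an episode table, so detection accuracy can be scored
exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .io import AccelSeries, AxisMap, FileFormatSpec
from .posture import LYING, STANDING

__all__ = [
    "Episode",
    "LegLift",
    "ScheduleParams",
    "SimSchedule",
    "sample_schedule",
    "render_accel",
    "write_fixture_files",
]


@dataclass(frozen=True)
class Episode:
    """One schedule entry: posture, lying side (None when standing),
    duration in seconds."""

    posture: str
    duration: float
    side: str | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("episode duration must be positive")
        if self.posture == LYING and self.side not in ("left", "right"):
            raise ValueError("lying episodes need side 'left' or 'right'")
        if self.posture == STANDING and self.side is not None:
            raise ValueError("standing episodes have no side")


@dataclass(frozen=True)
class LegLift:
    """Standing artifact: the instrumented leg lifted toward horizontal.
    ``start`` is seconds from recording start; the event must lie inside
    a standing episode."""

    start: float
    duration: float
    tilt_deg: float = 80.0


@dataclass(frozen=True)
class ScheduleParams:
    """Behavioral ranges and rendering settings of the simulator.

    The lying-behavior defaults reflect typical lactating dairy cows:
    9–11 lying bouts per day, bout durations averaging 60–100 min, total
    lying time 8–13 h.  Noise levels are in g; gait noise is band-limited
    to 0.5–3 Hz (or white at sampling rates too low to carry that band).
    """

    n_lying_bouts: tuple[int, int] = (9, 11)
    lying_bout_minutes: tuple[float, float] = (60.0, 100.0)
    total_lying_hours: tuple[float, float] = (8.0, 13.0)
    day_hours: float = 24.0
    min_standing_minutes: float = 5.0
    sampling_rate: float = 10.0
    sigma_standing: float = 0.2
    sigma_lying: float = 0.02
    transition_seconds: float = 5.0
    opposite_arc_max_deg: float = 85.0
    left_leg: bool = True
    n_leg_lifts: int = 0
    leg_lift_seconds: tuple[float, float] = (5.0, 25.0)
    leg_lift_tilt_deg: float = 80.0
    n_micro_bouts: int = 0
    micro_bout_seconds: float = 8.0
    n_side_switches: int = 0
    side_switch_seconds: float = 4.0
    start_time: str = "2024-01-01 00:00:00"


@dataclass
class SimSchedule:
    """A concrete day: alternating episodes, artifact events, and the
    rendering settings they were drawn under."""

    episodes: list[Episode]
    leg_lifts: list[LegLift] = field(default_factory=list)
    params: ScheduleParams = field(default_factory=ScheduleParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for a, b in zip(self.episodes, self.episodes[1:]):
            if a.posture == b.posture:
                raise ValueError("episodes must alternate standing and lying")
        bounds = self.episode_bounds()
        for ev in self.leg_lifts:
            inside = any(
                ep.posture == STANDING and s <= ev.start and ev.start + ev.duration <= e
                for ep, (s, e) in zip(self.episodes, bounds)
            )
            if not inside:
                raise ValueError(
                    f"leg-lift at {ev.start}s does not fit inside a standing episode"
                )

    def episode_bounds(self) -> list[tuple[float, float]]:
        """(start, end) offsets in seconds for each episode."""
        edges = np.concatenate(([0.0], np.cumsum([e.duration for e in self.episodes])))
        return list(zip(edges[:-1], edges[1:]))

    @property
    def total_seconds(self) -> float:
        return float(sum(e.duration for e in self.episodes))

    def lying_episodes(self) -> list[Episode]:
        return [e for e in self.episodes if e.posture == LYING]


def _bounded_partition(
    rng: np.random.Generator, total: float, n: int, lo: float, hi: float
) -> np.ndarray:
    """Split ``total`` into n parts, each within [lo, hi], randomized."""
    if not n * lo <= total <= n * hi:
        raise ValueError(f"cannot split {total} into {n} parts within [{lo}, {hi}]")
    base = total / n
    u = rng.uniform(-1.0, 1.0, n)
    u -= u.mean()
    span = np.max(np.abs(u))
    if span < 1e-12:
        return np.full(n, base)
    slack_up = (hi - base) / np.maximum(u, 1e-12)
    slack_dn = (base - lo) / np.maximum(-u, 1e-12)
    s_max = min(np.min(slack_up[u > 0], initial=np.inf),
                np.min(slack_dn[u < 0], initial=np.inf))
    s = s_max * rng.uniform(0.2, 0.9)
    return base + s * u


def sample_schedule(params: ScheduleParams | None = None, seed: int = 0) -> SimSchedule:
    """Draw a random daily schedule within the configured ranges.

    Deterministic under a fixed seed.  Raises when the requested ranges
    are infeasible (e.g. a total lying time that the bout count and
    per-bout duration range cannot produce, or lying longer than the
    day).
    """
    if params is None:
        params = ScheduleParams()
    rng = np.random.default_rng(seed)
    n_lo, n_hi = params.n_lying_bouts
    n = int(rng.integers(n_lo, n_hi + 1))
    d_lo, d_hi = (60.0 * m for m in params.lying_bout_minutes)
    t_lo = max(3600.0 * params.total_lying_hours[0], n * d_lo)
    t_hi = min(3600.0 * params.total_lying_hours[1], n * d_hi)
    day = 3600.0 * params.day_hours
    min_stand = 60.0 * params.min_standing_minutes
    t_hi = min(t_hi, day - (n + 1) * min_stand)
    if t_lo > t_hi:
        raise ValueError(
            f"infeasible schedule: {n} lying bouts of {params.lying_bout_minutes} min "
            f"cannot give a total lying time in {params.total_lying_hours} h within a "
            f"{params.day_hours} h day"
        )
    total_lying = float(rng.uniform(t_lo, t_hi))
    lying_durs = _bounded_partition(rng, total_lying, n, d_lo, d_hi)
    total_standing = day - total_lying
    stand_durs = _bounded_partition(
        rng, total_standing, n + 1, min_stand, total_standing
    )
    sides = rng.choice(["left", "right"], size=n)

    episodes: list[Episode] = [Episode(STANDING, float(stand_durs[0]))]
    for i in range(n):
        episodes.append(Episode(LYING, float(lying_durs[i]), str(sides[i])))
        episodes.append(Episode(STANDING, float(stand_durs[i + 1])))

    episodes = _inject_side_switches(rng, episodes, params)
    episodes = _inject_micro_bouts(rng, episodes, params)
    leg_lifts = _draw_leg_lifts(rng, episodes, params)
    return SimSchedule(episodes=episodes, leg_lifts=leg_lifts, params=params, seed=seed)


def _inject_side_switches(
    rng: np.random.Generator, episodes: list[Episode], params: ScheduleParams
) -> list[Episode]:
    for _ in range(params.n_side_switches):
        candidates = [
            i for i, e in enumerate(episodes)
            if e.posture == LYING and e.duration > 2 * 120.0 + params.side_switch_seconds
        ]
        if not candidates:
            break
        i = int(rng.choice(candidates))
        ep = episodes[i]
        cut = float(rng.uniform(120.0, ep.duration - 120.0 - params.side_switch_seconds))
        other = "right" if ep.side == "left" else "left"
        episodes[i:i + 1] = [
            Episode(LYING, cut, ep.side),
            Episode(STANDING, params.side_switch_seconds),
            Episode(LYING, ep.duration - cut - params.side_switch_seconds, other),
        ]
    return episodes


def _inject_micro_bouts(
    rng: np.random.Generator, episodes: list[Episode], params: ScheduleParams
) -> list[Episode]:
    margin = 60.0
    for _ in range(params.n_micro_bouts):
        candidates = [
            i for i, e in enumerate(episodes)
            if e.posture == STANDING
            and e.duration > 2 * margin + params.micro_bout_seconds
        ]
        if not candidates:
            break
        i = int(rng.choice(candidates))
        ep = episodes[i]
        cut = float(rng.uniform(margin, ep.duration - margin - params.micro_bout_seconds))
        side = str(rng.choice(["left", "right"]))
        episodes[i:i + 1] = [
            Episode(STANDING, cut),
            Episode(LYING, params.micro_bout_seconds, side),
            Episode(STANDING, ep.duration - cut - params.micro_bout_seconds),
        ]
    return episodes


def _draw_leg_lifts(
    rng: np.random.Generator, episodes: list[Episode], params: ScheduleParams
) -> list[LegLift]:
    if params.n_leg_lifts == 0:
        return []
    edges = np.concatenate(([0.0], np.cumsum([e.duration for e in episodes])))
    margin = max(params.transition_seconds, 10.0) + 2.0
    events: list[LegLift] = []
    for _ in range(params.n_leg_lifts):
        dur = float(rng.uniform(*params.leg_lift_seconds))
        candidates = [
            (edges[i] + margin, edges[i + 1] - margin - dur)
            for i, e in enumerate(episodes)
            if e.posture == STANDING and e.duration > 2 * margin + dur
        ]
        if not candidates:
            break
        lo, hi = candidates[int(rng.integers(len(candidates)))]
        events.append(LegLift(float(rng.uniform(lo, hi)), dur, params.leg_lift_tilt_deg))
    return sorted(events, key=lambda ev: ev.start)


# --- rendering -------------------------------------------------------------

def _slerp(g0: np.ndarray, g1: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Spherical interpolation between unit vectors; preserves |g| = 1."""
    cosw = float(np.clip(np.dot(g0, g1), -1.0, 1.0))
    omega = np.arccos(cosw)
    if omega < 1e-9:
        return np.outer(np.ones_like(tau), g1)
    sinw = np.sin(omega)
    return (np.sin((1 - tau)[:, None] * omega) * g0 + np.sin(tau[:, None] * omega) * g1) / sinw


def _episode_gravity(ep: Episode, params: ScheduleParams, rng: np.random.Generator) -> np.ndarray:
    """Static gravity direction (fwd, up, right) for one episode, |g| = 1."""
    if ep.posture == STANDING:
        return np.array([0.0, 1.0, 0.0])
    sensor_side = "left" if params.left_leg else "right"
    sign = 1.0 if ep.side == "left" else -1.0
    if ep.side == sensor_side:
        return np.array([0.0, 0.0, sign])
    # free leg: drawn once per bout on the arc between the right axis and
    # the forward axis (leg bent toward the head)
    phi = np.deg2rad(rng.uniform(0.0, params.opposite_arc_max_deg))
    return np.array([np.sin(phi), 0.0, sign * np.cos(phi)])


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, sigma: float
) -> np.ndarray:
    """Gait-like noise: Gaussian band-passed to 0.5-3 Hz, rescaled to sigma.
    Falls back to white noise when the band does not fit below Nyquist."""
    white = rng.standard_normal(n)
    lo, hi = 0.5, min(3.0, 0.45 * fs)
    if n < 30 or lo >= hi:
        return sigma * white
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    shaped = signal.sosfiltfilt(sos, white)
    sd = shaped.std()
    if sd < 1e-12:
        return sigma * white
    return sigma * shaped / sd


def render_accel(
    schedule: SimSchedule, cow_id: str = "cow1", seed: int | None = None
) -> tuple[AccelSeries, pd.DataFrame, pd.DataFrame]:
    """Render a schedule into an acceleration series plus ground truth.

    Returns ``(series, truth, episodes)`` where ``truth`` has per-sample
    ``posture`` and ``side`` columns aligned with the series, and
    ``episodes`` is the episode table (posture, side, start, end) with
    absolute timestamps.  Transitions are rendered as smooth gravity
    rotations over the first ``transition_seconds`` of each new episode;
    ground-truth labels switch at the first sample of the new posture.
    """
    p = schedule.params
    if seed is None:
        seed = schedule.seed + 1_000_000
    rng = np.random.default_rng(seed)
    fs = p.sampling_rate
    dt = 1.0 / fs
    total = schedule.total_seconds
    n = int(round(total * fs)) + 1
    offsets = np.arange(n) * dt
    start = pd.Timestamp(p.start_time)
    times = start + pd.to_timedelta(offsets, unit="s")

    bounds = schedule.episode_bounds()
    edges = np.array([b[0] for b in bounds] + [bounds[-1][1]])
    ep_idx = np.clip(np.searchsorted(edges, offsets, side="right") - 1,
                     0, len(schedule.episodes) - 1)

    gravities = [_episode_gravity(e, p, rng) for e in schedule.episodes]
    acc = np.empty((n, 3))
    for i, e in enumerate(schedule.episodes):
        mask = ep_idx == i
        acc[mask] = gravities[i]
        if i > 0 and p.transition_seconds > 0:
            t0, _ = bounds[i]
            ramp = mask & (offsets < t0 + min(p.transition_seconds, e.duration))
            if ramp.any():
                tau = (offsets[ramp] - t0) / min(p.transition_seconds, e.duration)
                acc[ramp] = _slerp(gravities[i - 1], gravities[i], tau)

    for ev in schedule.leg_lifts:
        target = np.array([np.sin(np.deg2rad(ev.tilt_deg)),
                           np.cos(np.deg2rad(ev.tilt_deg)), 0.0])
        ramp = min(1.0, ev.duration / 4.0)
        in_ev = (offsets >= ev.start) & (offsets <= ev.start + ev.duration)
        rel = offsets[in_ev] - ev.start
        tau = np.minimum(np.minimum(rel / ramp, (ev.duration - rel) / ramp), 1.0)
        acc[in_ev] = _slerp(np.array([0.0, 1.0, 0.0]), target, np.clip(tau, 0.0, 1.0))

    postures = np.array([e.posture for e in schedule.episodes])
    standing_mask = postures[ep_idx] == STANDING
    noise = np.empty((n, 3))
    for k in range(3):
        noise[:, k] = np.where(
            standing_mask,
            _band_limited_noise(rng, n, fs, p.sigma_standing),
            p.sigma_lying * rng.standard_normal(n),
        )
    acc = acc + noise

    data = pd.DataFrame(
        {"time": times, "acc_fwd": acc[:, 0], "acc_up": acc[:, 1], "acc_right": acc[:, 2]}
    )
    series = AccelSeries(cow_id=cow_id, data=data)

    sides = np.array([e.side if e.side is not None else "unassigned"
                      for e in schedule.episodes], dtype=object)
    truth = pd.DataFrame({"posture": postures[ep_idx], "side": sides[ep_idx]})
    episodes = pd.DataFrame(
        {
            "posture": [e.posture for e in schedule.episodes],
            "side": [e.side for e in schedule.episodes],
            "start": [start + pd.Timedelta(seconds=b[0]) for b in bounds],
            "end": [start + pd.Timedelta(seconds=b[1]) for b in bounds],
            "duration_s": [e.duration for e in schedule.episodes],
        }
    )
    return series, truth, episodes


def write_fixture_files(
    series_list: list[AccelSeries],
    spec: FileFormatSpec,
    directory: str | os.PathLike,
    axis_map: AxisMap | None = None,
) -> list[str]:
    """Write one raw-format file per cow, parseable back with ``spec``.

    The body-relative channels are converted to sensor XYZ with the
    inverse of ``axis_map`` (identity by default), so that
    ``map_axes(parse_file(path, spec), axis_map)`` round-trips to the
    original series.  Acceleration is written with 9 decimals.
    """
    if axis_map is None:
        axis_map = AxisMap()
    os.makedirs(directory, exist_ok=True)
    body_col = {"forward": "acc_fwd", "upward": "acc_up", "right": "acc_right"}
    width = max(spec.timestamp_col, spec.col_x, spec.col_y, spec.col_z) + 1
    channel_col = {"X": spec.col_x, "Y": spec.col_y, "Z": spec.col_z}
    paths = []
    for series in series_list:
        path = os.path.join(os.fspath(directory), f"{series.cow_id}.csv")
        cols: list[np.ndarray | list] = [None] * width  # type: ignore[list-item]
        cols[spec.timestamp_col] = series.data["time"].dt.strftime(
            spec.timestamp_format.replace("%-", "%")
        ).to_list()
        for axis, (channel, sign) in axis_map.as_dict().items():
            vals = sign * series.data[body_col[axis]].to_numpy(float)
            text = [f"{v:.9f}" for v in vals]
            if spec.decimal != ".":
                text = [s.replace(".", spec.decimal) for s in text]
            cols[channel_col[channel]] = text
        filler = [""] * len(series.data)
        cols = [c if c is not None else filler for c in cols]
        sep = spec.sep
        with open(path, "w") as fh:
            for i in range(spec.skip_header):
                fh.write(f"# header line {i + 1}\n")
            for row in zip(*cols):
                fh.write(sep.join(row) + "\n")
        paths.append(path)
    return paths
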