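import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lielog as ll

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def _rendered_day():
    """One simulated day at 1 Hz with ground truth (rendered once)."""
    params = ll.ScheduleParams(sampling_rate=1.0)
    schedule = ll.sample_schedule(params, seed=42)
    series, truth, episodes = ll.render_accel(schedule)
    return schedule, series, truth, episodes


@pytest.fixture
def sim_day(_rendered_day):
    """Fresh, unannotated copy of the simulated day for each test."""
    schedule, series, truth, episodes = _rendered_day
    clean = ll.AccelSeries(
        series.cow_id,
        series.data[["time", "acc_fwd", "acc_up", "acc_right"]].copy(),
    )
    return schedule, clean, truth, episodes


@pytest.fixture
def analyzed_day(sim_day):
    """Simulated day run through posture, laterality and activity."""
    schedule, series, truth, episodes = sim_day
    bouts = ll.add_lying(series)
    ll.assign_side(series, bouts, ll.LateralityParams(left_leg=True))
    activity = ll.add_activity(
        series, bouts, ll.ActivityParams(measures=("L1DBA", "L2DBA", "L1Jerk", "L2Jerk"))
    )
    return schedule, series, truth, episodes, bouts, activity


def make_series(up, fwd=None, right=None, rate=1.0, cow_id="cow1",
                start="2024-01-01 00:00:00"):
    """Small helper to build an AccelSeries from plain arrays."""
    up = np.asarray(up, dtype=float)
    n = len(up)
    zeros = np.zeros(n)
    t = pd.Timestamp(start) + pd.to_timedelta(np.arange(n) / rate, unit="s")
    return ll.AccelSeries(
        cow_id,
        pd.DataFrame(
            {
                "time": t,
                "acc_fwd": zeros if fwd is None else np.asarray(fwd, float),
                "acc_up": up,
                "acc_right": zeros if right is None else np.asarray(right, float),
            }
        ),
    )
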