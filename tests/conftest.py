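import datetime as dt

import numpy as np
import pytest

from actipredict.activity_io import MINUTES_PER_DAY, ActivityDay

OMEGA = 2 * np.pi / MINUTES_PER_DAY


def make_day(steps=None, heart_rate=None, sleep_stage=None,
             date=dt.date(2019, 6, 1)) -> ActivityDay:
    """ActivityDay from partial channel arrays (missing channels all-NaN)."""
    nan = np.full(MINUTES_PER_DAY, np.nan)
    return ActivityDay(
        date,
        nan.copy() if steps is None else np.asarray(steps, dtype=float),
        nan.copy() if heart_rate is None else np.asarray(heart_rate, dtype=float),
        nan.copy() if sleep_stage is None else np.asarray(sleep_stage, dtype=float),
    )


def circadian_day(seed=0, noise_sd=2.0, date=dt.date(2019, 6, 1)) -> ActivityDay:
    """Complete day: smooth circadian heart rate + step-coupled bumps."""
    rng = np.random.default_rng(seed)
    t = np.arange(MINUTES_PER_DAY)
    steps = rng.poisson(3.0 * np.maximum(0, np.cos(OMEGA * (t - 840)))).astype(float)
    hr = (75 + 10 * np.cos(OMEGA * (t - 960)) + 0.3 * steps
          + rng.normal(0, noise_sd, MINUTES_PER_DAY))
    return make_day(steps, hr, date=date)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small masked synthetic cohort shared by io/pipeline tests."""
    from actipredict.synthetic_cohort import CohortConfig, generate_masked_cohort
    cfg = CohortConfig(n_patients=6, monitoring_days_mean=10,
                       monitoring_days_range=(6, 14), seed=7)
    return generate_masked_cohort(cfg), cfg
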