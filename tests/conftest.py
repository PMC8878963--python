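import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

import nilmon as nm

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

MAPPING = {"cooking": frozenset({"kettle"})}


def make_series(values, period=8.0, start=dt.datetime(2014, 1, 1, tzinfo=dt.timezone.utc), channel="kettle"):
    return nm.PowerSeries(
        channel_id=channel, start_time=start, sample_period=period,
        values=np.asarray(values, dtype=float),
    )


def make_activation(hour, duration=150.0, appliance="kettle", date=dt.date(2014, 1, 6)):
    start = dt.datetime.combine(date, dt.time(), tzinfo=dt.timezone.utc) + dt.timedelta(hours=hour)
    return nm.Activation(
        appliance_id=appliance, start=start, duration=duration,
        max_power=2800.0, day_of_week=start.weekday(), day_of_month=start.day,
    )


@pytest.fixture(scope="session")
def mapping():
    return MAPPING


def _injected(preset, seed):
    cfg = nm.PipelineConfig(seed=seed)
    n_days = cfg.observation_days + 300
    ds = nm.generate_household(preset(), n_days, seed=seed)
    eligible = list(range(cfg.observation_days, n_days))
    ds = nm.inject_anomalies(ds, "night_usage", cfg.anomaly_rate, "kettle", seed=seed + 1000, days=eligible)
    ds = nm.inject_anomalies(ds, "divergent_usage", cfg.anomaly_rate, "kettle", seed=seed + 2000, days=eligible)
    return cfg, ds


@pytest.fixture(scope="session")
def house4_run():
    """Full house-4 study: 51-day observation, 300-day monitoring, 10%+10% anomalies."""
    cfg, ds = _injected(nm.house4_preset, seed=1)
    return cfg, ds, nm.run_pipeline(cfg, ds, MAPPING)


@pytest.fixture(scope="session")
def house11_run():
    """Same experiment on the house-11 preset (habitual night use in observation)."""
    cfg, ds = _injected(nm.house11_preset, seed=1)
    return cfg, ds, nm.run_pipeline(cfg, ds, MAPPING)
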