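"""Synthetic household traces with controlled anomaly injection.

Real annotated energy data for elderly households is scarce, so every
downstream stage is exercised on synthetic traces that emulate two
archetypal kettle-usage routines observed in single-senior UK households:

``house4``
    Typical behaviour — the kettle is used between 5 a.m. and 10 p.m. with
    heavier morning and evening use, moderate midday use and *no* night
    use.  The observation phase therefore captures only healthy routine.
``house11``
    Moderate daytime use, heavier use from 6 p.m. to 10 p.m., plus
    habitual night-time use (0–4 a.m.) that is part of the occupant's
    normal routine.  Night anomalies injected on top of this profile are
    indistinguishable from the baseline, which is the point of the preset.

Generation draws per-window activation counts from a Poisson law, start
times uniformly within their window and durations from a truncated normal;
each activation is a rectangular pulse at the appliance's rated power.  The
aggregate is the channel sum plus a constant base load plus non-negative
Gaussian noise.  Anomalous days of three classes (divergent usage time,
night usage, absence) are injected at a configurable rate — by default 10 %
of the period — and the aggregate is adjusted consistently so that at every
sample ``aggregate = sum(appliances) + base_load + noise`` continues to hold.
"""

from __future__ import annotations

import copy
import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ConfigurationError, PowerSeries

__all__ = [
    "ApplianceProfileSpec",
    "GroundTruthEvent",
    "LabelledDataset",
    "house4_preset",
    "house11_preset",
    "generate_household",
    "inject_anomalies",
    "write_dataset_csv",
]

SECONDS_PER_DAY = 86400

NORMAL = "normal"
DIVERGENT_USAGE = "divergent_usage"
NIGHT_USAGE = "night_usage"
ABSENCE = "absence"
DATA_GAP = "data_gap"
ANOMALY_CLASSES = (DIVERGENT_USAGE, NIGHT_USAGE, ABSENCE)

NIGHT_BAND = (0.0, 4.0)  # hours; injection protocol's night window


@dataclass(frozen=True)
class ApplianceProfileSpec:
    """Usage profile of one appliance.

    ``usage_windows`` is a list of ``(start_hour, end_hour, mean_activations
    per day)`` tuples; ``duration_dist`` is ``(mean_s, sd_s, min_s)`` of a
    truncated normal; ``night_use`` marks habitual activations in the 0–4
    a.m. band as part of the windows.
    """

    appliance_id: str
    rated_power: float
    usage_windows: tuple[tuple[float, float, float], ...]
    duration_dist: tuple[float, float, float] = (150.0, 45.0, 60.0)
    night_use: bool = False

    def __post_init__(self) -> None:
        if self.rated_power <= 0:
            raise ConfigurationError("rated_power must be positive")
        mean, sd, mn = self.duration_dist
        if mean <= 0 or mn <= 0 or sd < 0:
            raise ConfigurationError("durations must be positive")
        for start, end, rate in self.usage_windows:
            if not (0 <= start < end <= 24):
                raise ConfigurationError(
                    f"impossible window ({start}, {end}) for {self.appliance_id!r}"
                )
            if rate < 0:
                raise ConfigurationError("activation rate must be >= 0")


def house4_preset() -> list[ApplianceProfileSpec]:
    """Kettle routine of a retired couple with a regular daily rhythm.

    Usage spans 5 a.m.–10 p.m. only (never at night): habitual morning tea
    (main peak, twice most mornings), moderate midday use, and an evening
    peak.  Windows are narrow because the routine is regular — the same
    few habitual times each day with modest jitter.
    """
    return [
        ApplianceProfileSpec(
            appliance_id="kettle",
            rated_power=2800.0,
            usage_windows=(
                (7.0, 8.0, 1.2),    # breakfast tea
                (10.0, 10.8, 0.8),  # mid-morning
                (12.5, 13.3, 0.8),  # lunch
                (15.5, 16.3, 0.6),  # afternoon tea
                (19.0, 20.0, 1.8),  # evening
            ),
            duration_dist=(150.0, 45.0, 60.0),
            night_use=False,
        )
    ]


def house11_preset() -> list[ApplianceProfileSpec]:
    """Kettle routine with habitual night use and a heavier 6–10 p.m. peak.

    Daytime use is moderate; most use falls between 6 p.m. and 10 p.m.;
    night activations (0–4 a.m.) are part of the occupant's normal routine,
    so night anomalies injected on top are invisible by construction.
    """
    return [
        ApplianceProfileSpec(
            appliance_id="kettle",
            rated_power=2600.0,
            usage_windows=(
                (8.0, 9.0, 0.8),
                (12.5, 13.5, 0.7),
                (18.0, 20.0, 1.5),
                (20.0, 21.5, 1.0),
                (0.0, 4.0, 1.5),   # habitual night use
            ),
            duration_dist=(150.0, 45.0, 60.0),
            night_use=True,
        )
    ]


PRESETS = {"house4": house4_preset, "house11": house11_preset}


@dataclass(frozen=True)
class GroundTruthEvent:
    """One appliance activation: day index, start second within the day, duration."""

    appliance_id: str
    day: int
    start_s: float
    duration_s: float

    @property
    def start_hour(self) -> float:
        return self.start_s / 3600.0


@dataclass
class LabelledDataset:
    """Per-appliance and aggregate traces plus per-day anomaly labels.

    Invariant: ``aggregate = sum(appliance channels) + base_load + noise``
    at every sample (noise is retained so injection can rebuild the
    aggregate exactly), and every day carries exactly one label.
    """

    start_time: dt.datetime
    sample_period: float
    n_days: int
    specs: dict[str, ApplianceProfileSpec]
    events: dict[str, list[GroundTruthEvent]]
    day_labels: list[str]
    base_load: float
    noise: np.ndarray
    appliances: dict[str, PowerSeries] = field(default_factory=dict)
    aggregate: PowerSeries | None = None

    @property
    def samples_per_day(self) -> int:
        return int(round(SECONDS_PER_DAY / self.sample_period))

    def dates(self) -> list[dt.date]:
        d0 = self.start_time.date()
        return [d0 + dt.timedelta(days=i) for i in range(self.n_days)]

    def copy(self) -> "LabelledDataset":
        return LabelledDataset(
            start_time=self.start_time,
            sample_period=self.sample_period,
            n_days=self.n_days,
            specs=dict(self.specs),
            events={a: list(evs) for a, evs in self.events.items()},
            day_labels=list(self.day_labels),
            base_load=self.base_load,
            noise=self.noise.copy(),
            appliances=dict(self.appliances),
            aggregate=self.aggregate,
        )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    if sd == 0:
        return max(mean, lo)
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x >= lo:
            return float(x)
    return float(lo)


def _merge_events(events: list[GroundTruthEvent]) -> list[GroundTruthEvent]:
    """Merge overlapping activations of the same appliance within a day."""
    out: list[GroundTruthEvent] = []
    for ev in sorted(events, key=lambda e: (e.day, e.start_s)):
        if out and out[-1].day == ev.day and ev.start_s <= out[-1].start_s + out[-1].duration_s:
            prev = out[-1]
            end = max(prev.start_s + prev.duration_s, ev.start_s + ev.duration_s)
            out[-1] = replace(prev, duration_s=end - prev.start_s)
        else:
            out.append(ev)
    return out


def _render_appliance(ds: LabelledDataset, appliance_id: str) -> np.ndarray:
    """Rasterise an appliance's event list into a rectangular-pulse trace."""
    spd = ds.samples_per_day
    arr = np.zeros(ds.n_days * spd)
    rated = ds.specs[appliance_id].rated_power
    period = ds.sample_period
    for ev in ds.events[appliance_id]:
        i0 = ev.day * spd + int(round(ev.start_s / period))
        n = max(1, int(round(ev.duration_s / period)))
        i1 = min(i0 + n, (ev.day + 1) * spd)  # activations never cross midnight
        arr[i0:i1] = rated
    return arr


def _rebuild_traces(ds: LabelledDataset) -> None:
    """Recompute all PowerSeries from the event lists, base load and noise."""
    total = np.full(ds.n_days * ds.samples_per_day, ds.base_load)
    for app in ds.specs:
        vals = _render_appliance(ds, app)
        ds.appliances[app] = PowerSeries(
            channel_id=app,
            start_time=ds.start_time,
            sample_period=ds.sample_period,
            values=vals,
        )
        total = total + vals
    ds.aggregate = PowerSeries(
        channel_id="aggregate",
        start_time=ds.start_time,
        sample_period=ds.sample_period,
        values=total + ds.noise,
    )


def generate_household(
    specs: Sequence[ApplianceProfileSpec],
    n_days: int,
    base_load: float = 80.0,
    noise_sd: float = 20.0,
    seed: int = 0,
    start_date: dt.date = dt.date(2014, 1, 1),
    sample_period: float = 8.0,
) -> LabelledDataset:
    """Generate a labelled household dataset of ``n_days`` normal days.

    Per day and usage window, the activation count is Poisson with the
    window's mean; start times are uniform within the window; durations are
    truncated normal; overlapping activations are merged.  The aggregate is
    the channel sum plus ``base_load`` plus non-negative Gaussian noise.
    Identical seeds yield bit-identical datasets.
    """
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    start_time = dt.datetime.combine(start_date, dt.time(), tzinfo=dt.timezone.utc)
    ds = LabelledDataset(
        start_time=start_time,
        sample_period=sample_period,
        n_days=n_days,
        specs={s.appliance_id: s for s in specs},
        events={s.appliance_id: [] for s in specs},
        day_labels=[NORMAL] * n_days,
        base_load=base_load,
        noise=np.zeros(0),
    )
    for spec in specs:
        mean_d, sd_d, min_d = spec.duration_dist
        events: list[GroundTruthEvent] = []
        for day in range(n_days):
            for start_h, end_h, rate in spec.usage_windows:
                count = rng.poisson(rate)
                for _ in range(count):
                    start_s = rng.uniform(start_h * 3600, end_h * 3600)
                    dur = _truncated_normal(rng, mean_d, sd_d, min_d)
                    dur = min(dur, SECONDS_PER_DAY - start_s)
                    events.append(
                        GroundTruthEvent(spec.appliance_id, day, start_s, dur)
                    )
        ds.events[spec.appliance_id] = _merge_events(events)
    n_samples = n_days * ds.samples_per_day
    ds.noise = np.maximum(rng.normal(0.0, noise_sd, n_samples), 0.0) if noise_sd > 0 else np.zeros(n_samples)
    _rebuild_traces(ds)
    return ds


def _divergent_day(
    rng: np.random.Generator,
    events: list[GroundTruthEvent],
    night_band: tuple[float, float] = NIGHT_BAND,
    max_tries: int = 200,
) -> list[GroundTruthEvent]:
    """Shift every activation of the day by one random 4–8 h offset (wrapped).

    Offsets landing any activation in the night band are rejected and
    redrawn, keeping the divergent class disjoint from night usage.
    """
    lo, hi = night_band
    for _ in range(max_tries):
        offset_h = rng.uniform(4.0, 8.0)
        new_starts = [(ev.start_s + offset_h * 3600) % SECONDS_PER_DAY for ev in events]
        if all(not (lo * 3600 <= s < hi * 3600) for s in new_starts):
            break
    else:  # no joint offset found: nudge offenders just past the band
        new_starts = [
            s if not (lo * 3600 <= s < hi * 3600) else hi * 3600 + (s - lo * 3600)
            for s in new_starts
        ]
    out = []
    for ev, s in zip(events, new_starts):
        out.append(replace(ev, start_s=s, duration_s=min(ev.duration_s, SECONDS_PER_DAY - s)))
    return _merge_events(out)


def inject_anomalies(
    dataset: LabelledDataset,
    anomaly_class: str,
    rate: float,
    target_appliance: str,
    seed: int = 0,
    days: Sequence[int] | None = None,
) -> LabelledDataset:
    """Inject one anomaly class into ``round(rate * n_days)`` normal days.

    Days are chosen uniformly without replacement among currently-normal
    days (restricted to ``days`` when given, e.g. the monitoring period).
    ``divergent_usage`` shifts every target-appliance activation by a
    per-day random 4–8 h offset, wrapped and kept out of the 0–4 a.m. band;
    ``night_usage`` adds 1–2 activations with start hours uniform in
    [0 h, 4 h); ``absence`` removes all target-appliance activations.
    The aggregate trace is rebuilt so the channel-sum invariant holds.
    """
    if anomaly_class not in ANOMALY_CLASSES:
        raise ConfigurationError(f"unknown anomaly class {anomaly_class!r}")
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("rate must be in [0, 1]")
    if target_appliance not in dataset.specs:
        raise ConfigurationError(f"unknown appliance {target_appliance!r}")

    candidates = list(range(dataset.n_days)) if days is None else list(days)
    n_inject = int(round(rate * len(candidates)))
    if n_inject == 0:
        return dataset.copy()

    rng = np.random.default_rng(seed)
    normal_days = [d for d in candidates if dataset.day_labels[d] == NORMAL]
    if len(normal_days) < n_inject:
        raise ValueError(
            f"need {n_inject} normal days, only {len(normal_days)} available"
        )
    chosen = sorted(rng.choice(normal_days, size=n_inject, replace=False).tolist())

    ds = dataset.copy()
    spec = ds.specs[target_appliance]
    mean_d, sd_d, min_d = spec.duration_dist
    by_day: dict[int, list[GroundTruthEvent]] = {}
    for ev in ds.events[target_appliance]:
        by_day.setdefault(ev.day, []).append(ev)

    for day in chosen:
        day_events = by_day.get(day, [])
        if anomaly_class == DIVERGENT_USAGE:
            by_day[day] = _divergent_day(rng, day_events)
        elif anomaly_class == NIGHT_USAGE:
            k = int(rng.integers(1, 3))  # "random number (<3)": 1 or 2
            added = []
            for _ in range(k):
                start_s = rng.uniform(NIGHT_BAND[0] * 3600, NIGHT_BAND[1] * 3600)
                dur = _truncated_normal(rng, mean_d, sd_d, min_d)
                added.append(GroundTruthEvent(target_appliance, day, start_s, dur))
            by_day[day] = _merge_events(day_events + added)
        else:  # ABSENCE
            by_day[day] = []
        ds.day_labels[day] = anomaly_class

    ds.events[target_appliance] = [
        ev for day in sorted(by_day) for ev in by_day[day]
    ]
    _rebuild_traces(ds)
    return ds


def write_dataset_csv(
    dataset: LabelledDataset,
    data_path: str | Path,
    labels_path: str | Path | None = None,
) -> None:
    """Emit the dataset in the REFIT-style CSV dialect plus a labels CSV."""
    channels: dict[str, PowerSeries] = {"aggregate": dataset.aggregate}
    channels.update(dataset.appliances)
    times = pd.to_datetime(dataset.aggregate.sample_times(), unit="s", utc=True)
    data = {"timestamp": times.strftime("%Y-%m-%dT%H:%M:%SZ")}
    for name, s in channels.items():
        data[name] = s.values
    pd.DataFrame(data).to_csv(data_path, index=False)
    if labels_path is not None:
        pd.DataFrame(
            {"date": [d.isoformat() for d in dataset.dates()], "class": dataset.day_labels}
        ).to_csv(labels_path, index=False)
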