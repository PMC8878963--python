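"""Reading and writing the file dialects the pipeline touches.

Power traces arrive as REFIT-style CSV: one timestamp column, one aggregate
column and numbered appliance columns, sampled at roughly 8 s.  Internally a
channel is held as a :class:`PowerSeries` — a uniformly sampled watt vector
with an explicit start time and sample period.  Timestamps are UTC; day
boundaries are taken at local midnight of a configurable timezone (default
UTC) because the monitor scores whole days, so the boundary convention must
be fixed.

Gap convention: after :func:`resample`, windows containing no samples are
0 W and a per-day coverage fraction can be computed with
:func:`day_coverage`; days with coverage below 50 % are treated as data
gaps and excluded from the observation store.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PowerSeries",
    "PipelineConfig",
    "load_power_csv",
    "write_power_csv",
    "resample",
    "day_coverage",
    "write_report",
    "read_reports",
    "load_config",
]


class FormatError(ValueError):
    """Malformed input file (non-monotone timestamps, bad values)."""


class ConfigurationError(ValueError):
    """Invalid configuration or missing mapped column."""


@dataclass(frozen=True)
class PowerSeries:
    """Uniformly sampled power trace for one channel.

    Parameters
    ----------
    channel_id:
        Name of the channel ("aggregate" or an appliance id).
    start_time:
        UTC timestamp of the first sample.
    sample_period:
        Spacing between samples in seconds (default 8 s, the native smart
        meter rate).
    values:
        Watts, all finite and >= 0.
    timestamps:
        Optional explicit per-sample timestamps (epoch seconds).  Present
        only for freshly loaded, possibly non-uniform traces; callers must
        resample before using such a series downstream.
    """

    channel_id: str
    start_time: dt.datetime
    sample_period: float
    values: np.ndarray
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.size == 0:
            raise ValueError("PowerSeries must contain at least one sample")
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"channel {self.channel_id!r}: non-finite power value")
        if np.any(vals < 0):
            row = int(np.argmax(vals < 0))
            raise ValueError(
                f"channel {self.channel_id!r}: negative power at row {row}"
            )
        if self.start_time.tzinfo is None:
            object.__setattr__(
                self, "start_time", self.start_time.replace(tzinfo=dt.timezone.utc)
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end_time(self) -> dt.datetime:
        return self.start_time + dt.timedelta(
            seconds=self.sample_period * len(self.values)
        )

    def sample_times(self) -> np.ndarray:
        """Epoch seconds of every sample."""
        if self.timestamps is not None:
            return self.timestamps
        t0 = self.start_time.timestamp()
        return t0 + self.sample_period * np.arange(len(self.values))


@dataclass
class PipelineConfig:
    """Tunable parameters of the monitoring pipeline.

    ``state_threshold`` (500 W) separates ON from OFF samples;
    ``bins_per_day`` is the activity-curve resolution; ``beta`` weights
    non-feedback days in the divergence (must satisfy beta >= 2);
    ``observation_days`` (51) is the length of the profile-building phase;
    ``anomaly_rate`` (0.10) is the per-class injection rate;
    ``iqr_factor`` (1.5) scales the decision interval.
    """

    state_threshold: float = 500.0
    bins_per_day: int = 24
    beta: float = 2.0
    observation_days: int = 51
    anomaly_rate: float = 0.10
    iqr_factor: float = 1.5
    seed: int = 0
    sample_period: float = 8.0
    timezone: str = "UTC"
    night_band: tuple[float, float] = (0.0, 4.0)
    min_duration: float = 16.0
    merge_gap: float = 16.0
    min_coverage: float = 0.5
    backend: str = "passthrough"
    combination_cap: int = 4096
    activation_analysis: bool = True

    def __post_init__(self) -> None:
        if self.beta < 2:
            raise ConfigurationError("beta must be >= 2")
        if not 0.0 <= self.anomaly_rate <= 1.0:
            raise ConfigurationError("anomaly_rate must be in [0, 1]")
        if self.bins_per_day <= 0 or (24 * 3600) % self.bins_per_day:
            raise ConfigurationError("bins_per_day must divide the day evenly")
        if self.state_threshold <= 0:
            raise ConfigurationError("state_threshold must be positive")
        if self.iqr_factor < 0:
            raise ConfigurationError("iqr_factor must be non-negative")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "night_band" in data:
        data["night_band"] = tuple(data["night_band"])
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# CSV power traces


def _parse_timestamps(col: pd.Series) -> pd.Series:
    """Accept ISO-8601 strings or epoch seconds; return UTC datetimes."""
    if pd.api.types.is_numeric_dtype(col):
        return pd.to_datetime(col, unit="s", utc=True)
    return pd.to_datetime(col, utc=True, format="ISO8601")


def load_power_csv(
    path: str | Path,
    channel_map: Mapping[str, str],
    timestamp_column: str = "timestamp",
) -> dict[str, PowerSeries]:
    """Read a REFIT-style CSV into one :class:`PowerSeries` per mapped channel.

    ``channel_map`` maps channel ids (e.g. ``"aggregate"``, ``"kettle"``) to
    CSV column names; unmapped columns are ignored.  Timestamps must be
    strictly increasing.  Non-uniform spacing is preserved (the returned
    series carry explicit timestamps); resample before downstream use.
    """
    df = pd.read_csv(path)
    if timestamp_column not in df.columns:
        raise ConfigurationError(f"timestamp column {timestamp_column!r} not in file")
    missing = [c for c in channel_map.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(f"mapped columns missing from file: {missing}")
    if len(df) == 0:
        raise FormatError("empty power file")

    times = _parse_timestamps(df[timestamp_column])
    epoch = times.astype("int64").to_numpy() / 1e9
    diffs = np.diff(epoch)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 1
        raise FormatError(f"timestamps not strictly increasing at row {row}")

    period = float(diffs[0]) if len(diffs) else 8.0
    uniform = len(diffs) == 0 or bool(np.allclose(diffs, period))
    start = times.iloc[0].to_pydatetime()

    out: dict[str, PowerSeries] = {}
    for channel, column in channel_map.items():
        vals = df[column].to_numpy(dtype=float)
        if np.any(vals < 0):
            row = int(np.argmax(vals < 0))
            raise ValueError(f"negative power in column {column!r} at row {row}")
        out[channel] = PowerSeries(
            channel_id=channel,
            start_time=start,
            sample_period=period,
            values=vals,
            timestamps=None if uniform else epoch.copy(),
        )
    return out


def write_power_csv(
    path: str | Path,
    series: Mapping[str, PowerSeries],
    timestamp_column: str = "timestamp",
) -> None:
    """Write aligned channels back to the same CSV dialect."""
    items = list(series.items())
    if not items:
        raise ValueError("no channels to write")
    first = items[0][1]
    n = len(first)
    for name, s in items:
        if len(s) != n:
            raise ValueError(f"channel {name!r} length mismatch")
    times = pd.to_datetime(first.sample_times(), unit="s", utc=True)
    data = {timestamp_column: times.strftime("%Y-%m-%dT%H:%M:%SZ")}
    for name, s in items:
        data[name] = s.values
    pd.DataFrame(data).to_csv(path, index=False)


def resample(series: PowerSeries, period: float) -> PowerSeries:
    """Average a trace over non-overlapping windows of ``period`` seconds.

    Windows are aligned to ``start_time``; a window containing no samples
    yields 0 W (the documented gap convention).  Upsampling is unsupported.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if period < series.sample_period:
        raise ValueError("upsampling is not supported")
    t0 = series.start_time.timestamp()
    rel = series.sample_times() - t0
    idx = np.floor(rel / period).astype(np.int64)
    n_win = int(idx[-1]) + 1
    sums = np.bincount(idx, weights=series.values, minlength=n_win)
    counts = np.bincount(idx, minlength=n_win)
    out = np.divide(sums, counts, out=np.zeros(n_win), where=counts > 0)
    return PowerSeries(
        channel_id=series.channel_id,
        start_time=series.start_time,
        sample_period=float(period),
        values=out,
    )


def day_coverage(series: PowerSeries, date: dt.date) -> float:
    """Fraction of a calendar day covered by samples of the series."""
    day_start = dt.datetime.combine(date, dt.time(), tzinfo=dt.timezone.utc)
    day_end = day_start + dt.timedelta(days=1)
    t = series.sample_times()
    mask = (t >= day_start.timestamp()) & (t < day_end.timestamp())
    return float(mask.sum() * series.sample_period / 86400.0)


# ---------------------------------------------------------------------------
# JSON-lines anomaly reports


def write_report(reports: Sequence, path: str | Path) -> None:
    """Serialise anomaly reports as JSON lines (one record per day).

    Each record carries the date, divergence score, decision interval,
    decision, anomaly class (null for normal days) and the day's
    contributing activations.  ``read_reports`` round-trips losslessly.
    """
    with open(path, "w") as fh:
        for rep in reports:
            fh.write(json.dumps(rep.to_record()) + "\n")


def read_reports(path: str | Path) -> list[dict]:
    """Read back a JSON-lines report file as plain dicts."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out
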