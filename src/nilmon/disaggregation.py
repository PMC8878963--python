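"""Appliance state derivation, activation extraction and CO disaggregation.

Two interchangeable back-ends turn power traces into per-appliance
estimates: a ground-truth pass-through (the sub-metered channels are the
estimate) and Hart-style Combinatorial Optimisation (CO), which at every
sample picks the combination of rated power levels whose sum best matches
the aggregate.  Operational states are derived by thresholding at 500 W
(appropriate for a kettle) and contiguous ON runs become
:class:`Activation` summaries carrying start time, duration, max power and
calendar context.
"""

from __future__ import annotations

import datetime as dt
import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import PowerSeries

__all__ = [
    "StateSeries",
    "Activation",
    "RatedModel",
    "DisaggregationEstimate",
    "derive_states",
    "extract_activations",
    "fit_rated_model",
    "co_disaggregate",
]


@dataclass(frozen=True)
class StateSeries:
    """ON/OFF states aligned 1:1 with a power trace."""

    appliance_id: str
    start_time: dt.datetime
    sample_period: float
    states: np.ndarray  # boolean, True = ON

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class Activation:
    """One contiguous ON episode with temporal context and max power."""

    appliance_id: str
    start: dt.datetime
    duration: float  # seconds
    max_power: float
    day_of_week: int  # 0 = Monday
    day_of_month: int

    @property
    def start_hour(self) -> float:
        """Start time as fractional hour of day."""
        t = self.start
        return t.hour + t.minute / 60 + t.second / 3600 + t.microsecond / 3.6e9

    @property
    def date(self) -> dt.date:
        return self.start.date()


@dataclass(frozen=True)
class RatedModel:
    """Discrete power levels per appliance (OFF = 0 plus one or more ON levels)."""

    levels: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        for app, lv in self.levels.items():
            if 0.0 not in lv:
                raise ValueError(f"appliance {app!r} must include the 0 W level")
            if any(x < 0 for x in lv):
                raise ValueError(f"appliance {app!r} has a negative level")


@dataclass
class DisaggregationEstimate:
    """Per-appliance estimated power and state series."""

    power: dict[str, PowerSeries]
    states: dict[str, StateSeries]


def derive_states(series: PowerSeries, threshold: float) -> StateSeries:
    """ON wherever the power is at or above ``threshold`` (500 W default use)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return StateSeries(
        appliance_id=series.channel_id,
        start_time=series.start_time,
        sample_period=series.sample_period,
        states=series.values >= threshold,
    )


def extract_activations(
    states: StateSeries,
    power: PowerSeries,
    min_duration: float = 16.0,
    merge_gap: float = 16.0,
) -> list[Activation]:
    """Summarise maximal ON runs as activations.

    Runs separated by at most ``merge_gap`` seconds of OFF are merged;
    merged runs shorter than ``min_duration`` are discarded (suppresses
    single-sample noise without hiding short kettle boils).
    """
    if len(states) != len(power) or states.start_time != power.start_time:
        raise ValueError("states and power series are misaligned")
    s = np.asarray(states.states, dtype=bool)
    if not s.any():
        return []
    period = states.sample_period
    padded = np.diff(np.concatenate(([0], s.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)  # exclusive

    # merge runs separated by short OFF gaps
    merged: list[tuple[int, int]] = [(int(starts[0]), int(ends[0]))]
    gap_samples = int(np.floor(merge_gap / period))
    for b, e in zip(starts[1:], ends[1:]):
        pb, pe = merged[-1]
        if b - pe <= gap_samples:
            merged[-1] = (pb, int(e))
        else:
            merged.append((int(b), int(e)))

    out: list[Activation] = []
    for b, e in merged:
        n_on = int(s[b:e].sum())
        duration = n_on * period
        if duration < min_duration:
            continue
        start = states.start_time + dt.timedelta(seconds=b * period)
        out.append(
            Activation(
                appliance_id=states.appliance_id,
                start=start,
                duration=duration,
                max_power=float(power.values[b:e].max()),
                day_of_week=start.weekday(),
                day_of_month=start.day,
            )
        )
    return out


def fit_rated_model(
    appliance_traces: Mapping[str, PowerSeries], threshold: float = 500.0
) -> RatedModel:
    """Estimate one ON level per appliance as the median power of ON samples.

    Appliances that never reach ``threshold`` are excluded with a warning.
    """
    levels: dict[str, tuple[float, ...]] = {}
    for app, series in appliance_traces.items():
        on = series.values[series.values >= threshold]
        if on.size == 0:
            warnings.warn(f"appliance {app!r} never ON at {threshold} W; excluded")
            continue
        levels[app] = (0.0, float(np.median(on)))
    return RatedModel(levels=levels)


def co_disaggregate(
    aggregate: PowerSeries,
    model: RatedModel,
    combination_cap: int = 4096,
    chunk: int = 200_000,
) -> DisaggregationEstimate:
    """Per-sample exhaustive Combinatorial Optimisation.

    At each sample the state combination minimising the absolute deviation
    ``|aggregate - sum(levels)|`` is chosen; ties break toward fewer ON
    appliances, then toward lexicographically smaller level tuples in
    appliance order.  No temporal smoothing is applied.
    """
    apps = sorted(model.levels)
    if not apps:
        raise ValueError("rated model is empty")
    n_comb = int(np.prod([len(model.levels[a]) for a in apps]))
    if n_comb > combination_cap:
        raise ValueError(
            f"{n_comb} state combinations exceed the cap ({combination_cap}); "
            "reduce the number of appliances or levels"
        )
    combos = list(itertools.product(*(model.levels[a] for a in apps)))
    # stable sort: preferred tie-break order first
    combos.sort(key=lambda c: (sum(1 for x in c if x > 0), c))
    combo_mat = np.array(combos)  # (C, A)
    sums = combo_mat.sum(axis=1)  # (C,)

    agg = aggregate.values
    choice = np.empty(len(agg), dtype=np.int64)
    for i in range(0, len(agg), chunk):
        block = agg[i : i + chunk]
        # argmin over combinations; first index wins ties -> preferred combo
        choice[i : i + chunk] = np.argmin(
            np.abs(block[None, :] - sums[:, None]), axis=0
        )

    power: dict[str, PowerSeries] = {}
    states: dict[str, StateSeries] = {}
    for j, app in enumerate(apps):
        vals = combo_mat[choice, j]
        power[app] = PowerSeries(
            channel_id=app,
            start_time=aggregate.start_time,
            sample_period=aggregate.sample_period,
            values=vals,
        )
        states[app] = StateSeries(
            appliance_id=app,
            start_time=aggregate.start_time,
            sample_period=aggregate.sample_period,
            states=vals > 0,
        )
    return DisaggregationEstimate(power=power, states=states)
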