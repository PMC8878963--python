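"""Daily activity curves, weighted Jensen–Shannon scoring and the IQR rule.

The monitor models the regularity of a daily activity (e.g. cooking) as an
*activity curve*: the normalised distribution, over hour-of-day bins, of
the time spent on appliances mapped to that activity during one day.  An
observation phase stores the curves of an initial period in a database
(the observation store).  In the monitoring phase each new day's curve is
scored against the weighted mixture of stored curves with the generalized
Jensen–Shannon divergence

    JSD_pi(P_1..P_n) = sum_i pi_i * D(P_i || M),   M = sum_i pi_i P_i,

where D is the Kullback–Leibler divergence with natural logarithms.  The
weights give feedback-tagged days weight 1/(N1 + beta*N2) and plain days
beta/(N1 + beta*N2) with beta >= 2, so they always sum to one.  A day is
scored as the equal-weight two-distribution JSD between its curve and the
weighted mixture of the store — bounded by ln 2 and finite even under
disjoint support.

The decision rule is the classical inter-quartile-range test: reference
scores are obtained by leave-one-out scoring of every stored day, and a
monitored day is anomalous when its score falls outside
[Q1 - factor*IQR, Q3 + factor*IQR] (factor 1.5 by default).  Anomalous
days are then explained at two levels: a day-level class (absence, night
usage, or abnormal usage time) and, optionally, per-activation verdicts
(variation vs deviation) derived from appliance self-similarity matrices
with the same IQR rule on nearest-neighbour distances.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .disaggregation import Activation
from .io_formats import ConfigurationError, PipelineConfig

__all__ = [
    "ActivityCurve",
    "WeightVector",
    "ObservationStore",
    "StoredDay",
    "IQRInterval",
    "DayScore",
    "AnomalyReport",
    "build_activity_curve",
    "split_at_midnight",
    "group_by_day",
    "summarize_profile",
    "compute_weights",
    "generalized_jsd",
    "day_score",
    "iqr_interval",
    "classify_day",
    "build_similarity_matrix",
    "classify_activation",
    "classify_anomaly_type",
]

LN2 = math.log(2.0)

DEFAULT_MAPPING: dict[str, frozenset[str]] = {
    "cooking": frozenset({"oven", "kettle", "coffee maker", "microwave", "toaster"}),
    "ironing": frozenset({"iron"}),
    "entertaining": frozenset({"television", "audio system"}),
    "laundry": frozenset({"washing machine", "washer dryer"}),
    "cleaning": frozenset({"dishwasher", "vacuum cleaner"}),
}


# ---------------------------------------------------------------------------
# Activity curves


@dataclass(frozen=True)
class ActivityCurve:
    """Normalised distribution of time spent on one activity over day bins."""

    date: dt.date
    activity_name: str
    bins: np.ndarray
    total_duration: float  # seconds
    empty: bool = False

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=float)
        object.__setattr__(self, "bins", b)
        if not self.empty:
            if self.total_duration <= 0:
                raise ValueError("non-empty curve needs positive total duration")
            if np.any(b < 0) or abs(b.sum() - 1.0) > 1e-9:
                raise ValueError("curve bins must be a probability vector")


def split_at_midnight(activation: Activation) -> list[Activation]:
    """Split an activation crossing midnight into per-day pieces."""
    pieces: list[Activation] = []
    cur = activation
    while True:
        day_end = dt.datetime.combine(
            cur.start.date() + dt.timedelta(days=1), dt.time(), tzinfo=cur.start.tzinfo
        )
        head = (day_end - cur.start).total_seconds()
        if cur.duration <= head:
            pieces.append(cur)
            return pieces
        pieces.append(replace(cur, duration=head))
        nxt_start = day_end
        cur = replace(
            cur,
            start=nxt_start,
            duration=cur.duration - head,
            day_of_week=nxt_start.weekday(),
            day_of_month=nxt_start.day,
        )


def group_by_day(activations: Iterable[Activation]) -> dict[dt.date, list[Activation]]:
    """Group activations by calendar date, splitting midnight-crossers first."""
    out: dict[dt.date, list[Activation]] = {}
    for act in activations:
        for piece in split_at_midnight(act):
            out.setdefault(piece.date, []).append(piece)
    return out


def build_activity_curve(
    activations: Sequence[Activation],
    mapping: Mapping[str, frozenset[str] | set[str]],
    activity: str,
    date: dt.date,
    bins_per_day: int = 24,
) -> ActivityCurve:
    """Build one day's activity curve from that day's activations.

    Each activation of an appliance mapped to the activity contributes its
    duration to the bins it overlaps; the result is normalised to sum 1.
    Days with zero mapped usage give an empty curve.
    """
    if activity not in mapping:
        raise ConfigurationError(f"unknown activity {activity!r}")
    appliances = mapping[activity]
    width = 86400.0 / bins_per_day
    raw = np.zeros(bins_per_day)
    midnight = dt.datetime.combine(date, dt.time(), tzinfo=dt.timezone.utc)
    for act in activations:
        if act.appliance_id not in appliances or act.date != date:
            continue
        t = act.start
        if t.tzinfo is None:
            t = t.replace(tzinfo=dt.timezone.utc)
        s = (t - midnight).total_seconds()
        e = min(s + act.duration, 86400.0)
        b0, b1 = int(s // width), int(min(e, 86400.0 - 1e-9) // width)
        for b in range(b0, b1 + 1):
            overlap = min(e, (b + 1) * width) - max(s, b * width)
            if overlap > 0:
                raw[b] += overlap
    total = float(raw.sum())
    if total <= 0:
        return ActivityCurve(date, activity, np.zeros(bins_per_day), 0.0, empty=True)
    return ActivityCurve(date, activity, raw / total, total)


# ---------------------------------------------------------------------------
# Observation store


@dataclass
class StoredDay:
    date: dt.date
    curves: dict[str, ActivityCurve]
    activations: list[Activation]
    feedback: bool = False


def _act_features(act: Activation) -> tuple[float, float]:
    return (act.start_hour, math.log(act.duration))


def _pairwise_distances(a: Sequence[Activation], b: Sequence[Activation]) -> np.ndarray:
    """Distances between activation feature vectors.

    Features: start hour with circular difference (range [0, 12]) and log
    duration; distance is Euclidean over the two.
    """
    ha = np.array([x.start_hour for x in a])
    hb = np.array([x.start_hour for x in b])
    la = np.array([math.log(x.duration) for x in a])
    lb = np.array([math.log(x.duration) for x in b])
    dh = np.abs(ha[:, None] - hb[None, :])
    dh = np.minimum(dh, 24.0 - dh)
    dl = la[:, None] - lb[None, :]
    return np.sqrt(dh**2 + dl**2)


def build_similarity_matrix(activations: Sequence[Activation]) -> np.ndarray:
    """Self-similarity (distance) matrix of a set of activations."""
    if len(activations) < 2:
        raise ValueError("need at least 2 activations")
    m = _pairwise_distances(activations, activations)
    np.fill_diagonal(m, 0.0)
    return m


class ObservationStore:
    """Ordered database of daily curves, feedback flags and similarity matrices.

    The store holds at most ``capacity`` days (the observation-phase
    length); per appliance it maintains the self-similarity matrix of all
    stored activations, updated incrementally as days are added or
    replaced.
    """

    def __init__(self, capacity: int | None = None):
        self.capacity = capacity
        self.days: list[StoredDay] = []
        self._acts: dict[str, list[tuple[int, Activation]]] = {}  # (slot, act)
        self._mats: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.days)

    @property
    def full(self) -> bool:
        return self.capacity is not None and len(self.days) >= self.capacity

    @property
    def n_feedback(self) -> int:
        return sum(d.feedback for d in self.days)

    def activations_for(self, appliance_id: str) -> list[Activation]:
        return [a for _, a in self._acts.get(appliance_id, [])]

    def matrix_for(self, appliance_id: str) -> np.ndarray:
        if appliance_id not in self._mats:
            raise KeyError(f"no similarity matrix for {appliance_id!r}")
        return self._mats[appliance_id]

    def add_day(
        self,
        date: dt.date,
        curves: Mapping[str, ActivityCurve],
        activations: Sequence[Activation],
        feedback: bool = False,
    ) -> None:
        if self.full:
            raise ValueError("store full; use the replacement procedure")
        slot = len(self.days)
        self.days.append(StoredDay(date, dict(curves), list(activations), feedback))
        self._append_matrix_rows(slot, activations)

    def _append_matrix_rows(self, slot: int, activations: Sequence[Activation]) -> None:
        by_app: dict[str, list[Activation]] = {}
        for act in activations:
            by_app.setdefault(act.appliance_id, []).append(act)
        for app, new in by_app.items():
            old = self.activations_for(app)
            if old:
                cross = _pairwise_distances(old, new)
                block = _pairwise_distances(new, new)
                np.fill_diagonal(block, 0.0)
                m = self._mats[app]
                self._mats[app] = np.block([[m, cross], [cross.T, block]])
            else:
                block = _pairwise_distances(new, new)
                np.fill_diagonal(block, 0.0)
                self._mats[app] = block
            self._acts.setdefault(app, []).extend((slot, a) for a in new)

    def _remove_matrix_rows(self, slot: int) -> None:
        for app in list(self._acts):
            keep = [i for i, (s, _) in enumerate(self._acts[app]) if s != slot]
            if len(keep) != len(self._acts[app]):
                self._acts[app] = [self._acts[app][i] for i in keep]
                m = self._mats[app]
                self._mats[app] = m[np.ix_(keep, keep)]

    def replace_slot(
        self,
        index: int,
        date: dt.date,
        curves: Mapping[str, ActivityCurve],
        activations: Sequence[Activation],
        feedback: bool,
    ) -> None:
        if not 0 <= index < len(self.days):
            raise IndexError(f"invalid store index {index}")
        self._remove_matrix_rows(index)
        self.days[index] = StoredDay(date, dict(curves), list(activations), feedback)
        self._append_matrix_rows(index, activations)


# ---------------------------------------------------------------------------
# Weights and divergence


@dataclass(frozen=True)
class WeightVector:
    """Per-day mixture weights (feedback days 1, plain days beta, normalised)."""

    pi: np.ndarray
    n_feedback: int
    n_plain: int
    beta: float


def compute_weights(store: ObservationStore, beta: float = 2.0) -> WeightVector:
    """Weights over stored days: 1/(N1+beta*N2) with feedback, beta/(N1+beta*N2) without."""
    if beta < 2:
        raise ConfigurationError("beta must be >= 2")
    if not store.days:
        raise ValueError("empty observation store")
    flags = np.array([d.feedback for d in store.days])
    n1, n2 = int(flags.sum()), int((~flags).sum())
    denom = n1 + beta * n2
    pi = np.where(flags, 1.0 / denom, beta / denom)
    return WeightVector(pi=pi, n_feedback=n1, n_plain=n2, beta=beta)


def _as_bins(curve) -> np.ndarray:
    return curve.bins if isinstance(curve, ActivityCurve) else np.asarray(curve, float)


def generalized_jsd(curves: Sequence, weights) -> float:
    """Generalized Jensen–Shannon divergence of weighted distributions.

    ``weights`` may be a :class:`WeightVector` or a plain sequence summing
    to 1.  Natural logarithms; terms with P(x)=0 contribute 0; curves with
    zero weight are ignored.  Zero iff all positive-weight curves are
    identical; the equal-weight two-distribution value is bounded by ln 2.
    """
    w = weights.pi if isinstance(weights, WeightVector) else np.asarray(weights, float)
    P = np.vstack([_as_bins(c) for c in curves])
    if len(w) != len(P):
        raise ValueError("weights and curves length mismatch")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    live = w > 0
    w, P = w[live], P[live]
    M = w @ P
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(P > 0, np.log(np.where(P > 0, P, 1.0) / np.where(M > 0, M, 1.0)), 0.0)
    return float(max((w * (P * logs).sum(axis=1)).sum(), 0.0))


def _jsd2_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise equal-weight two-distribution JSD for stacked curve pairs."""
    M = 0.5 * (A + B)
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = np.where(A > 0, A * np.log(np.where(A > 0, A, 1.0) / np.where(M > 0, M, 1.0)), 0.0)
        tb = np.where(B > 0, B * np.log(np.where(B > 0, B, 1.0) / np.where(M > 0, M, 1.0)), 0.0)
    return np.maximum(0.5 * ta.sum(axis=1) + 0.5 * tb.sum(axis=1), 0.0)


# ---------------------------------------------------------------------------
# Day scoring and the IQR decision


@dataclass(frozen=True)
class DayScore:
    date: dt.date
    activity_name: str
    jsd: float
    empty_day: bool = False


@dataclass(frozen=True)
class IQRInterval:
    """Decision interval [Q1 - factor*IQR, Q3 + factor*IQR]."""

    q1: float
    q3: float
    factor: float = 1.5

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower(self) -> float:
        return self.q1 - self.factor * self.iqr

    @property
    def upper(self) -> float:
        return self.q3 + self.factor * self.iqr

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def iqr_interval(scores: Sequence[float], factor: float = 1.5) -> IQRInterval:
    """Empirical quartiles by linear interpolation between order statistics."""
    arr = np.asarray(scores, dtype=float)
    if arr.size < 4:
        raise ValueError("insufficient observation days (need >= 4 scores)")
    q1, q3 = np.quantile(arr, [0.25, 0.75], method="linear")
    return IQRInterval(q1=float(q1), q3=float(q3), factor=factor)


def _mixture(store: ObservationStore, activity: str, beta: float) -> np.ndarray:
    """pi-weighted mixture of the store's non-empty curves, renormalised."""
    pi = compute_weights(store, beta=beta).pi
    rows, w = [], []
    for day, p in zip(store.days, pi):
        curve = day.curves.get(activity)
        if curve is not None and not curve.empty:
            rows.append(curve.bins)
            w.append(p)
    if not rows:
        raise ValueError(f"no observations for activity {activity!r}")
    w = np.asarray(w)
    return (w / w.sum()) @ np.vstack(rows)


def day_score(
    day_curve: ActivityCurve,
    store: ObservationStore,
    weights: WeightVector | None = None,
) -> DayScore:
    """Score a day as the equal-weight JSD between its curve and the store mixture.

    Bounded by ln 2; an empty day short-circuits (it is classified as
    absence by the anomaly typer rather than scored).
    """
    if day_curve.empty:
        return DayScore(day_curve.date, day_curve.activity_name, float("nan"), True)
    if not store.days:
        raise ValueError("empty observation store")
    beta = weights.beta if weights is not None else 2.0
    m = _mixture(store, day_curve.activity_name, beta)
    score = generalized_jsd([day_curve.bins, m], [0.5, 0.5])
    return DayScore(day_curve.date, day_curve.activity_name, score)


def reference_scores(
    store: ObservationStore, activity: str, beta: float = 2.0
) -> np.ndarray:
    """Leave-one-out day scores of every stored (non-empty) day.

    Each stored curve is scored against the weighted mixture of the other
    stored curves (weights renormalised after removal); this estimates the
    score distribution of normal days.
    """
    pi = compute_weights(store, beta=beta).pi
    rows, w = [], []
    for day, p in zip(store.days, pi):
        curve = day.curves.get(activity)
        if curve is not None and not curve.empty:
            rows.append(curve.bins)
            w.append(p)
    if len(rows) < 2:
        raise ValueError("need >= 2 non-empty stored days")
    P = np.vstack(rows)
    w = np.asarray(w)
    w = w / w.sum()
    M_all = w @ P
    # leave-one-out mixture: remove day i's contribution and renormalise
    M_loo = (M_all[None, :] - w[:, None] * P) / (1.0 - w)[:, None]
    return _jsd2_rows(P, M_loo)


def classify_day(
    day_curve: ActivityCurve,
    store: ObservationStore,
    config: PipelineConfig,
) -> tuple[str, DayScore, IQRInterval]:
    """Decide whether a day is normal or anomalous via the IQR rule.

    Reference scores come from leave-one-out scoring of the stored days;
    the monitored day is anomalous when its score falls outside the
    interval, or immediately when its curve is empty.
    """
    refs = reference_scores(store, day_curve.activity_name, beta=config.beta)
    interval = iqr_interval(refs, factor=config.iqr_factor)
    score = day_score(day_curve, store, compute_weights(store, config.beta))
    if score.empty_day:
        return "anomalous", score, interval
    decision = "normal" if interval.contains(score.jsd) else "anomalous"
    return decision, score, interval


# ---------------------------------------------------------------------------
# Appliance-level analysis and anomaly typing


def classify_activation(activation: Activation, store: ObservationStore) -> str:
    """Label an activation a benign ``variation`` or a reportable ``deviation``.

    The threshold is the IQR upper bound over the historical
    nearest-neighbour distances read off the appliance's self-similarity
    matrix; the activation is a deviation when its own nearest-neighbour
    distance to history exceeds it.
    """
    history = store.activations_for(activation.appliance_id)
    if len(history) < 2:
        raise ValueError(f"no history for appliance {activation.appliance_id!r}")
    m = store.matrix_for(activation.appliance_id)
    off = m + np.diag(np.full(len(m), np.inf))
    nn = off.min(axis=1)
    threshold = iqr_interval(nn, factor=1.5).upper
    d = float(_pairwise_distances([activation], history).min())
    return "deviation" if d > threshold else "variation"


def classify_anomaly_type(
    day: dt.date,
    activations: Sequence[Activation],
    decision: str,
    night_band: tuple[float, float] = (0.0, 4.0),
) -> str:
    """Explain an anomalous day: absence, night usage, or abnormal usage time.

    Priority order: no activations at all -> ``absence``; any activation
    starting inside the night band -> ``night_usage``; otherwise
    ``abnormal_usage_time``.
    """
    if decision != "anomalous":
        raise ValueError("anomaly typing is only defined for anomalous days")
    if not activations:
        return "absence"
    lo, hi = night_band
    if any(lo <= a.start_hour < hi for a in activations):
        return "night_usage"
    return "abnormal_usage_time"


def summarize_profile(store: ObservationStore, activity: str) -> ActivityCurve:
    """Mean of the stored non-empty curves, renormalised — the occupant profile."""
    rows = []
    total = 0.0
    for day in store.days:
        curve = day.curves.get(activity)
        if curve is not None and not curve.empty:
            rows.append(curve.bins)
            total += curve.total_duration
    if not rows:
        raise ValueError(f"no observations for activity {activity!r}")
    mean = np.mean(rows, axis=0)
    mean = mean / mean.sum()
    date = store.days[-1].date
    return ActivityCurve(date, activity, mean, total / len(rows))


# ---------------------------------------------------------------------------
# Reports


@dataclass
class AnomalyReport:
    """Per-day decision with scores, interval and contributing activations."""

    date: dt.date
    decision: str  # "normal" | "anomalous"
    anomaly_class: str | None
    scores: dict[str, DayScore]
    intervals: dict[str, IQRInterval]
    activations: list[Activation]
    activation_verdicts: dict[int, str] = field(default_factory=dict)
    curves: dict[str, ActivityCurve] = field(default_factory=dict)  # not serialised

    def to_record(self) -> dict:
        finite = {a: s.jsd for a, s in self.scores.items() if not s.empty_day}
        top = max(finite, key=finite.get) if finite else None
        return {
            "date": self.date.isoformat(),
            "score": finite[top] if top else None,
            "interval": (
                {"lower": self.intervals[top].lower, "upper": self.intervals[top].upper}
                if top and top in self.intervals
                else None
            ),
            "decision": self.decision,
            "anomaly_class": self.anomaly_class,
            "activities": {
                a: {"score": None if s.empty_day else s.jsd, "empty": s.empty_day}
                for a, s in self.scores.items()
            },
            "activations": [
                {
                    "appliance": act.appliance_id,
                    "start": act.start.isoformat(),
                    "duration": act.duration,
                    "max_power": act.max_power,
                    "day_of_week": act.day_of_week,
                    "day_of_month": act.day_of_month,
                    "verdict": self.activation_verdicts.get(i),
                }
                for i, act in enumerate(self.activations)
            ],
        }
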