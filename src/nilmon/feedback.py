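"""External-agent feedback integration and the store replacement procedure.

After each monitored day the observation store is maintained as a sliding
window of fixed capacity so the profile tracks seasonal changes in the
occupant's routine:

* a normal day with no feedback is folded in, replacing the day chosen by
  the forgetting rule below;
* an anomalous day with no feedback leaves the store untouched (the
  framework trusts its own report);
* a rejected anomaly (the agent found it irrelevant) is folded in and
  tagged as feedback, so the profile learns the new habit;
* a confirmed anomaly never enters the store.

The forgetting rule prefers unlabelled (no-feedback) entries; within the
candidate set days are ranked by leave-one-out divergence (most divergent
first) with age as the tie-break (oldest first).  When every stored day
has feedback the rule degrades to "oldest most divergent day".
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .disaggregation import Activation
from .monitor import (
    ActivityCurve,
    AnomalyReport,
    ObservationStore,
    StoredDay,
    reference_scores,
)

__all__ = [
    "FeedbackRecord",
    "load_feedback",
    "select_replacement",
    "replace_day",
    "update_after_day",
]

CONFIRM = "confirm_anomaly"
REJECT = "reject_anomaly"


@dataclass(frozen=True)
class FeedbackRecord:
    """One asynchronous verdict from the external agent on a reported day."""

    date: dt.date
    verdict: str  # "confirm_anomaly" | "reject_anomaly"
    received_at: dt.datetime | None = None

    def __post_init__(self) -> None:
        if self.verdict not in (CONFIRM, REJECT):
            raise ValueError(f"unknown verdict {self.verdict!r}")


def load_feedback(path) -> dict[dt.date, FeedbackRecord]:
    """Read a feedback CSV of (date, verdict) rows."""
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[dt.date, FeedbackRecord] = {}
    for _, row in df.iterrows():
        date = dt.date.fromisoformat(str(row["date"]))
        out[date] = FeedbackRecord(date=date, verdict=str(row["verdict"]))
    return out


def _divergences(store: ObservationStore, beta: float = 2.0) -> np.ndarray:
    """Per-day leave-one-out divergence, averaged over scoreable activities."""
    n = len(store.days)
    totals = np.zeros(n)
    counts = np.zeros(n)
    activities = {a for d in store.days for a in d.curves}
    for activity in activities:
        idx = [
            i
            for i, d in enumerate(store.days)
            if activity in d.curves and not d.curves[activity].empty
        ]
        if len(idx) < 2:
            continue
        scores = reference_scores(store, activity, beta=beta)
        for i, s in zip(idx, scores):
            totals[i] += s
            counts[i] += 1
    with np.errstate(invalid="ignore"):
        div = np.divide(totals, counts, out=np.zeros(n), where=counts > 0)
    return div


def select_replacement(store: ObservationStore, beta: float = 2.0) -> int:
    """Pick the store slot to overwrite.

    While unlabelled (no-feedback) days exist they are the candidates and
    the oldest one is evicted — a rolling window that keeps the reference
    score distribution representative of recent normal behaviour.  (Always
    evicting the most divergent unlabelled day instead progressively
    homogenises the store and collapses the decision interval.)  When every
    stored day has feedback, the oldest most divergent day is evicted.
    """
    if not store.days:
        raise ValueError("empty observation store")
    unlabelled = [i for i, d in enumerate(store.days) if not d.feedback]
    div = _divergences(store, beta=beta)
    if unlabelled:
        # oldest first; ties -> most divergent, then lowest slot
        return min(unlabelled, key=lambda i: (store.days[i].date, -div[i], i))
    candidates = list(range(len(store.days)))
    # most divergent first; ties -> oldest date, then lowest slot
    return min(candidates, key=lambda i: (-div[i], store.days[i].date, i))


def replace_day(
    store: ObservationStore,
    index: int,
    new_day: tuple[dt.date, Mapping[str, ActivityCurve], Sequence[Activation]] | StoredDay,
    feedback_flag: bool = False,
) -> ObservationStore:
    """Overwrite one stored day and update the similarity matrices in place.

    Rows and columns of the evicted day's activations are removed from each
    appliance matrix and rows for the new day's activations are appended
    with freshly computed distances; the incremental result equals a full
    rebuild.
    """
    if isinstance(new_day, StoredDay):
        date, curves, activations = new_day.date, new_day.curves, new_day.activations
    else:
        date, curves, activations = new_day
    store.replace_slot(index, date, curves, activations, feedback_flag)
    return store


def update_after_day(
    store: ObservationStore,
    day: dt.date,
    report: AnomalyReport,
    feedback: FeedbackRecord | None = None,
    beta: float = 2.0,
) -> ObservationStore:
    """Fold a monitored day into the store according to decision and feedback."""
    if report.date != day:
        raise ValueError(f"no report for day {day}")
    new_day = (day, report.curves, report.activations)
    if feedback is None:
        if report.decision == "normal":
            idx = select_replacement(store, beta=beta)
            replace_day(store, idx, new_day, feedback_flag=False)
        # anomalous without feedback: trusted report, store untouched
    elif feedback.verdict == REJECT:
        idx = select_replacement(store, beta=beta)
        replace_day(store, idx, new_day, feedback_flag=True)
    # confirm_anomaly: confirmed deviations never contaminate the profile
    return store
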