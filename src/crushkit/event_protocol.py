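"""Hyperkalemia intervention events and time-to-event analysis.

The critical-care protocol treats any scheduled blood draw with potassium
strictly above 5.0 mmol/L (insulin, calcium gluconate, dextrose); each
exceedance is one protocol activation.  This module detects those events
from potassium series, summarises intervention burden, and implements the
Kaplan–Meier product-limit estimator and the two-group log-rank test from
first principles for time-to-first-intervention analysis.  Subjects are
right-censored at the 48 h endpoint (or at death, which censors the
intervention clock).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "InterventionEvent",
    "SurvivalDataset",
    "KMCurve",
    "LogRankResult",
    "detect_interventions",
    "intervention_ratio",
    "km_estimate",
    "logrank_test",
]

K_THRESHOLD_MMOL_L = 5.0


@dataclass(frozen=True)
class InterventionEvent:
    """One protocolized hyperkalemia treatment."""

    animal_id: str
    time_h: float
    trigger_potassium_mmol_l: float


@dataclass(frozen=True)
class SurvivalDataset:
    """Per-subject time to (first) event with right-censoring and group label."""

    times_h: tuple[float, ...]
    observed: tuple[bool, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.times_h)
        if not (len(self.observed) == len(self.groups) == n):
            raise ValueError("times, observed flags and groups must align")
        if n == 0:
            raise ValueError("empty survival dataset")
        if any(t < 0 for t in self.times_h):
            raise ValueError("event/censoring times must be >= 0")

    def subset(self, group: str) -> "SurvivalDataset":
        idx = [i for i, g in enumerate(self.groups) if g == group]
        return SurvivalDataset(
            tuple(self.times_h[i] for i in idx),
            tuple(self.observed[i] for i in idx),
            tuple(self.groups[i] for i in idx),
        )

    @property
    def group_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return tuple(seen)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: tuple[float, ...]        # distinct event times, increasing
    survival: tuple[float, ...]     # S(t) just after each event time
    n_at_risk: tuple[int, ...]
    n_events: tuple[int, ...]

    def at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p: float
    observed: dict[str, float]
    expected: dict[str, float]


def detect_interventions(
    animal_id: str,
    times_h,
    potassium_mmol_l,
    threshold: float = K_THRESHOLD_MMOL_L,
) -> list[InterventionEvent]:
    """One event per scheduled measurement with K strictly above threshold."""
    t = np.asarray(times_h, dtype=float)
    k = np.asarray(potassium_mmol_l, dtype=float)
    if t.shape != k.shape:
        raise ValueError("times and potassium values must align")
    if np.any(np.diff(t) <= 0):
        raise ValueError("potassium series times must be strictly increasing")
    return [
        InterventionEvent(animal_id, float(ti), float(ki))
        for ti, ki in zip(t, k)
        if ki > threshold
    ]


def intervention_ratio(group_a_counts, group_b_counts) -> float:
    """Ratio of median intervention counts, median(b)/median(a), one decimal."""
    a = np.asarray(group_a_counts, dtype=float)
    b = np.asarray(group_b_counts, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("intervention count vectors must be non-empty")
    med_a = float(np.median(a))
    if med_a == 0:
        raise ValueError("denominator group has zero median intervention count")
    return round(float(np.median(b)) / med_a, 1)


def _km_single(times: np.ndarray, observed: np.ndarray) -> KMCurve:
    order = np.argsort(times, kind="stable")
    times, observed = times[order], observed[order]
    n = len(times)
    out_t, out_s, out_n, out_d = [], [], [], []
    s = 1.0
    i = 0
    while i < n:
        t = times[i]
        j = i
        d = 0
        while j < n and times[j] == t:
            d += int(observed[j])
            j += 1
        if d > 0:
            at_risk = n - i
            s *= 1.0 - d / at_risk
            out_t.append(float(t))
            out_s.append(s)
            out_n.append(at_risk)
            out_d.append(d)
        i = j
    return KMCurve(tuple(out_t), tuple(out_s), tuple(out_n), tuple(out_d))


def km_estimate(data: SurvivalDataset) -> dict[str, KMCurve]:
    """Kaplan–Meier estimate per group: S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    curves = {}
    for g in data.group_labels:
        sub = data.subset(g)
        curves[g] = _km_single(
            np.asarray(sub.times_h, dtype=float),
            np.asarray(sub.observed, dtype=bool),
        )
    return curves


def logrank_test(data: SurvivalDataset) -> LogRankResult:
    """Two-group log-rank test with pooled-risk-set handling of ties.

    At each distinct event time the expected events per group are allocated
    in proportion to the group's share of the pooled risk set; the statistic
    is (O - E)^2 / V with the hypergeometric variance, chi-square(1) under
    the null.
    """
    labels = data.group_labels
    if len(labels) != 2:
        raise ValueError(f"log-rank test requires exactly 2 groups, got {len(labels)}")
    times = np.asarray(data.times_h, dtype=float)
    obs = np.asarray(data.observed, dtype=bool)
    grp = np.asarray([g == labels[0] for g in data.groups])  # True = group 0
    if not obs.any():
        raise ValueError("log-rank statistic undefined: no observed events")

    event_times = np.unique(times[obs])
    o0 = e0 = v = 0.0
    total_o = {labels[0]: 0.0, labels[1]: 0.0}
    for t in event_times:
        at_risk = times >= t
        n_tot = int(at_risk.sum())
        n0 = int((at_risk & grp).sum())
        dying = obs & (times == t)
        d_tot = int(dying.sum())
        d0 = int((dying & grp).sum())
        o0 += d0
        e0 += d_tot * n0 / n_tot
        if n_tot > 1:
            v += d_tot * (n0 / n_tot) * (1 - n0 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
        total_o[labels[0]] += d0
        total_o[labels[1]] += d_tot - d0
    if v <= 0:
        raise ValueError("log-rank variance is zero; groups cannot be compared")
    stat = (o0 - e0) ** 2 / v
    p = float(_sps.chi2.sf(stat, 1))
    expected = {labels[0]: e0, labels[1]: sum(total_o.values()) - e0}
    return LogRankResult(float(stat), 1, p, total_o, expected)
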