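"""Kaplan-Meier survival estimation and the Breslow (generalized Wilcoxon)
two-group test.

The Kaplan-Meier estimator is the product-limit survivor function
S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i, with
d_i deaths at t_i and n_i the number at risk just before t_i.  At tied
times, deaths precede censorings: a record censored at t_i is still at risk
for the events at t_i.

The Breslow test is a weighted log-rank test with weight w_i = n_i (the
total number at risk), so early event times — where most subjects remain at
risk — dominate.  With unit weights the same machinery is the ordinary
log-rank test.  For groups a/b:

    chi2 = ( sum_i w_i (d_ai - e_ai) )^2 / sum_i w_i^2 v_i

with hypergeometric expectation e_ai = d_i * n_ai / n_i and variance
v_i = d_i (n_ai/n_i)(1 - n_ai/n_i)(n_i - d_i)/(n_i - 1), referred to a
chi-square distribution on 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DataError


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient: follow-up time, event indicator, and expression stratum."""

    patient_id: str
    time: float
    event: bool          # True = death observed, False = censored
    group: str

    def __post_init__(self):
        if self.time < 0:
            raise DataError(
                f"patient {self.patient_id!r}: negative follow-up time"
            )
        if not self.group:
            raise DataError(f"patient {self.patient_id!r}: empty group label")


@dataclass(frozen=True)
class KMCurve:
    """A right-continuous step estimate of the survivor function."""

    group: str
    times: np.ndarray         # distinct event times, ascending
    survival: np.ndarray      # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t): value of the step function at time t (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def _group_records(
    records: Iterable[SurvivalRecord],
) -> dict[str, list[SurvivalRecord]]:
    grouped: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        grouped.setdefault(r.group, []).append(r)
    return grouped


def _km_one_group(recs: Sequence[SurvivalRecord], group: str) -> KMCurve:
    times = np.array([r.time for r in recs], dtype=float)
    events = np.array([r.event for r in recs], dtype=bool)
    event_times = np.unique(times[events])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for t in event_times:
        n_i = int((times >= t).sum())   # censored at t still at risk
        d_i = int((events & (times == t)).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        n_ev.append(d_i)
    return KMCurve(
        group=group,
        times=event_times,
        survival=np.array(surv),
        n_at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(n_ev, dtype=int),
    )


def km_estimate(records: Iterable[SurvivalRecord]) -> dict[str, KMCurve]:
    """Kaplan-Meier survivor curve per expression stratum."""
    grouped = _group_records(records)
    if not grouped:
        raise DataError("no survival records")
    return {g: _km_one_group(recs, g) for g, recs in sorted(grouped.items())}


@dataclass(frozen=True)
class TwoSampleTestResult:
    statistic: float   # chi-square, 1 df
    pvalue: float
    test: str

    def __iter__(self):
        return iter((self.statistic, self.pvalue))


def _weighted_logrank(
    records: Iterable[SurvivalRecord],
    group_a: str,
    group_b: str,
    weighting: Literal["breslow", "logrank"],
) -> TwoSampleTestResult:
    grouped = _group_records(records)
    for g in (group_a, group_b):
        if g not in grouped or not grouped[g]:
            raise DataError(f"group {g!r} is empty")
    recs = grouped[group_a] + grouped[group_b]
    times = np.array([r.time for r in recs], dtype=float)
    events = np.array([r.event for r in recs], dtype=bool)
    in_a = np.array([r.group == group_a for r in recs], dtype=bool)
    if not events.any():
        raise DataError("no events in either group: test undefined")

    z = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n_i = int(at_risk.sum())
        n_ai = int((at_risk & in_a).sum())
        d_i = int((events & (times == t)).sum())
        d_ai = int((events & (times == t) & in_a).sum())
        e_ai = d_i * n_ai / n_i
        v_i = 0.0
        if n_i > 1:
            v_i = (
                d_i * (n_ai / n_i) * (1 - n_ai / n_i) * (n_i - d_i) / (n_i - 1)
            )
        w_i = float(n_i) if weighting == "breslow" else 1.0
        z += w_i * (d_ai - e_ai)
        var += w_i * w_i * v_i
    if var == 0.0:
        # all events in risk sets fully on one side; no information
        return TwoSampleTestResult(0.0, 1.0, weighting)
    chi2 = z * z / var
    return TwoSampleTestResult(
        float(chi2), float(stats.chi2.sf(chi2, 1)), weighting
    )


def breslow_test(
    records: Iterable[SurvivalRecord], group_a: str, group_b: str
) -> TwoSampleTestResult:
    """Breslow (generalized Wilcoxon) test: weights = number at risk."""
    return _weighted_logrank(records, group_a, group_b, "breslow")


def logrank_test(
    records: Iterable[SurvivalRecord], group_a: str, group_b: str
) -> TwoSampleTestResult:
    """Ordinary (unit-weight) log-rank test on the same machinery."""
    return _weighted_logrank(records, group_a, group_b, "logrank")
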