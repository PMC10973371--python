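"""Survival read-outs: Kaplan-Meier, log-rank, Pearson trait correlation and
IPCW time-dependent ROC.

The Kaplan-Meier product-limit estimator is implemented directly so the
curve type can expose at-risk/event counts and so the same kernel estimates
the censoring distribution for inverse-probability-of-censoring weights
(IPCW) in the cumulative/dynamic time-dependent AUC. The two-group log-rank
test delegates to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

from .datatypes import ValidationError

log = logging.getLogger("sigforge")

DAYS_PER_YEAR = 365.25


def years_to_days(years: float) -> float:
    return years * DAYS_PER_YEAR


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate with its risk table.

    ``event_times`` are the distinct times with at least one event;
    ``survival_prob[i]`` is S(event_times[i]). The curve is right-continuous
    with S(0) = 1.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])

    def survival_before(self, t: float) -> float:
        """Left limit S(t-)."""
        idx = np.searchsorted(self.event_times, t, side="left") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


def kaplan_meier(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Subjects censored at an event time are kept in the risk set for that
    time (events processed first, the standard convention).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValidationError("empty survival input")
    if (t < 0).any():
        raise ValidationError("negative survival times")
    if set(np.unique(e)) - {0, 1}:
        raise ValidationError("event indicators must be 0/1")
    event_times = np.unique(t[e == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for et in event_times:
        n = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n
        surv.append(s)
        at_risk.append(n)
        n_ev.append(d)
    return SurvivalCurve(
        event_times=event_times,
        survival_prob=np.asarray(surv),
        n_at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_ev),
    )


@dataclass
class LogRankResult:
    chi2: float
    p: float
    n_1: int
    n_2: int


def logrank_test(times_1, events_1, times_2, events_2) -> LogRankResult:
    """Two-group log-rank test, two-sided p from chi-square with 1 df."""
    t1, t2 = np.asarray(times_1, dtype=float), np.asarray(times_2, dtype=float)
    e1, e2 = np.asarray(events_1, dtype=int), np.asarray(events_2, dtype=int)
    if t1.size == 0 or t2.size == 0:
        raise ValidationError("both groups must be non-empty")
    if e1.sum() + e2.sum() == 0:
        log.warning("log-rank with zero events; returning p = 1")
        return LogRankResult(chi2=0.0, p=1.0, n_1=t1.size, n_2=t2.size)
    res = _lifelines_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):
        chi2, p = 0.0, 1.0
    return LogRankResult(chi2=chi2, p=p, n_1=t1.size, n_2=t2.size)


@dataclass
class TraitCorrelation:
    r: float
    p: float
    n: int


def trait_correlation(values_x, values_y) -> TraitCorrelation:
    """Pearson correlation with the two-sided t-distribution p-value."""
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.size != y.size:
        raise ValidationError("vectors must have equal length")
    if x.size < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance in a correlation input")
    r, p = stats.pearsonr(x, y)
    return TraitCorrelation(r=float(r), p=float(p), n=int(x.size))


@dataclass
class TimeROCResult:
    horizon: float
    auc: float
    n_cases: int
    n_controls: int
    weighting: str = "IPCW-KM"


def time_dependent_auc(scores, times, events, horizon: float) -> TimeROCResult:
    """Cumulative/dynamic time-dependent AUC with IPCW-KM weights.

    Cases are subjects with an event at or before the horizon, controls
    those still event-free strictly past it. Case i is weighted by
    1/G(T_i-) and control j by 1/G(horizon), where G is the Kaplan-Meier
    estimate of the censoring survival function; tied scores get half
    credit. Without censoring this reduces to the plain rank AUC.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if horizon <= 0 or horizon >= t.max():
        raise ValidationError(f"horizon {horizon} outside observed follow-up (0, {t.max()})")
    case = (e == 1) & (t <= horizon)
    control = t > horizon
    if not case.any() or not control.any():
        raise ValidationError(f"no cases or no controls at horizon {horizon}")

    g_curve = kaplan_meier(t, 1 - e)  # censoring distribution
    g_case = np.array([g_curve.survival_before(ti) for ti in t[case]])
    g_case = np.clip(g_case, 1e-12, None)
    w_case = 1.0 / g_case
    w_control = np.full(int(control.sum()), 1.0 / max(g_curve.survival_at(horizon), 1e-12))

    sc, sk = s[case], s[control]
    greater = (sc[:, None] > sk[None, :]).astype(float)
    ties = (sc[:, None] == sk[None, :]).astype(float)
    num = (w_case[:, None] * w_control[None, :] * (greater + 0.5 * ties)).sum()
    den = w_case.sum() * w_control.sum()
    return TimeROCResult(
        horizon=float(horizon),
        auc=float(num / den),
        n_cases=int(case.sum()),
        n_controls=int(control.sum()),
    )


def km_table(curve: SurvivalCurve) -> pd.DataFrame:
    """Risk table as a DataFrame (for TSV emission)."""
    return pd.DataFrame(
        {
            "time": curve.event_times,
            "n_at_risk": curve.n_at_risk,
            "n_events": curve.n_events,
            "survival": curve.survival_prob,
        }
    )
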