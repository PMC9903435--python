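"""Censoring-aware evaluation metrics.

All metrics take predictions oriented as *survival times* (larger value =
longer predicted survival), matching how the models report median survival
times.  Callers holding risk scores (larger = worse) must negate before
calling :func:`concordance_index`.

Metrics whose denominator can be empty (no comparable pairs, no uncensored
subjects, no horizon-evaluable subjects) return an explicit undefined result:
``value = nan`` with ``n = 0`` — never a silent 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
from scipy import stats

from .survival import SurvivalCurve, as_time_event

__all__ = [
    "MetricResult",
    "LogRankResult",
    "MetricBundle",
    "concordance_index",
    "mae_uncensored",
    "horizon_status_accuracy",
    "kaplan_meier",
    "log_rank_test",
    "compute_metric_bundle",
]

TWO_YEARS_DAYS = 730.0
FIVE_YEARS_DAYS = 1825.0


class MetricResult(NamedTuple):
    """A metric value plus the evaluable count behind it (nan/0 = undefined)."""

    value: float
    n: int

    @property
    def defined(self) -> bool:
        return self.n > 0


class LogRankResult(NamedTuple):
    statistic: float
    p_value: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.statistic)


def concordance_index(records, predicted_times) -> MetricResult:
    """Harrell's concordance index over comparable pairs.

    A pair ``(i, j)`` is comparable when ``T_i < T_j`` and subject ``i`` died
    (the shorter time is a true event); pairs with tied observed times are
    excluded.  The pair is concordant when ``predicted_i < predicted_j``;
    tied predictions score 0.5.
    """
    t, e = as_time_event(records)
    p = np.asarray(predicted_times, dtype=float).reshape(-1)
    if p.shape != t.shape:
        raise ValueError("records and predicted_times are misaligned")
    # comparable[i, j]: T_i < T_j and E_i = 1
    comparable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        return MetricResult(float("nan"), 0)
    less = p[:, None] < p[None, :]
    tied = p[:, None] == p[None, :]
    score = np.sum(comparable * (less + 0.5 * tied))
    return MetricResult(float(score / n_pairs), n_pairs)


def mae_uncensored(records, predicted_times) -> MetricResult:
    """Mean absolute error between predictions and observed times, events only.

    Censored subjects are excluded: their recorded time under-states the true
    survival time, so the absolute error against it is not meaningful.
    """
    t, e = as_time_event(records)
    p = np.asarray(predicted_times, dtype=float).reshape(-1)
    if p.shape != t.shape:
        raise ValueError("records and predicted_times are misaligned")
    mask = e == 1
    n = int(mask.sum())
    if n == 0:
        return MetricResult(float("nan"), 0)
    return MetricResult(float(np.mean(np.abs(p[mask] - t[mask]))), n)


def horizon_status_accuracy(
    records, predicted_times, horizon_days: float
) -> MetricResult:
    """Accuracy of alive/dead status at a fixed horizon (e.g. 2 or 5 years).

    True status is *alive* when ``T >= horizon`` (regardless of the event
    indicator) and *dead* when ``E = 1`` and ``T < horizon``.  Subjects
    censored before the horizon have unknowable status and are excluded from
    the denominator.  Predicted status: ``predicted_time >= horizon``.
    """
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    t, e = as_time_event(records)
    p = np.asarray(predicted_times, dtype=float).reshape(-1)
    if p.shape != t.shape:
        raise ValueError("records and predicted_times are misaligned")
    evaluable = (t >= horizon_days) | ((e == 1) & (t < horizon_days))
    n = int(evaluable.sum())
    if n == 0:
        return MetricResult(float("nan"), 0)
    true_alive = t[evaluable] >= horizon_days
    pred_alive = p[evaluable] >= horizon_days
    return MetricResult(float(np.mean(true_alive == pred_alive)), n)


def kaplan_meier(records) -> SurvivalCurve:
    """Product-limit (Kaplan-Meier) estimator of the survival function.

    Returns a step curve over the distinct observed event times with
    ``S(0) = 1`` prepended.  With no events the curve is flat at 1.
    """
    t, e = as_time_event(records)
    if t.size == 0:
        raise ValueError("empty cohort")
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    n = t.size
    times = [0.0]
    surv = [1.0]
    s = 1.0
    for tv in np.unique(ts[es == 1]):
        at_risk = n - int(np.searchsorted(ts, tv, side="left"))
        d = int(np.sum(es[ts == tv]))
        s *= 1.0 - d / at_risk
        times.append(float(tv))
        surv.append(s)
    return SurvivalCurve(np.asarray(times), np.asarray(surv))


def log_rank_test(group_a, group_b) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct pooled event time the observed events in group A are
    compared with their hypergeometric expectation given the at-risk counts;
    the statistic is ``(sum(O - E))^2 / sum(V)`` referred to chi-square with
    one degree of freedom.  Returns an undefined result (nan, nan) when the
    pooled sample has no events or no variance.
    """
    ta, ea = as_time_event(group_a)
    tb, eb = as_time_event(group_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])
    if e.sum() == 0:
        return LogRankResult(float("nan"), float("nan"))

    o_minus_e = 0.0
    var = 0.0
    for tv in np.unique(t[e == 1]):
        at_risk = t >= tv
        n_tot = int(at_risk.sum())
        n_a = int((at_risk & (g == 0)).sum())
        died = (t == tv) & (e == 1)
        d_tot = int(died.sum())
        d_a = int((died & (g == 0)).sum())
        o_minus_e += d_a - d_tot * n_a / n_tot
        if n_tot > 1:
            var += (
                d_tot
                * (n_a / n_tot)
                * (1 - n_a / n_tot)
                * (n_tot - d_tot)
                / (n_tot - 1)
            )
    if var <= 0:
        return LogRankResult(float("nan"), float("nan"))
    stat = o_minus_e**2 / var
    return LogRankResult(float(stat), float(stats.chi2.sf(stat, df=1)))


@dataclass(frozen=True)
class MetricBundle:
    """The evaluation bundle reported per cross-validation fold.

    ``n_pairs`` / ``n_uncensored`` / ``n_eval_2yr`` / ``n_eval_5yr`` record
    the evaluable denominators so that the censoring-exclusion rules are
    auditable.
    """

    c_index: float
    mae_days: float
    acc_2yr: float
    acc_5yr: float
    n_pairs: int
    n_uncensored: int
    n_eval_2yr: int
    n_eval_5yr: int

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metric_bundle(
    records,
    predicted_times,
    horizons: tuple[float, float] = (TWO_YEARS_DAYS, FIVE_YEARS_DAYS),
) -> MetricBundle:
    """Compute the full per-fold metric bundle from predicted survival times."""
    ci = concordance_index(records, predicted_times)
    mae = mae_uncensored(records, predicted_times)
    a2 = horizon_status_accuracy(records, predicted_times, horizons[0])
    a5 = horizon_status_accuracy(records, predicted_times, horizons[1])
    return MetricBundle(
        c_index=ci.value,
        mae_days=mae.value,
        acc_2yr=a2.value,
        acc_5yr=a5.value,
        n_pairs=ci.n,
        n_uncensored=mae.n,
        n_eval_2yr=a2.n,
        n_eval_5yr=a5.n,
    )
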