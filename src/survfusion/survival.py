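"""Hazard-based survival mathematics shared by every model.

All models in this package emit a single scalar per subject: the log relative
hazard ``h(x)``.  Under a proportional-hazards model the hazard of subject
``x`` is ``lambda(t | x) = lambda_0(t) * exp(h(x))``.  This module supplies

* the negative log partial likelihood (the training loss of the neural
  survival models, Breslow convention for ties) and its analytic gradient,
* a Newton-Raphson Cox proportional-hazards fitter with the Efron tie
  correction (for the tabular clinical baseline model),
* the Breslow estimator of the cumulative baseline hazard ``H_0(t)``,
* per-subject survival curves ``S(t | x) = exp(-H_0(t) * exp(h))``, and
* the median-survival-time reader that turns a curve into an absolute
  predicted survival time in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "SurvivalRecord",
    "BaselineHazard",
    "SurvivalCurve",
    "CoxFit",
    "DegenerateBatchError",
    "as_time_event",
    "make_records",
    "neg_log_partial_likelihood",
    "partial_likelihood_gradient",
    "fit_cph",
    "breslow_baseline",
    "survival_curve",
    "median_survival_time",
    "MedianSurvival",
]

#: clip applied to risk scores before exponentiation in the Breslow estimator
RISK_CLIP = 50.0


class DegenerateBatchError(ValueError):
    """Raised when a batch/cohort contains no observed events.

    The partial likelihood is undefined without at least one event; callers
    (e.g. the minibatch sampler) should resample or skip such batches.
    """


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: time in days and event indicator.

    ``event`` is 1 when death was observed at ``time`` and 0 when the subject
    was censored (follow-up ended with the subject still alive).
    """

    subject_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not (self.time > 0) or not math.isfinite(self.time):
            raise ValueError(
                f"subject {self.subject_id!r}: time must be positive and finite, "
                f"got {self.time!r}"
            )
        if self.event not in (0, 1):
            raise ValueError(
                f"subject {self.subject_id!r}: event must be 0 or 1, got {self.event!r}"
            )


def make_records(
    times: Iterable[float],
    events: Iterable[int],
    subject_ids: Iterable[str] | None = None,
) -> list[SurvivalRecord]:
    """Build a list of :class:`SurvivalRecord` from parallel arrays."""
    times = list(times)
    events = list(events)
    if subject_ids is None:
        subject_ids = [f"s{i:05d}" for i in range(len(times))]
    return [
        SurvivalRecord(sid, float(t), int(e))
        for sid, t, e in zip(subject_ids, times, events, strict=True)
    ]


def as_time_event(records) -> tuple[np.ndarray, np.ndarray]:
    """Coerce survival outcomes to ``(times, events)`` float/int arrays.

    Accepts a sequence of :class:`SurvivalRecord`, a structured array with
    ``time``/``event`` (or scikit-survival style boolean-event) fields, a
    mapping/DataFrame with ``time`` and ``event`` columns, or a 2-tuple of
    arrays.
    """
    if isinstance(records, tuple) and len(records) == 2:
        t = np.asarray(records[0], dtype=float)
        e = np.asarray(records[1])
    elif isinstance(records, np.ndarray) and records.dtype.names:
        names = records.dtype.names
        tname = "time" if "time" in names else names[1]
        ename = "event" if "event" in names else names[0]
        t = np.asarray(records[tname], dtype=float)
        e = np.asarray(records[ename])
    elif hasattr(records, "columns"):  # pandas DataFrame
        t = np.asarray(records["time"], dtype=float)
        e = np.asarray(records["event"])
    elif len(records) > 0 and isinstance(records[0], SurvivalRecord):
        t = np.array([r.time for r in records], dtype=float)
        e = np.array([r.event for r in records])
    else:
        raise TypeError(f"cannot interpret {type(records)!r} as survival outcomes")
    e = e.astype(bool).astype(np.int64)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be aligned 1-D arrays")
    return t, e


@dataclass(frozen=True)
class BaselineHazard:
    """Step-function cumulative baseline hazard ``H_0`` at distinct event times.

    ``cumulative_hazard[i]`` is ``H_0`` evaluated at ``event_times[i]``;
    ``H_0(t) = 0`` for ``t`` before the first event time.
    """

    event_times: np.ndarray
    cumulative_hazard: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        h = np.asarray(self.cumulative_hazard, dtype=float)
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "cumulative_hazard", h)
        if t.shape != h.shape or t.ndim != 1:
            raise ValueError("event_times and cumulative_hazard must be aligned 1-D")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] <= 0):
            raise ValueError("event_times must be strictly increasing and positive")
        if h.size and (np.any(h < 0) or np.any(np.diff(h) < 0)):
            raise ValueError("cumulative_hazard must be nonnegative and nondecreasing")


@dataclass(frozen=True)
class SurvivalCurve:
    """Per-subject survival step function ``S(t)`` on a grid of times."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.shape != s.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times and survival must be aligned nonempty 1-D arrays")
        if np.any(np.diff(t) < 0) or np.any(t < 0):
            raise ValueError("times must be nonnegative and nondecreasing")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12) or np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be nonincreasing and within [0, 1]")

    def to_csv(self, path) -> None:
        """Serialize as two-column delimited text (time, survival)."""
        arr = np.column_stack([self.times, self.survival])
        np.savetxt(path, arr, delimiter=",", header="time,survival", comments="")

    @classmethod
    def from_csv(cls, path) -> "SurvivalCurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 0], arr[:, 1])


@dataclass(frozen=True)
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    ``coefficients`` are log hazard ratios per design column;
    ``standard_errors`` come from the inverse observed information.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int = 0
    column_names: tuple[str, ...] | None = None

    def wald_p_values(self) -> np.ndarray:
        from scipy import stats

        z = self.coefficients / self.standard_errors
        return 2.0 * stats.norm.sf(np.abs(z))


class MedianSurvival(NamedTuple):
    time: float
    extrapolated: bool


def _validate_aligned(risks, records) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h = np.asarray(risks, dtype=float).reshape(-1)
    t, e = as_time_event(records)
    if h.shape[0] != t.shape[0]:
        raise ValueError(
            f"risks (n={h.shape[0]}) and records (n={t.shape[0]}) are misaligned"
        )
    if not np.all(np.isfinite(h)):
        raise ValueError("risk scores must be finite")
    return h, t, e


def neg_log_partial_likelihood(
    risks,
    records,
    l2_weight: float = 0.0,
    param_norm_sq: float = 0.0,
) -> float:
    """Negative log Cox partial likelihood, Breslow ties, event-normalized.

    Returns ``-(1/d) * sum_{i: E_i=1} [h_i - log sum_{j: T_j >= T_i} exp(h_j)]
    + l2_weight * param_norm_sq`` where ``d`` is the number of events.  Tied
    event times share the full tied risk set (Breslow convention).  This is
    the training loss of the neural survival models; dividing by the event
    count makes the regularization scale batch-size-invariant.
    """
    if l2_weight < 0:
        raise ValueError("l2_weight must be nonnegative")
    h, t, e = _validate_aligned(risks, records)
    d = int(e.sum())
    if d == 0:
        raise DegenerateBatchError("batch contains no events; partial likelihood undefined")

    order = np.argsort(-t, kind="stable")  # descending time
    hs, ts, es = h[order], t[order], e[order]
    m = hs.max()
    # cumulative log-sum-exp over descending times: position i covers {j: T_j >= T_i}
    # up to ties; extend each tie block to its last (smallest-index-in-time) member.
    cum = np.logaddexp.accumulate(hs - m) + m
    _, inverse, counts = np.unique(-ts, return_inverse=True, return_counts=True)
    block_end = np.cumsum(counts) - 1
    lse = cum[block_end[inverse]]
    ev = es == 1
    loss = -float(np.sum(hs[ev] - lse[ev])) / d
    return loss + float(l2_weight) * float(param_norm_sq)


def partial_likelihood_gradient(risks, records) -> np.ndarray:
    """Analytic gradient of :func:`neg_log_partial_likelihood` w.r.t. each risk.

    ``dL/dh_i = (exp(h_i) * H_0^{Breslow}(T_i) - E_i) / d`` where
    ``H_0^{Breslow}(T_i) = sum over event times t_k <= T_i of
    d(t_k) / sum_{j: T_j >= t_k} exp(h_j)`` (the Breslow cumulative hazard
    evaluated at the subject's own time).  No regularization term.
    """
    h, t, e = _validate_aligned(risks, records)
    d = int(e.sum())
    if d == 0:
        raise DegenerateBatchError("batch contains no events")
    base = breslow_baseline(h, (t, e), clip=None)
    # H0 evaluated at each subject's time (step function, 0 before first event)
    idx = np.searchsorted(base.event_times, t, side="right") - 1
    h0_at_t = np.where(idx >= 0, base.cumulative_hazard[np.maximum(idx, 0)], 0.0)
    return (np.exp(h) * h0_at_t - e) / d


def breslow_baseline(risks, records, clip: float | None = RISK_CLIP) -> BaselineHazard:
    """Breslow estimator of the cumulative baseline hazard.

    At each distinct event time ``t`` the hazard increment is
    ``d(t) / sum_{j: T_j >= t} exp(h_j)`` with ``d(t)`` the number of deaths
    at ``t``.  Risk scores are clipped to ``+-clip`` before exponentiation for
    numerical stability (disable with ``clip=None``).
    """
    h, t, e = _validate_aligned(risks, records)
    if e.sum() == 0:
        raise DegenerateBatchError("no events: baseline hazard undefined")
    if clip is not None:
        h = np.clip(h, -clip, clip)
    w = np.exp(h)

    order = np.argsort(t, kind="stable")
    ts, es, ws = t[order], e[order], w[order]
    # total exp-risk of subjects with T_j >= t, for t at each sorted position
    at_risk = np.cumsum(ws[::-1])[::-1]
    increments = []
    times_out = []
    for tv in np.unique(ts[es == 1]):
        i = np.searchsorted(ts, tv, side="left")
        d_t = int(np.sum(es[ts == tv]))
        increments.append(d_t / at_risk[i])
        times_out.append(tv)
    return BaselineHazard(
        np.asarray(times_out, dtype=float),
        np.cumsum(np.asarray(increments, dtype=float)),
    )


def survival_curve(baseline: BaselineHazard, risk: float) -> SurvivalCurve:
    """Per-subject survival curve ``S(t | x) = exp(-H_0(t) exp(h))``.

    Evaluated at the baseline's event times, with ``S(0) = 1`` prepended.
    """
    h = float(np.clip(risk, -RISK_CLIP, RISK_CLIP))
    times = np.concatenate([[0.0], baseline.event_times])
    surv = np.concatenate([[1.0], np.exp(-baseline.cumulative_hazard * math.exp(h))])
    return SurvivalCurve(times, surv)


def median_survival_time(
    curve: SurvivalCurve, horizon: float = 3650.0
) -> MedianSurvival:
    """Smallest ``t`` with ``S(t) <= 0.5``, linearly interpolated.

    If the curve never reaches 0.5 over its observed range, an exponential
    tail with rate ``-log S(t_last) / t_last`` is fitted to the last point
    and the crossing extrapolated (capped at ``horizon``, flag set).
    """
    t, s = curve.times, curve.survival
    if t.size == 0:
        raise ValueError("empty survival curve")
    below = np.nonzero(s <= 0.5)[0]
    if below.size:
        i = int(below[0])
        if i == 0 or s[i] == 0.5 or s[i - 1] == s[i]:
            return MedianSurvival(float(t[i]), False)
        frac = (s[i - 1] - 0.5) / (s[i - 1] - s[i])
        return MedianSurvival(float(t[i - 1] + frac * (t[i] - t[i - 1])), False)
    s_last, t_last = float(s[-1]), float(t[-1])
    if t_last <= 0 or s_last >= 1.0:
        return MedianSurvival(float(horizon), True)
    rate = -math.log(s_last) / t_last
    return MedianSurvival(min(math.log(2.0) / rate, float(horizon)), True)


# ---------------------------------------------------------------------------
# Cox proportional-hazards fitting (Newton-Raphson, Efron tie correction)
# ---------------------------------------------------------------------------


def _efron_quantities(beta, X, t, e):
    """Log-likelihood, score and observed information under Efron ties.

    Iterates over distinct times in descending order, maintaining running
    sums S = sum exp(eta), Z = sum exp(eta) x, Q = sum exp(eta) x x^T over
    the risk set.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # shift-invariant; stabilizes exp
    w = np.exp(eta)

    order = np.argsort(-t, kind="stable")
    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    S = 0.0
    Z = np.zeros(p)
    Q = np.zeros((p, p))
    i = 0
    idx = order
    while i < n:
        j = i
        tv = t[idx[i]]
        while j < n and t[idx[j]] == tv:
            j += 1
        block = idx[i:j]
        wb = w[block]
        Xb = X[block]
        S += wb.sum()
        Z += wb @ Xb
        Q += (Xb * wb[:, None]).T @ Xb
        ev = block[e[block] == 1]
        dcount = ev.size
        if dcount:
            wd = w[ev]
            Xd = X[ev]
            Sd = wd.sum()
            Zd = wd @ Xd
            Qd = (Xd * wd[:, None]).T @ Xd
            loglik += float((eta[ev]).sum())
            for l in range(dcount):
                f = l / dcount
                denom = S - f * Sd
                zl = (Z - f * Zd) / denom
                ql = (Q - f * Qd) / denom
                loglik -= math.log(denom)
                score += -zl
                info += ql - np.outer(zl, zl)
            score += Xd.sum(axis=0)
        i = j
    return loglik, score, info


def fit_cph(
    design,
    records,
    tol: float = 1e-9,
    max_iter: int = 100,
    column_names: Sequence[str] | None = None,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson (Efron ties).

    ``design`` is the (already encoded) covariate matrix, rows aligned with
    ``records``.  Standard errors come from the inverse observed information;
    ``converged`` is set when ``max |score| < tol * max(1, |loglik|)`` — the
    score is measured relative to the log-likelihood magnitude because the
    achievable score precision scales with it in floating point.  A singular
    information matrix raises with the name/index of the offending column;
    reaching ``max_iter`` without convergence returns the fit with
    ``converged=False``.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    t, e = as_time_event(records)
    if X.shape[0] != t.shape[0]:
        raise ValueError("design rows and records are misaligned")
    if e.sum() == 0:
        raise DegenerateBatchError("no events: partial likelihood undefined")
    zero_cols = np.nonzero(np.all(X == 0, axis=0))[0]
    if zero_cols.size:
        name = column_names[zero_cols[0]] if column_names else f"column {zero_cols[0]}"
        raise ValueError(f"design has a constant-zero column: {name}")

    p = X.shape[1]
    beta = np.zeros(p)
    loglik, score, info = _efron_quantities(beta, X, t, e)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            bad = int(np.argmax(np.abs(np.linalg.svd(info)[2][-1])))
            name = column_names[bad] if column_names else f"column {bad}"
            raise np.linalg.LinAlgError(
                f"singular information matrix; check {name} for collinearity "
                "or separation"
            ) from None
        # step-halving line search on the partial log-likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            new_loglik, new_score, new_info = _efron_quantities(cand, X, t, e)
            if new_loglik >= loglik - 1e-12:
                break
            factor /= 2.0
        stalled = abs(new_loglik - loglik) <= 1e-12 * max(1.0, abs(new_loglik))
        beta, loglik, score, info = cand, new_loglik, new_score, new_info
        if np.max(np.abs(score)) < tol * max(1.0, abs(loglik)):
            converged = True
            break
        if stalled:  # at the floating-point floor of the likelihood
            converged = np.max(np.abs(score)) < 1e-4 * max(1.0, abs(loglik))
            break
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        bad = int(np.argmax(np.abs(np.linalg.svd(info)[2][-1])))
        name = column_names[bad] if column_names else f"column {bad}"
        raise np.linalg.LinAlgError(
            f"singular information matrix at optimum; check {name}"
        ) from None
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return CoxFit(
        coefficients=beta,
        standard_errors=se,
        log_likelihood=float(loglik),
        converged=converged,
        n_iter=it,
        column_names=tuple(column_names) if column_names is not None else None,
    )
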