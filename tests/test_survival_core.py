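"""Partial likelihood, Breslow baseline, survival curves, Cox fitting."""

import math

import numpy as np
import pytest

from survfusion import (
    DegenerateBatchError,
    SurvivalCurve,
    SurvivalRecord,
    breslow_baseline,
    fit_cph,
    make_records,
    median_survival_time,
    neg_log_partial_likelihood,
    partial_likelihood_gradient,
    survival_curve,
)

from conftest import random_survival_instance


def brute_force_nlpl(h, times, events):
    """Risk-set enumeration oracle for the Breslow partial likelihood."""
    d = events.sum()
    total = 0.0
    for i in range(len(times)):
        if events[i]:
            denom = sum(math.exp(h[j]) for j in range(len(times)) if times[j] >= times[i])
            total -= h[i] - math.log(denom)
    return total / d


class TestPartialLikelihood:
    def test_two_equal_hazard_subjects_give_log2(self):
        recs = make_records([1.0, 2.0], [1, 0])
        assert neg_log_partial_likelihood([0.0, 0.0], recs) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_singleton_risk_set_is_zero(self):
        recs = make_records([5.0], [1])
        assert neg_log_partial_likelihood([2.7], recs) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_risk_set_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t, e = random_survival_instance(rng, 6)
        h = rng.normal(0, 1.5, 6)
        assert neg_log_partial_likelihood(h, make_records(t, e)) == pytest.approx(
            brute_force_nlpl(h, t, e), abs=1e-10
        )

    def test_l2_term_added(self):
        recs = make_records([1.0, 2.0], [1, 0])
        base = neg_log_partial_likelihood([0.0, 0.0], recs)
        assert neg_log_partial_likelihood(
            [0.0, 0.0], recs, l2_weight=0.01, param_norm_sq=4.0
        ) == pytest.approx(base + 0.04)

    def test_shift_invariance(self, rng):
        for _ in range(10):
            t, e = random_survival_instance(rng, 12)
            h = rng.normal(0, 1, 12)
            recs = make_records(t, e)
            a = neg_log_partial_likelihood(h, recs)
            b = neg_log_partial_likelihood(h + 3.7, recs)
            assert a == pytest.approx(b, abs=1e-10)

    def test_no_events_raises_degenerate_batch(self):
        recs = make_records([1.0, 2.0], [0, 0])
        with pytest.raises(DegenerateBatchError):
            neg_log_partial_likelihood([0.0, 0.0], recs)

    def test_misaligned_lengths_raise(self):
        with pytest.raises(ValueError):
            neg_log_partial_likelihood([0.0], make_records([1.0, 2.0], [1, 0]))

    def test_analytic_gradient_matches_finite_differences(self, rng):
        for _ in range(5):
            n = int(rng.integers(4, 20))
            t, e = random_survival_instance(rng, n)
            h = rng.normal(0, 1, n)
            recs = make_records(t, e)
            g = partial_likelihood_gradient(h, recs)
            eps = 1e-6
            for i in range(n):
                hp, hm = h.copy(), h.copy()
                hp[i] += eps
                hm[i] -= eps
                fd = (
                    neg_log_partial_likelihood(hp, recs)
                    - neg_log_partial_likelihood(hm, recs)
                ) / (2 * eps)
                assert g[i] == pytest.approx(fd, abs=1e-5)


class TestBreslowBaseline:
    def test_uniform_hazards_first_increment(self):
        n = 7
        recs = make_records(np.arange(1, n + 1.0), [1] + [0] * (n - 1))
        base = breslow_baseline(np.zeros(n), recs)
        assert base.cumulative_hazard[0] == pytest.approx(1.0 / n)

    def test_single_event_curve_value(self):
        recs = make_records([3.0, 1.0, 2.0], [1, 0, 0])
        base = breslow_baseline(np.zeros(3), recs)
        curve = survival_curve(base, 0.0)
        # only the single event subject remains at risk at t=3
        assert curve.survival[-1] == pytest.approx(math.exp(-1.0))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_hand_enumerated_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t, e = random_survival_instance(rng, 8)
        h = rng.normal(0, 1, 8)
        base = breslow_baseline(h, make_records(t, e))
        cum = 0.0
        for k, tv in enumerate(base.event_times):
            d = sum(1 for j in range(8) if t[j] == tv and e[j])
            s = sum(math.exp(h[j]) for j in range(8) if t[j] >= tv)
            cum += d / s
            assert base.cumulative_hazard[k] == pytest.approx(cum, abs=1e-10)

    def test_equals_nelson_aalen_at_zero_risk(self, rng):
        # h = 0, no ties: Breslow reduces to Nelson-Aalen
        t = rng.uniform(1, 50, 15)
        e = rng.integers(0, 2, 15)
        e[0] = 1
        base = breslow_baseline(np.zeros(15), make_records(t, e))
        order = np.argsort(t)
        cum = 0.0
        na = {}
        for i in order:
            if e[i]:
                at_risk = np.sum(t >= t[i])
                cum += 1.0 / at_risk
                na[t[i]] = cum
        for tv, hz in zip(base.event_times, base.cumulative_hazard):
            assert hz == pytest.approx(na[tv], abs=1e-12)

    def test_no_events_raises(self):
        with pytest.raises(DegenerateBatchError):
            breslow_baseline([0.0], make_records([1.0], [0]))


class TestSurvivalCurve:
    def test_unit_relative_hazard(self, rng):
        t, e = random_survival_instance(rng, 10)
        base = breslow_baseline(rng.normal(0, 1, 10), make_records(t, e))
        curve = survival_curve(base, 0.0)
        np.testing.assert_allclose(
            curve.survival[1:], np.exp(-base.cumulative_hazard), rtol=1e-12
        )

    def test_protective_limit(self, rng):
        t, e = random_survival_instance(rng, 10)
        base = breslow_baseline(np.zeros(10), make_records(t, e))
        curve = survival_curve(base, -40.0)
        assert np.all(curve.survival > 1 - 1e-6)

    def test_matches_exponentiation_oracle(self, rng):
        t, e = random_survival_instance(rng, 12)
        base = breslow_baseline(rng.normal(0, 1, 12), make_records(t, e))
        curve = survival_curve(base, 0.7)
        expected = np.exp(-base.cumulative_hazard * math.exp(0.7))
        np.testing.assert_allclose(curve.survival[1:], expected, rtol=1e-12)
        assert curve.times[0] == 0 and curve.survival[0] == 1.0

    def test_round_trips_through_csv(self, tmp_path, rng):
        t, e = random_survival_instance(rng, 6)
        curve = survival_curve(breslow_baseline(np.zeros(6), make_records(t, e)), 0.3)
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = SurvivalCurve.from_csv(path)
        np.testing.assert_allclose(back.times, curve.times)
        np.testing.assert_allclose(back.survival, curve.survival)


class TestMedianSurvivalTime:
    def test_exponential_curve_median(self):
        lam = math.log(2) / 100.0
        t = np.linspace(0, 500, 2001)
        m = median_survival_time(SurvivalCurve(t, np.exp(-lam * t)))
        assert m.time == pytest.approx(100.0, abs=0.5)
        assert not m.extrapolated

    def test_step_curve_first_crossing(self):
        m = median_survival_time(SurvivalCurve([0.0, 50.0], [1.0, 0.4]))
        assert m.time <= 50.0 and not m.extrapolated

    def test_exponential_tail_extrapolation(self):
        # curve never reaches 0.5: tail rate -ln(0.8)/400
        m = median_survival_time(
            SurvivalCurve([0.0, 200.0, 400.0], [1.0, 0.9, 0.8]), horizon=20000.0
        )
        expected = math.log(2) * 400.0 / (-math.log(0.8))
        assert m.extrapolated
        assert m.time == pytest.approx(expected, rel=1e-9)

    def test_extrapolation_capped_at_horizon(self):
        m = median_survival_time(
            SurvivalCurve([0.0, 400.0], [1.0, 0.99]), horizon=3650.0
        )
        assert m.time == 3650.0 and m.extrapolated

    def test_antitone_in_risk(self, rng):
        t, e = random_survival_instance(rng, 30)
        base = breslow_baseline(rng.normal(0, 1, 30), make_records(t, e))
        risks = np.sort(rng.normal(0, 2, 10))
        preds = [
            median_survival_time(survival_curve(base, h), horizon=1e6).time
            for h in risks
        ]
        assert all(a >= b - 1e-9 for a, b in zip(preds, preds[1:]))


class TestCoxFit:
    @staticmethod
    def _simulate_ph(rng, n, beta, censor_scale=None):
        p = len(beta)
        X = rng.normal(0, 1, (n, p))
        t = -np.log(rng.random(n)) / (0.01 * np.exp(X @ beta))
        if censor_scale is None:
            e = np.ones(n, dtype=int)
        else:
            c = rng.exponential(censor_scale * t.mean(), n)
            e = (t <= c).astype(int)
            t = np.minimum(t, c)
        return X, t, e

    def test_one_dimensional_brute_force_maximum(self, rng):
        X, t, e = self._simulate_ph(rng, 60, np.array([0.7]))
        recs = make_records(t, e)
        fit = fit_cph(X, recs)

        def nll(b):
            # Efron-corrected negative partial log-likelihood, direct form
            total = 0.0
            eta = X[:, 0] * b
            for tv in np.unique(t[e == 1]):
                dead = np.nonzero((t == tv) & (e == 1))[0]
                risk = np.nonzero(t >= tv)[0]
                s_all = np.exp(eta[risk]).sum()
                s_d = np.exp(eta[dead]).sum()
                total -= eta[dead].sum()
                for l in range(len(dead)):
                    total += math.log(s_all - l / len(dead) * s_d)
            return total

        from scipy.optimize import minimize_scalar

        res = minimize_scalar(nll, bounds=(-3, 3), method="bounded",
                              options={"xatol": 1e-10})
        assert fit.coefficients[0] == pytest.approx(res.x, abs=1e-4)

    def test_recovers_planted_coefficients(self, rng):
        beta = np.array([0.5, -0.3, 0.8])
        X, t, e = self._simulate_ph(rng, 2000, beta, censor_scale=2.2)
        assert 0.2 < 1 - e.mean() < 0.4  # roughly 30% censoring
        fit = fit_cph(X, make_records(t, e))
        assert fit.converged
        np.testing.assert_allclose(fit.coefficients, beta, atol=0.1)

    def test_agrees_with_lifelines(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        X, t, e = self._simulate_ph(rng, 400, np.array([0.4, -0.6]), censor_scale=2.0)
        fit = fit_cph(X, make_records(t, e))
        df = pd.DataFrame(X, columns=["x0", "x1"])
        df["T"], df["E"] = t, e
        ll = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coefficients, ll.params_.values, atol=1e-4)
        np.testing.assert_allclose(
            fit.standard_errors, ll.standard_errors_.values, atol=1e-4
        )

    def test_consistency_bias_shrinks_with_n(self):
        beta = np.array([0.6])
        biases = []
        for n in (200, 1000, 5000):
            errs = []
            for seed in range(5):
                rng = np.random.default_rng(1000 + seed)
                X, t, e = self._simulate_ph(rng, n, beta, censor_scale=2.5)
                fit = fit_cph(X, make_records(t, e))
                errs.append(abs(fit.coefficients[0] - beta[0]))
            biases.append(np.median(errs))
        assert biases[0] > biases[1] > biases[2]

    def test_non_convergence_reported_not_raised(self, rng):
        X, t, e = self._simulate_ph(rng, 100, np.array([0.5]))
        fit = fit_cph(X, make_records(t, e), tol=1e-14, max_iter=1)
        assert not fit.converged

    def test_zero_column_rejected_by_name(self, rng):
        X = np.zeros((20, 2))
        X[:, 0] = rng.normal(0, 1, 20)
        t, e = random_survival_instance(rng, 20)
        with pytest.raises(ValueError, match="dead_col"):
            fit_cph(X, make_records(t, e), column_names=["x", "dead_col"])


class TestSurvivalRecord:
    def test_rejects_nonpositive_time(self):
        with pytest.raises(ValueError):
            SurvivalRecord("a", 0.0, 1)

    def test_rejects_bad_event(self):
        with pytest.raises(ValueError):
            SurvivalRecord("a", 1.0, 2)
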