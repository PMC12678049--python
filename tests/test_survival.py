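"""Survival engine: partial-likelihood oracles, library cross-checks,
penalized-path limits, Gompertz likelihood oracles, concordance."""

import numpy as np
import pandas as pd
import pytest

from metaboaging.survival import (ConvergenceError, SurvivalError, cox_loglik,
                                  fit_cox, fit_gompertz_ph,
                                  fit_penalized_cox, gompertz_loglik,
                                  harrell_c, one_se_lambda,
                                  stratified_event_folds)


def brute_force_cox_beta(time, event, x, lo=-5.0, hi=5.0, step=1e-3):
    """Grid-search maximiser of the exact (Breslow/Efron-free, untied)
    partial likelihood for a single covariate."""
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    x = np.asarray(x, float)
    order = np.argsort(time)
    t, d, xs = time[order], event[order], x[order]
    grid = np.arange(lo, hi + step / 2, step)
    ll = np.zeros(grid.size)
    exb = np.exp(np.outer(grid, xs))           # (G, n)
    suffix = np.cumsum(exb[:, ::-1], axis=1)[:, ::-1]
    for i in np.flatnonzero(d):
        ll += grid * xs[i] - np.log(suffix[:, i])
    return grid[np.argmax(ll)]


class TestFitCox:
    def test_matches_grid_oracle_small_n(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            t = rng.exponential(1.0, n) + rng.uniform(0, 0.01, n)
            x = rng.normal(size=n)
            e = np.ones(n)
            try:
                fit = fit_cox(t, e, x.reshape(-1, 1))
            except ConvergenceError:
                continue
            if abs(fit.coef[0]) > 4.5:
                continue
            oracle = brute_force_cox_beta(t, e, x)
            assert abs(fit.coef[0] - oracle) < 2e-3

    def test_worked_four_point_dataset(self):
        t = np.array([1.0, 2, 3, 4])
        e = np.ones(4)
        x = np.array([1.0, 0, 1, 0]).reshape(-1, 1)
        fit = fit_cox(t, e, x)
        oracle = brute_force_cox_beta(t, e, x.ravel(), step=1e-4)
        assert abs(fit.coef[0] - oracle) < 1e-3

    def test_sign_symmetry(self, rng):
        n = 60
        t = rng.exponential(1, n)
        e = (rng.uniform(size=n) < 0.8).astype(float)
        x = rng.normal(size=(n, 1))
        a = fit_cox(t, e, x)
        b = fit_cox(t, e, -x)
        assert a.coef[0] == pytest.approx(-b.coef[0], abs=1e-9)

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter

        n = 150
        X = rng.normal(size=(n, 3))
        t = np.ceil(rng.exponential(np.exp(-0.5 * X[:, 0]), n) * 4) / 4
        e = (rng.uniform(size=n) < 0.7).astype(float)
        fit = fit_cox(t, e, X)
        df = pd.DataFrame(np.c_[t, e, X], columns=["t", "e", "a", "b", "c"])
        ll = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coef, ll.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.se, ll.standard_errors_.values,
                                   atol=1e-6)

    def test_constant_covariate_rank_error(self):
        with pytest.raises(SurvivalError, match="constant"):
            fit_cox([1, 2, 3], [1, 1, 0], np.ones((3, 1)))

    def test_zero_events_error(self):
        with pytest.raises(SurvivalError, match="events"):
            fit_cox([1, 2, 3], [0, 0, 0], np.arange(3.0).reshape(-1, 1))

    def test_perfect_separation_diverges(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.array([1.0, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1, 1, 0, 0, 0]).reshape(-1, 1)
        with pytest.raises(ConvergenceError):
            fit_cox(t, e, x)

    def test_hr_and_ci_consistency(self, rng):
        n = 100
        t = rng.exponential(1, n)
        e = np.ones(n)
        x = rng.normal(size=(n, 2))
        fit = fit_cox(t, e, x)
        np.testing.assert_allclose(fit.hr, np.exp(fit.coef))
        np.testing.assert_allclose(
            fit.ci_low, np.exp(fit.coef - 1.959963984540054 * fit.se))


class TestPenalizedCox:
    @pytest.fixture(scope="class")
    def data(self):
        rng = np.random.default_rng(12)
        n = 400
        Xp = rng.normal(size=(n, 6))
        Xu = rng.normal(size=(n, 2))
        lp = 0.6 * Xp[:, 0] - 0.5 * Xp[:, 1] + 0.3 * Xu[:, 0]
        T = rng.exponential(np.exp(-lp))
        C = rng.exponential(2.0, n)
        return np.minimum(T, C), (T <= C).astype(float), Xp, Xu

    def test_large_lambda_limit(self, data):
        t, e, Xp, Xu = data
        fit = fit_penalized_cox(t, e, Xp, Xu, folds=4, seed=0)
        big = fit.coef_path[:, 0]
        assert np.all(big[:6] == 0.0)
        ref = fit_cox(t, e, Xu, ties="breslow")
        np.testing.assert_allclose(big[6:], ref.coef, atol=1e-6)

    def test_tiny_lambda_matches_unpenalized(self, data):
        t, e, Xp, Xu = data
        amax = fit_penalized_cox(t, e, Xp, Xu, folds=4,
                                 seed=0).lambda_path[0]
        alphas = np.r_[np.geomspace(amax, amax * 1e-3, 20), 0.0]
        fit = fit_penalized_cox(t, e, Xp, Xu, folds=4, seed=0, alphas=alphas)
        full = fit_cox(t, e, np.c_[Xp, Xu], ties="breslow")
        np.testing.assert_allclose(fit.coef_path[:, -1], full.coef, atol=1e-4)

    def test_selected_subset_of_penalized_block(self, data):
        t, e, Xp, Xu = data
        fit = fit_penalized_cox(t, e, Xp, Xu, folds=4, seed=1)
        assert set(fit.selected_features) <= set(range(6))
        assert fit.lambda_1se >= fit.lambda_min

    def test_folds_stratified_by_event(self, data):
        t, e, *_ = data
        fold = stratified_event_folds(e, 5, seed=0)
        for k in range(5):
            assert e[fold == k].sum() > 0
        counts = np.bincount(fold)
        assert counts.max() - counts.min() <= 2

    def test_one_se_rule_worked_example(self):
        lam = one_se_lambda([0.3, 0.2, 0.1], [12.0, 10.5, 10.0],
                            [0.4, 0.5, 0.6])
        assert lam == pytest.approx(0.2)

    def test_invalid_arguments(self, data):
        t, e, Xp, Xu = data
        with pytest.raises(ValueError):
            fit_penalized_cox(t, e, Xp, Xu, folds=1)
        with pytest.raises(ValueError):
            fit_penalized_cox(t, e, Xp, Xu, rule="nope")


def brute_force_gompertz_grid(entry, exit_, d):
    """Two-stage 2-D grid maximiser of the left-truncated Gompertz
    likelihood (coarse sweep, then refinement around the argmax)."""
    def sweep(logb_grid, g_grid):
        best, arg = -np.inf, None
        for lb in logb_grid:
            for g in g_grid:
                ll = gompertz_loglik(lb, g, entry, exit_, d)
                if ll > best:
                    best, arg = ll, (lb, g)
        return arg
    lb, g = sweep(np.arange(-20.0, -1.0, 0.1),
                  np.arange(0.005, 0.40, 0.005))
    lb, g = sweep(np.arange(lb - 0.5, lb + 0.5, 0.005),
                  np.arange(max(1e-4, g - 0.02), g + 0.02, 2e-4))
    return sweep(np.arange(lb - 0.02, lb + 0.02, 2e-4),
                 np.arange(max(1e-5, g - 0.001), g + 0.001, 1e-5))


class TestGompertz:
    def test_matches_2d_grid_oracle(self):
        rng = np.random.default_rng(4)
        entry = rng.uniform(50, 60, 6)
        exit_ = entry + rng.uniform(1, 12, 6)
        d = np.array([1.0, 1, 0, 1, 1, 1])
        fit = fit_gompertz_ph(entry, exit_, d)
        lb, g = brute_force_gompertz_grid(entry, exit_, d)
        assert abs(fit.gamma - g) < 1e-2
        assert abs(fit.log_b - lb) < 1e-2

    def test_gamma_zero_limit_equals_exponential_likelihood(self, rng):
        entry = rng.uniform(40, 60, 50)
        exit_ = entry + rng.uniform(0.5, 13.5, 50)
        d = (rng.uniform(size=50) < 0.5).astype(float)
        log_b = -4.0
        ll_g = gompertz_loglik(log_b, 1e-10, entry, exit_, d)
        ll_exp = np.sum(d * log_b - np.exp(log_b) * (exit_ - entry))
        assert ll_g == pytest.approx(ll_exp, rel=1e-6)

    def test_entry_after_exit_rejected(self):
        with pytest.raises(SurvivalError):
            fit_gompertz_ph([55.0], [54.0], [1.0])

    def test_loglik_value_matches_formula(self, rng):
        # spot-check the left-truncated likelihood against a direct sum
        entry = rng.uniform(40, 60, 20)
        exit_ = entry + rng.uniform(1, 10, 20)
        d = (rng.uniform(size=20) < 0.6).astype(float)
        X = rng.normal(size=(20, 2))
        beta = np.array([0.2, -0.1])
        lb, g = -10.0, 0.08
        eta = lb + X @ beta
        manual = np.sum(d * (eta + g * exit_)
                        - np.exp(eta) / g * (np.exp(g * exit_)
                                             - np.exp(g * entry)))
        assert gompertz_loglik(lb, g, entry, exit_, d, X, beta) == \
            pytest.approx(manual, rel=1e-12)


class TestHarrellC:
    def test_worked_pair_enumeration(self):
        assert harrell_c([3, 1, 2], [1, 2, 3], [1, 1, 1]) == pytest.approx(2 / 3)

    def test_perfect_concordance(self):
        assert harrell_c([5, 4, 3, 2], [1, 2, 3, 4], [1, 1, 1, 1]) == 1.0

    def test_all_tied_risks_half(self):
        assert harrell_c([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 1, 1]) == 0.5

    def test_complement_property_no_ties(self, rng):
        n = 200
        t = rng.exponential(1, n)
        e = (rng.uniform(size=n) < 0.6).astype(float)
        r = rng.normal(size=n)
        assert harrell_c(r, t, e) + harrell_c(-r, t, e) == pytest.approx(1.0)

    def test_matches_lifelines(self, rng):
        from lifelines.utils import concordance_index

        n = 300
        t = rng.exponential(1, n)
        e = (rng.uniform(size=n) < 0.7).astype(float)
        r = rng.normal(size=n)
        # lifelines scores higher-predicted = longer survival
        assert harrell_c(r, t, e) == pytest.approx(
            concordance_index(t, -r, e), abs=1e-12)

    def test_no_usable_pairs_errors(self):
        with pytest.raises(SurvivalError):
            harrell_c([1, 2], [1, 2], [0, 0])

    def test_nonfinite_risk_rejected(self):
        with pytest.raises(SurvivalError):
            harrell_c([np.inf, 1], [1, 2], [1, 1])


def test_cox_loglik_standalone_matches_fit(rng):
    n = 80
    t = rng.exponential(1, n)
    e = (rng.uniform(size=n) < 0.7).astype(float)
    X = rng.normal(size=(n, 2))
    fit = fit_cox(t, e, X, ties="breslow")
    assert cox_loglik(fit.coef, t, e, X, ties="breslow") == \
        pytest.approx(fit.loglik, rel=1e-9)
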