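"""Cox engine, KM, log-rank and Mann–Whitney against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from survsig.survival import (
    BETA_CAP,
    DegenerateCovariateError,
    InsufficientEventsError,
    fit_cox,
    km_estimate,
    logrank,
    mann_whitney,
    nagelkerke_r2,
    ph_test,
)


def partial_loglik_grid(times, events, x, grid):
    """Brute-force partial log-likelihood over a beta grid (no ties)."""
    times = np.asarray(times, float)
    x = np.asarray(x, float)
    ll = np.zeros_like(grid)
    for i in np.flatnonzero(np.asarray(events) == 1):
        risk = times >= times[i]
        eta = np.outer(grid, x[risk])
        ll += grid * x[i] - np.log(np.exp(eta).sum(axis=1))
    return ll


def random_tiny_dataset(rng):
    n = int(rng.integers(4, 9))
    times = rng.permutation(np.arange(1.0, n + 1))  # distinct -> no ties
    events = (rng.random(n) < 0.8).astype(int)
    if events.sum() < 2:
        events[:2] = 1
    x = rng.normal(size=n)
    return times, events, x


class TestFitCox:
    def test_toy_dataset_matches_grid_search(self):
        times = np.arange(1.0, 7.0)
        events = np.ones(6, int)
        x = np.array([0.0, 0, 1, 0, 1, 1])
        grid = np.arange(-10, 10, 1e-4)
        ll = partial_loglik_grid(times, events, x, grid)
        beta_bf = grid[np.argmax(ll)]
        res = fit_cox(times, events, x)
        assert abs(res.beta[0] - beta_bf) < 1e-4

    def test_hr_scale_identity(self):
        rng = np.random.default_rng(3)
        t, e, x = random_tiny_dataset(rng)
        res = fit_cox(t, e, x)
        assert np.isclose(res.hr_per_01[0], res.hr_per_unit[0] ** 0.1)

    def test_reparameterization_invariance(self):
        rng = np.random.default_rng(7)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        e = (rng.random(n) < 0.7).astype(int)
        b1 = fit_cox(t, e, x).beta[0]
        b2 = fit_cox(t, e, 4.0 * x).beta[0]
        assert np.isclose(b1, 4.0 * b2, rtol=1e-6)

    def test_monotone_likelihood_flagged_degenerate(self):
        res = fit_cox([1.0, 2.0], [1, 1], [1.0, 0.0])
        assert res.degenerate
        assert abs(res.beta[0]) == pytest.approx(BETA_CAP)

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(DegenerateCovariateError):
            fit_cox([1.0, 2, 3], [1, 1, 1], [2.0, 2.0, 2.0])

    def test_insufficient_events_rejected(self):
        with pytest.raises(InsufficientEventsError):
            fit_cox([1.0, 2, 3], [1, 0, 0], [1.0, 2.0, 3.0])

    def test_agrees_with_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(11)
        for _ in range(10):
            n = 80
            X = rng.normal(size=(n, 2))
            t = np.ceil(rng.exponential(np.exp(-0.6 * X[:, 0])) * 3) / 3
            e = (rng.random(n) < 0.7).astype(int)
            res = fit_cox(t, e, X)
            df = pd.DataFrame(X, columns=["a", "b"])
            df["t"], df["e"] = t, e
            cph = CoxPHFitter().fit(df, "t", "e")
            # tolerance reflects lifelines' looser default stopping rule
            assert np.allclose(res.beta, cph.params_.to_numpy(), atol=2e-4)
            assert np.allclose(res.se, cph.standard_errors_.to_numpy(), atol=2e-4)

    def test_binary_covariate_beta_unbiased(self):
        # exponential survival with true log-HR b on a binary covariate
        rng = np.random.default_rng(19)
        b = 0.7
        betas = []
        for _ in range(200):
            x = (rng.random(500) < 0.5).astype(float)
            t = rng.exponential(np.exp(-b * x))
            c = rng.exponential(1.5, 500)
            e = (t <= c).astype(int)
            betas.append(fit_cox(np.minimum(t, c), e, x).beta[0])
        assert abs(np.mean(betas) - b) < 0.05

    def test_nagelkerke_r2_bounds(self):
        rng = np.random.default_rng(23)
        n = 100
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-x))
        res = fit_cox(t, np.ones(n, int), x, compute_r2=True)
        assert 0 < res.r2_nagelkerke < 1
        # null covariate: R2 near zero
        res0 = fit_cox(t, np.ones(n, int), rng.normal(size=n), compute_r2=True)
        assert res0.r2_nagelkerke < 0.05
        assert nagelkerke_r2(-10.0, -10.0, 50) == 0.0


class TestPhTest:
    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=80)
        t = rng.exponential(np.exp(-0.5 * x))
        p = ph_test(t, np.ones(80, int), x)
        assert 0 <= p[0] <= 1

    def test_calibration_under_proportional_hazards(self):
        rng = np.random.default_rng(29)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 120
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.5 * x))
            e = (rng.random(n) < 0.8).astype(int)
            rejections += ph_test(t, e, x)[0] < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_detects_time_varying_effect(self):
        rng = np.random.default_rng(31)
        detected = 0
        n_rep = 40
        for _ in range(n_rep):
            n = 200
            x = (rng.random(n) < 0.5).astype(float)
            # effect reverses over time: early harm, late protection
            t_early = rng.exponential(np.exp(-1.5 * x))
            t_late = 0.7 + rng.exponential(np.exp(1.5 * x))
            t = np.where(t_early < 0.7, t_early, t_late)
            detected += ph_test(t, np.ones(n, int), x)[0] < 0.05
        assert detected / n_rep >= 0.8

    def test_too_few_events_not_testable(self):
        p = ph_test([1.0, 2, 3, 4], [1, 1, 0, 0], [0.0, 1, 0, 1])
        assert np.isnan(p[0])


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        km = km_estimate([1.0, 2, 3], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_censoring_at_event_time_keeps_at_risk(self):
        km = km_estimate([1.0, 2.0], [0, 1])
        assert km.survival_at(2.0) == 0.0

    def test_all_censored_flat_curve(self):
        km = km_estimate([1.0, 2, 3], [0, 0, 0])
        assert np.all(km.survival == 1.0)
        assert np.isnan(km.median)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(1.0, 50)
        km = km_estimate(t, np.ones(50, int))
        for tau in np.quantile(t, [0.2, 0.5, 0.9]):
            assert np.isclose(km.survival_at(tau), (t > tau).mean(), atol=1e-12)


def logrank_two_group_oracle(times, events, groups):
    """Hand-enumerated O-E/V two-group log-rank statistic."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    o_minus_e = 0.0
    v = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == groups[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == groups[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1.0, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = ["a", "a", "a", "b", "b", "b"]
        res = logrank(t, e, g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)
        assert res.df == 1

    def test_matches_hand_enumeration(self):
        t = [1.0, 2, 3, 4]
        e = [1, 1, 1, 1]
        g = ["A", "A", "B", "B"]
        res = logrank(t, e, g)
        assert res.chi2 == pytest.approx(logrank_two_group_oracle(t, e, g), abs=1e-6)

    def test_random_two_group_matches_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = 30
            t = np.round(rng.exponential(1.0, n), 2) + 0.01
            e = (rng.random(n) < 0.8).astype(int)
            g = np.where(rng.random(n) < 0.5, "A", "B")
            if e[g == "A"].sum() == 0 or e[g == "B"].sum() == 0:
                continue
            res = logrank(t, e, g)
            assert res.chi2 == pytest.approx(
                logrank_two_group_oracle(t, e, g), abs=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([1.0, 2], [1, 1], ["a", "a"])

    def test_three_groups_df(self):
        t = [1.0, 2, 3, 4, 5, 6]
        res = logrank(t, [1] * 6, ["a", "a", "b", "b", "c", "c"])
        assert res.df == 2


class TestMannWhitney:
    def test_exact_enumeration_separated(self):
        # all 20 assignments of {1..6} into two triples: U=0 is one-sided
        # probability 1/20, two-sided p = 0.1
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        _, p = mann_whitney([1, 2, 2, 3] * 4, [1, 2, 2, 3] * 4)
        assert p == pytest.approx(1.0)

    def test_tie_handled_by_midrank(self):
        u, p = mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert 0 < p <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
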