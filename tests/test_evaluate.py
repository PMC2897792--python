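"""Logistic fits, G², c-statistic, bootstrap: closed forms and oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats
from scipy.special import expit

from comorbidikit.errors import (ContractError, DegenerateOutcomeError,
                                 UndefinedStatisticError)
from comorbidikit.evaluate import (bootstrap_c_ci, c_statistic,
                                   drop_degenerate_columns, fit_logistic,
                                   g2_statistic, paired_bootstrap_compare)


def brute_force_c(scores, outcomes):
    """Exhaustive pairwise concordance, ties counted one-half."""
    s = np.asarray(scores, float)
    y = np.asarray(outcomes, int)
    num = n_pairs = 0.0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            n_pairs += 1
            if s[i] > s[j]:
                num += 1
            elif s[i] == s[j]:
                num += 0.5
    return num / n_pairs


def neg_loglik(beta, X, y):
    eta = X @ beta
    return -np.sum(y * eta - np.log1p(np.exp(eta)))


def oracle_loglik(X, y):
    """Independent direct maximization (Nelder–Mead polish on BFGS start)."""
    Xc = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    res = optimize.minimize(neg_loglik, np.zeros(Xc.shape[1]),
                            args=(Xc, np.asarray(y, float)), method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 2000})
    return -res.fun


class TestDropDegenerate:
    def test_all_one_and_all_zero_dropped(self):
        df = pd.DataFrame({"mi": [1, 1, 1], "aids": [0, 0, 0],
                           "chf": [0, 1, 0]})
        reduced, dropped = drop_degenerate_columns(df)
        assert sorted(dropped) == ["aids", "mi"]
        assert list(reduced.columns) == ["chf"]

    def test_single_positive_retained(self):
        df = pd.DataFrame({"rare": [1] + [0] * 99})
        reduced, dropped = drop_degenerate_columns(df)
        assert dropped == [] and list(reduced.columns) == ["rare"]

    def test_empty_identity(self):
        df = pd.DataFrame(index=range(5))
        reduced, dropped = drop_degenerate_columns(df)
        assert dropped == [] and reduced.shape == (5, 0)


class TestFitLogistic:
    def test_two_by_two_slope_equals_log_odds_ratio(self):
        # exposed: 10 events / 40 non-events; unexposed: 5 / 45
        x = np.r_[np.ones(50), np.zeros(50)]
        y = np.r_[np.ones(10), np.zeros(40), np.ones(5), np.zeros(45)]
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.params["x"] == pytest.approx(
            math.log((10 * 45) / (40 * 5)), abs=1e-6)

    def test_intercept_only_bernoulli_mle(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(pd.DataFrame(index=range(100)), y)
        assert fit.params["const"] == pytest.approx(math.log(30 / 70),
                                                    abs=1e-6)

    def test_all_zero_outcome_degenerate(self):
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(pd.DataFrame({"x": [0.0, 1.0]}), [0, 0])

    def test_separation_flagged(self):
        x = np.r_[np.zeros(15), np.ones(15)]
        fit = fit_logistic(pd.DataFrame({"x": x}), x.astype(int))
        assert fit.separation


class TestG2:
    def _fits(self, rng, n=200, k=3):
        X = pd.DataFrame(rng.normal(size=(n, k)),
                         columns=[f"x{i}" for i in range(k)])
        y = (rng.random(n) < expit(0.5 * X["x0"] - 0.3)).astype(int)
        return X, y

    def test_identical_models_g2_zero_p_one(self):
        rng = np.random.default_rng(0)
        X, y = self._fits(rng)
        fit = fit_logistic(X, y)
        g2, df_diff, df_total, p = g2_statistic(fit, fit)
        assert g2 == 0.0 and df_diff == 0 and p == 1.0 and df_total == 3

    def test_duplicated_column_adds_nothing(self):
        rng = np.random.default_rng(1)
        X, y = self._fits(rng)
        X2 = X.copy()
        X2["x0_copy"] = X["x0"]
        base = fit_logistic(X, y)
        full = fit_logistic(X2, y)
        g2, df_diff, _, _ = g2_statistic(full, base)
        assert g2 == pytest.approx(0.0, abs=1e-4)
        assert df_diff == 1

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(2)
        X, y = self._fits(rng)
        a = fit_logistic(X[["x0", "x1"]], y)
        b = fit_logistic(X[["x2"]], y)
        with pytest.raises(ContractError):
            g2_statistic(a, b)

    def test_matches_independent_optimizer_oracle(self):
        """Deviance difference vs direct likelihood maximization, 50 fixtures."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(40, 120))
            X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
            y = (rng.random(n) < expit(0.8 * X["a"])).astype(int)
            if y.sum() in (0, n):
                continue
            base = fit_logistic(X[["a"]], y)
            full = fit_logistic(X, y)
            g2, _, _, _ = g2_statistic(full, base)
            oracle_g2 = 2 * (oracle_loglik(X, y) - oracle_loglik(X[["a"]], y))
            assert g2 == pytest.approx(oracle_g2, abs=1e-6)


class TestCStatistic:
    def test_constant_scores_give_half(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        assert c_statistic(np.full(100, 0.3), y) == 0.5

    def test_perfect_separation_gives_one(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        s = np.r_[np.linspace(0.6, 1.0, 30), np.linspace(0.0, 0.4, 70)]
        assert c_statistic(s, y) == 1.0

    def test_four_point_example(self):
        # events score 0.9, 0.7; non-events 0.8, 0.6: 3 of 4 pairs concordant
        assert c_statistic([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            c_statistic([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            n = int(rng.integers(4, 25))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            # discretized scores so ties occur often
            s = rng.integers(0, 6, size=n) / 5.0
            assert c_statistic(s, y) == pytest.approx(brute_force_c(s, y),
                                                      abs=1e-12)

    def test_matches_mann_whitney_u(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            s = rng.normal(size=n).round(1)
            u = stats.mannwhitneyu(s[y == 1], s[y == 0],
                                   alternative="two-sided").statistic
            assert c_statistic(s, y) == pytest.approx(
                u / (y.sum() * (n - y.sum())), abs=1e-12)

    @given(st.lists(st.tuples(st.floats(-5, 5), st.integers(0, 1)),
                    min_size=4, max_size=30).filter(
        lambda v: 0 < sum(t[1] for t in v) < len(v)))
    @settings(max_examples=60, deadline=None)
    def test_invariant_under_increasing_transform(self, pairs):
        # power-of-two scaling is strictly increasing and float-exact, so it
        # preserves the order and tie structure of the scores precisely
        s = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        assert c_statistic(4.0 * s + 0.0, y) == pytest.approx(
            c_statistic(s, y), abs=1e-12)


class TestBootstrap:
    def _simple(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = (rng.random(n) < expit(1.0 * X["x"])).astype(int)
        return X, y

    def test_same_seed_identical_ci(self):
        X, y = self._simple()
        b1 = bootstrap_c_ci(X, y, n_reps=50, seed=4)
        b2 = bootstrap_c_ci(X, y, n_reps=50, seed=4)
        assert (b1.ci_low, b1.ci_high) == (b2.ci_low, b2.ci_high)
        assert np.array_equal(b1.replicates, b2.replicates)

    def test_separable_toy_ci_is_degenerate_at_one(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        b = bootstrap_c_ci(X, y, n_reps=40, seed=1)
        assert (b.ci_low, b.ci_high) == (1.0, 1.0)

    def test_point_estimate_inside_ci(self):
        X, y = self._simple(seed=3)
        b = bootstrap_c_ci(X, y, n_reps=100, seed=2)
        assert b.ci_low <= b.point <= b.ci_high

    def test_nominal_coverage_of_percentile_ci(self):
        """~95% CIs should cover the large-sample true c in most datasets."""
        beta = 1.2
        rng = np.random.default_rng(123)
        xs = rng.normal(size=100_000)
        ys = (rng.random(100_000) < expit(beta * xs)).astype(int)
        true_c = c_statistic(xs, ys)  # large-sample truth, score = x
        covered = 0
        n_data = 40
        for d in range(n_data):
            X = pd.DataFrame({"x": rng.normal(size=500)})
            y = (rng.random(500) < expit(beta * X["x"])).astype(int)
            b = bootstrap_c_ci(X, y, n_reps=100, seed=1000 + d)
            covered += b.ci_low <= true_c <= b.ci_high
        assert 0.85 * n_data <= covered <= n_data


class TestPairedCompare:
    def test_identical_designs_all_ties(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"x": rng.normal(size=200)})
        y = (rng.random(200) < expit(X["x"])).astype(int)
        res = paired_bootstrap_compare(X, X.copy(), y, n_reps=30, seed=6)
        assert res.win_fraction_a == 0.0 and res.tie_fraction == 1.0

    def test_pure_noise_column_no_systematic_win(self):
        # adding a pure-noise column cannot give either model a material
        # edge: A never wins systematically, and the replicate c differences
        # are negligible (the extra in-sample parameter can only produce a
        # hair-thin overfitting advantage for B, never a real one)
        rng = np.random.default_rng(6)
        n = 3000
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = (rng.random(n) < expit(0.8 * X["x"])).astype(int)
        Xb = X.copy()
        Xb["noise"] = rng.normal(size=n)
        res = paired_bootstrap_compare(X, Xb, y, n_reps=200, seed=7)
        assert res.win_fraction_a <= 0.8
        assert abs(res.diffs.mean()) < 0.005

    def test_symmetric_noise_null_is_balanced(self):
        # two non-nested models with independent noise columns: neither
        # should win systematically
        rng = np.random.default_rng(16)
        n = 3000
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.8 * x)).astype(int)
        Xa = pd.DataFrame({"x": x, "noise_a": rng.normal(size=n)})
        Xb = pd.DataFrame({"x": x, "noise_b": rng.normal(size=n)})
        res = paired_bootstrap_compare(Xa, Xb, y, n_reps=200, seed=7)
        assert 0.2 <= res.win_fraction_a <= 0.8

    def test_informative_columns_dominate(self):
        rng = np.random.default_rng(7)
        n = 3000
        hidden = pd.DataFrame(rng.integers(0, 2, size=(n, 2)).astype(float),
                              columns=["u", "v"])
        y = (rng.random(n) < expit(-1 + 1.2 * hidden["u"]
                                   + 1.0 * hidden["v"])).astype(int)
        noise = pd.DataFrame({"w": rng.normal(size=n)})
        res = paired_bootstrap_compare(hidden, noise, y, n_reps=100, seed=8)
        assert res.win_fraction_a >= 0.99
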