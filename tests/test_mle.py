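"""Interval-censored likelihood, optimizer, robust covariance, Wald test."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import equiwtp as ew
from equiwtp.errors import DataError, EstimationError
from equiwtp.mle import _loglik_terms, _score_matrix

from conftest import grid_loglik_argmax, make_intercept_data


def iv(lo, up):
    return ew.WTPInterval(lower=lo, upper=up)


class TestObsLoglik:
    def test_unbounded_interval_is_exactly_zero(self):
        assert ew.obs_loglik(iv(-math.inf, math.inf), [1.0], [0.3], -2.0) == 0.0

    def test_right_censored_at_the_mean_is_log_half(self):
        ll = ew.obs_loglik(iv(0.25, math.inf), [1.0], [0.25], np.log(0.05))
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    def test_central_interval_matches_normal_cdf(self):
        ll = ew.obs_loglik(iv(-1.96, 1.96), [1.0], [0.0], 0.0)
        expected = math.log(stats.norm.cdf(1.96) - stats.norm.cdf(-1.96))
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_extreme_tail_does_not_underflow(self):
        # both bounds 30+ sigma below the mean: naive CDF difference is 0-0
        ll = ew.obs_loglik(iv(0.10, 0.11), [1.0], [3.5], np.log(0.1))
        assert np.isfinite(ll) and ll < -100

    def test_degenerate_interval_rejected(self):
        with pytest.raises(DataError):
            iv(0.2, 0.2)


class TestScore:
    def test_analytic_score_matches_finite_differences(self):
        # 100 random (interval, x, beta, ln_sigma) points, including censored rows
        r = np.random.default_rng(77)
        h = 1e-6
        for _ in range(100):
            k = r.integers(1, 4)
            x = r.normal(size=k)
            beta = r.normal(scale=0.3, size=k)
            lns = r.uniform(-3.0, 0.0)
            mu = x @ beta
            kind = r.integers(0, 3)
            a, b = np.sort(mu + np.exp(lns) * r.uniform(-3, 3, size=2))
            if abs(a - b) < 1e-6:
                b = a + 1e-3
            lo, up = {0: (a, b), 1: (-np.inf, b), 2: (a, np.inf)}[int(kind)]
            theta = np.append(beta, lns)
            X = x[None, :]
            S, _ = _score_matrix(theta, np.array([lo]), np.array([up]), X)
            for j in range(k + 1):
                e = np.zeros(k + 1)
                e[j] = h
                lp = _loglik_terms(theta + e, np.array([lo]), np.array([up]), X)[0][0]
                lm = _loglik_terms(theta - e, np.array([lo]), np.array([up]), X)[0][0]
                fd = (lp - lm) / (2 * h)
                assert S[0, j] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestFit:
    def test_intercept_only_recovery(self):
        data = make_intercept_data(2000, mu=0.20, sigma=0.05, seed=314)
        res = ew.fit(data)
        assert res.converged
        se = res.robust_se()[0]
        assert abs(res.beta[0] - 0.20) < 3 * se
        assert res.sigma == pytest.approx(0.05, rel=0.15)
        assert res.loglik <= 0

    def test_all_unbounded_is_unidentified(self):
        with pytest.raises(EstimationError):
            ew.EstimationDataset(lower=np.full(5, -np.inf), upper=np.full(5, np.inf),
                                 X=np.ones((5, 1)), names=["const"])

    def test_rank_deficient_design_names_columns(self):
        data = make_intercept_data(100, mu=0.15, sigma=0.08, seed=1)
        X = np.column_stack([data.X[:, 0], np.ones(100), np.zeros(100)])
        bad = ew.EstimationDataset(lower=data.lower, upper=data.upper, X=X,
                                   names=["const", "dup", "zero"])
        with pytest.raises(EstimationError, match="collinear"):
            ew.fit(bad)

    def test_too_few_observations(self):
        data = make_intercept_data(30, mu=0.15, sigma=0.08, seed=2)
        tiny = ew.EstimationDataset(lower=data.lower[:2], upper=data.upper[:2],
                                    X=data.X[:2], names=["const"])
        with pytest.raises(EstimationError):
            ew.fit(tiny)

    def test_sigma_positive_by_construction(self):
        data = make_intercept_data(200, mu=0.12, sigma=0.02, seed=3)
        res = ew.fit(data)
        assert res.sigma > 0

    def test_matches_grid_search_oracle(self):
        # brute-force maximization of the same objective on a fine grid
        data = make_intercept_data(30, mu=0.18, sigma=0.06, seed=99)
        res = ew.fit(data)
        b_grid = np.arange(0.05, 0.35, 0.002)
        s_grid = np.arange(np.log(0.01), np.log(0.3), 0.01)
        best = grid_loglik_argmax(data, b_grid, s_grid)
        assert abs(res.beta[0] - best[0]) <= 0.002 + 1e-12
        assert abs(res.ln_sigma - best[1]) <= 0.01 + 1e-12


class TestRobustCovariance:
    def test_close_to_model_based_under_correct_specification(self):
        data = make_intercept_data(20000, mu=0.15, sigma=0.08, seed=8)
        res = ew.fit(data)
        robust = res.robust_se()
        model = np.sqrt(np.diag(res.model_cov))
        assert np.all(np.abs(robust / model - 1) < 0.15)

    def test_symmetric_positive_semidefinite(self):
        data = make_intercept_data(500, mu=0.15, sigma=0.08, seed=9)
        res = ew.fit(data)
        V = res.robust_cov
        assert np.allclose(V, V.T)
        assert np.all(np.linalg.eigvalsh(V) > -1e-12)

    def test_recompute_matches_fit(self):
        data = make_intercept_data(500, mu=0.15, sigma=0.08, seed=10)
        res = ew.fit(data)
        V = ew.robust_covariance(res, data)
        assert np.allclose(V, res.robust_cov, rtol=1e-4, atol=1e-10)

    def test_dof_scaling_factor(self):
        data = make_intercept_data(300, mu=0.15, sigma=0.08, seed=11)
        res = ew.fit(data)
        V = ew.robust_covariance(res, data, dof_scale=True)
        assert np.allclose(V, res.robust_cov * data.n / (data.n - 2), rtol=1e-4)


class TestWald:
    def test_definition_and_df(self, preset):
        import dataclasses

        cfg = dataclasses.replace(preset.groups["boarder"], n=1500)
        data, _ = ew.simulate_estimation_data(cfg, np.random.default_rng(4))
        res = ew.fit(data)
        W, df, p = ew.wald_test(res)
        assert df == len(ew.MODEL_COLUMNS["boarder"]) == 15
        slope_idx = [j for j, nm in enumerate(res.names) if nm != "const"]
        b = res.beta[slope_idx]
        Vb = res.beta_cov()[np.ix_(slope_idx, slope_idx)]
        assert W == pytest.approx(float(b @ np.linalg.solve(Vb, b)))
        assert res.wald_chi2 == pytest.approx(W)

    def test_owner_and_leaser_df(self):
        assert len(ew.MODEL_COLUMNS["owner"]) == 13
        assert len(ew.MODEL_COLUMNS["leaser"]) == 13

    def test_single_slope_equals_squared_z(self):
        r = np.random.default_rng(12)
        n = 800
        x = (r.random(n) < 0.5).astype(float)
        data_base = make_intercept_data(n, mu=0.15, sigma=0.08, seed=13)
        data = ew.EstimationDataset(lower=data_base.lower, upper=data_base.upper,
                                    X=np.column_stack([np.ones(n), x]),
                                    names=["const", "treat"])
        res = ew.fit(data)
        z = res.z_values()[1]
        assert res.wald_chi2 == pytest.approx(z ** 2, rel=1e-8)


class TestLikelihoodProperties:
    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-0.2, 0.4), st.floats(-2.5, -1.0),
           st.floats(0.02, 0.3), st.floats(0.02, 0.3))
    def test_tightening_never_raises_loglik(self, mu, lns, lo_off, width):
        lo = mu - lo_off
        up = lo + width
        wide = ew.obs_loglik(iv(lo, up), [1.0], [mu], lns)
        inner = ew.obs_loglik(iv(lo + width * 0.2, up - width * 0.2), [1.0], [mu], lns)
        assert inner <= wide + 1e-12

    def test_loglik_terms_always_nonpositive(self, rng):
        data = make_intercept_data(200, mu=0.15, sigma=0.08, seed=21)
        ll, _, _ = _loglik_terms(np.array([0.1, -2.0]), data.lower, data.upper, data.X)
        assert np.all(ll <= 1e-12)


class TestSequenceProbabilities:
    def test_example_against_normal_cdf(self):
        sched = ew.BidSchedule(c2y_frac=0.15, c2n_frac=0.05)
        probs = ew.sequence_probabilities([1.0], [0.155], 0.05, sched)
        assert probs["yes_yes"] == pytest.approx(1 - stats.norm.cdf(-0.1), abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-0.3, 0.5), st.floats(0.01, 0.5),
           st.sampled_from([0.11, 0.15, 0.20]), st.sampled_from([0.01, 0.05, 0.09]))
    def test_sums_to_one(self, mu, sigma, c2y, c2n):
        sched = ew.BidSchedule(c2y_frac=c2y, c2n_frac=c2n)
        probs = ew.sequence_probabilities([1.0], [mu], sigma, sched)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0 <= v <= 1 for v in probs.values())

    def test_bad_schedule_rejected(self):
        with pytest.raises(DataError):
            ew.sequence_probabilities([1.0], [0.1], 0.05,
                                      ew.BidSchedule(c2y_frac=0.05, c2n_frac=0.15))

    def test_bad_sigma_rejected(self):
        sched = ew.BidSchedule(c2y_frac=0.15, c2n_frac=0.05)
        with pytest.raises(DataError):
            ew.sequence_probabilities([1.0], [0.1], 0.0, sched)


class TestDegenerateColumns:
    def test_all_zero_indicator_is_omitted(self):
        data = make_intercept_data(100, mu=0.15, sigma=0.08, seed=31)
        X = np.column_stack([data.X[:, 0], np.zeros(100)])
        d = ew.EstimationDataset(lower=data.lower, upper=data.upper, X=X,
                                 names=["const", "empty"])
        reduced, dropped = ew.drop_degenerate_columns(d)
        assert dropped == ["empty"]
        assert reduced.names == ["const"]
        res = ew.fit(reduced)
        assert res.converged

    def test_varying_columns_kept(self):
        data = make_intercept_data(50, mu=0.15, sigma=0.08, seed=32)
        reduced, dropped = ew.drop_degenerate_columns(data)
        assert dropped == [] and reduced.names == data.names
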