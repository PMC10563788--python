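"""Unit and property tests of the mixture density regression core."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import sweepmix as sm
from sweepmix.model import FitConfig, _nll_and_grad, _pack


def _params(a=0.0, b=(0.0,), mu0=0.0, s0=1.0, mu1=0.0, s1=1.0):
    return sm.MDRParameters(intercept=a, slopes=np.asarray(b, float),
                            mu0=mu0, sigma0=s0, mu1=mu1, sigma1=s1)


class TestMixingProbability:
    def test_sigmoid_at_zero(self):
        p = _params(a=0.0, b=(0.0, 0.0))
        assert sm.mixing_probability(p, [1.3, -2.1]) == 0.5

    def test_hand_evaluated_logit(self):
        p = _params(a=1.0, b=(2.0, -1.0))
        expected = 1.0 / (1.0 + math.exp(-1.0))  # sigmoid(1 + 1 - 1)
        assert sm.mixing_probability(p, [0.5, 1.0]) == pytest.approx(
            expected, abs=1e-12)

    def test_monotone_in_intercept_and_limit(self):
        x = [0.3]
        values = [sm.mixing_probability(_params(a=a, b=(0.5,)), x)
                  for a in (-5, 0, 5, 20)]
        assert all(v1 < v2 for v1, v2 in zip(values, values[1:]))
        saturated = sm.mixing_probability(_params(a=800.0, b=(0.5,)), x)
        assert saturated < 1.0  # strictly inside (0, 1) even at eta ~ 800
        assert saturated > 1.0 - 1e-12

    def test_numerically_stable_far_tail(self):
        p = _params(a=-750.0, b=(0.0,))
        v = sm.mixing_probability(p, [0.0])
        assert 0.0 < v < 1e-300 or v > 0.0

    def test_dimension_mismatch_names_lengths(self):
        with pytest.raises(ValueError, match="length 3, expected 2"):
            sm.mixing_probability(_params(b=(1.0, 2.0)), [1, 2, 3])

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(-3, 3), st.floats(0.05, 3), st.floats(-2, 2))
    def test_strictly_monotone_in_covariate(self, x, slope, a):
        up = _params(a=a, b=(slope,))
        down = _params(a=a, b=(-slope,))
        assert (sm.mixing_probability(up, [x + 0.1])
                > sm.mixing_probability(up, [x]))
        assert (sm.mixing_probability(down, [x + 0.1])
                < sm.mixing_probability(down, [x]))


class TestLogLikelihood:
    def test_identical_components_give_standard_normal(self):
        p = _params()
        ll = sm.log_likelihood(p, np.zeros((1, 1)), [0.0])
        assert ll == pytest.approx(math.log(1 / math.sqrt(2 * math.pi)),
                                   abs=1e-12)

    def test_mixture_collapse_ignores_mixing_parameters(self):
        y = np.array([-1.0, 0.2, 2.3])
        X = np.array([[1.0], [2.0], [-0.5]])
        base = stats.norm.logpdf(y, 0.3, 1.7).sum()
        for a, b in [(0.0, 5.0), (-30.0, 0.1), (12.0, -4.0)]:
            p = _params(a=a, b=(b,), mu0=0.3, s0=1.7, mu1=0.3, s1=1.7)
            assert sm.log_likelihood(p, X, y) == pytest.approx(base,
                                                               abs=1e-10)

    def test_matches_direct_density_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((5, 2))
        y = rng.standard_normal(5)
        p = _params(a=-0.4, b=(0.8, -1.2), mu0=-0.5, s0=0.9, mu1=1.1, s1=1.3)
        w = 1 / (1 + np.exp(-(p.intercept + X @ p.slopes)))
        direct = np.log(w * stats.norm.pdf(y, p.mu1, p.sigma1)
                        + (1 - w) * stats.norm.pdf(y, p.mu0, p.sigma0)).sum()
        assert sm.log_likelihood(p, X, y) == pytest.approx(direct, abs=1e-10)

    def test_no_underflow_in_far_tail(self):
        p = _params(a=-2.0, b=(0.0,), mu0=0.0, s0=0.5, mu1=2.0, s1=0.5)
        ll = sm.log_likelihood(p, np.zeros((1, 1)), [40.0])
        assert np.isfinite(ll)

    def test_rejects_empty_and_nonfinite(self):
        p = _params()
        with pytest.raises(ValueError, match="empty"):
            sm.log_likelihood(p, np.zeros((0, 1)), [])
        with pytest.raises(ValueError):
            sm.log_likelihood(p, np.array([[np.nan]]), [0.0])

    def test_intercept_translation_invariance(self):
        # shifting one standardized covariate by c and compensating the
        # intercept by -b_j * c leaves the linear predictor unchanged
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        p = _params(a=0.2, b=(0.7, -0.3, 1.1), mu0=-0.4, s0=0.8, mu1=0.9,
                    s1=1.0)
        c = 1.7
        X2 = X.copy()
        X2[:, 1] += c
        p2 = sm.MDRParameters(p.intercept - p.slopes[1] * c, p.slopes,
                              p.mu0, p.sigma0, p.mu1, p.sigma1)
        assert sm.log_likelihood(p2, X2, y) == pytest.approx(
            sm.log_likelihood(p, X, y), abs=1e-10)

    def test_mixture_density_normalizes(self):
        from scipy.integrate import quad
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = _params(a=rng.normal(), b=(rng.normal(),),
                        mu0=rng.normal(), s0=rng.uniform(0.3, 2),
                        mu1=rng.normal() + 3, s1=rng.uniform(0.3, 2))
            x = rng.standard_normal(1)
            w = sm.mixing_probability(p, x)
            total, _ = quad(lambda y: w * stats.norm.pdf(y, p.mu1, p.sigma1)
                            + (1 - w) * stats.norm.pdf(y, p.mu0, p.sigma0),
                            -30, 30)
            assert total == pytest.approx(1.0, abs=1e-6)


class TestResponsibilities:
    def test_collapse_equals_mixing_probability(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 2))
        y = rng.standard_normal(8)
        p = _params(a=0.3, b=(1.0, -0.5), mu0=0.1, s0=1.2, mu1=0.1, s1=1.2)
        r = sm.responsibilities(p, X, y)
        np.testing.assert_allclose(r, sm.mixing_probability(p, X), rtol=1e-12)

    def test_tail_dominance(self):
        p = _params(a=0.0, b=(0.0,), mu0=0.0, s0=1.0, mu1=1.0, s1=1.0)
        r = sm.responsibilities(p, np.zeros((1, 1)), [60.0])
        assert r[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_unlogged_density_ratio(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((4, 2))
        y = rng.standard_normal(4)
        p = _params(a=0.2, b=(0.5, -0.7), mu0=-0.3, s0=0.8, mu1=0.8, s1=1.1)
        w = 1 / (1 + np.exp(-(p.intercept + X @ p.slopes)))
        n1 = w * stats.norm.pdf(y, p.mu1, p.sigma1)
        n0 = (1 - w) * stats.norm.pdf(y, p.mu0, p.sigma0)
        np.testing.assert_allclose(sm.responsibilities(p, X, y),
                                   n1 / (n1 + n0), atol=1e-12)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        eps = 1e-6
        for _ in range(20):
            theta = rng.normal(scale=0.8, size=3 + 5)
            f0, g = _nll_and_grad(theta, X, y)
            num = np.empty_like(theta)
            for i in range(theta.size):
                tp, tm = theta.copy(), theta.copy()
                tp[i] += eps
                tm[i] -= eps
                num[i] = (_nll_and_grad(tp, X, y)[0]
                          - _nll_and_grad(tm, X, y)[0]) / (2 * eps)
            np.testing.assert_allclose(g, num, rtol=1e-5, atol=1e-6)


class TestFit:
    def test_warns_on_small_sample(self, small_params):
        cfg = sm.GeneratorConfig(n_windows=40, true_params=small_params,
                                 seed=0)
        X, y, _ = sm.simulate_mdr_dataset(cfg)
        with pytest.warns(UserWarning, match="recommend"):
            sm.fit_mdr(X, y, FitConfig(restarts=1))

    def test_duplicating_rows_doubles_loglik(self, small_params):
        cfg = sm.GeneratorConfig(n_windows=3000, true_params=small_params,
                                 seed=4)
        X, y, _ = sm.simulate_mdr_dataset(cfg)
        fc = FitConfig(restarts=1, seed=0)
        fit1 = sm.fit_mdr(X, y, fc)
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = np.concatenate([y, y])
        fit2 = sm.fit_mdr(X2, y2, fc)
        # the optimum is identical; stopping points differ microscopically
        np.testing.assert_allclose(fit2.params.slopes, fit1.params.slopes,
                                   atol=1e-3)
        assert fit2.loglik == pytest.approx(2 * fit1.loglik, rel=1e-6)

    def test_loglik_improves_on_init(self, small_params):
        cfg = sm.GeneratorConfig(n_windows=2000, true_params=small_params,
                                 seed=9)
        X, y, _ = sm.simulate_mdr_dataset(cfg)
        fit = sm.fit_mdr(X, y, FitConfig(restarts=2, seed=0))
        assert fit.converged
        assert fit.loglik >= sm.log_likelihood(small_params, X, y) - 1e-6

    def test_restart_seed_does_not_move_well_separated_solution(
            self, small_params):
        cfg = sm.GeneratorConfig(n_windows=5000, true_params=small_params,
                                 seed=2)
        X, y, _ = sm.simulate_mdr_dataset(cfg)
        fit_a = sm.fit_mdr(X, y, FitConfig(restarts=3, seed=1))
        fit_b = sm.fit_mdr(X, y, FitConfig(restarts=3, seed=99))
        np.testing.assert_allclose(fit_a.params.slopes, fit_b.params.slopes,
                                   atol=1e-4)
        assert abs(fit_a.params.mu1 - fit_b.params.mu1) < 1e-4


class TestLRT:
    def test_duplicate_column_gives_null_statistic(self, small_params):
        cfg = sm.GeneratorConfig(n_windows=3000, true_params=small_params,
                                 seed=8)
        X, y, _ = sm.simulate_mdr_dataset(cfg)
        X = X.copy()
        X["dup"] = X["x1"]  # dropping a perfect duplicate changes nothing
        res = sm.lrt_covariate(X, y, "dup", FitConfig(restarts=1, seed=0))
        assert res.lr_statistic < 1e-2
        assert res.pvalue > 0.9

    def test_statistic_nonnegative_and_chi2_tail(self, small_params):
        cfg = sm.GeneratorConfig(n_windows=2000, true_params=small_params,
                                 seed=3)
        X, y, _ = sm.simulate_mdr_dataset(cfg)
        res = sm.lrt_covariate(X, y, "x1", FitConfig(restarts=1, seed=0))
        assert res.lr_statistic >= 0
        assert res.pvalue == pytest.approx(
            stats.chi2.sf(res.lr_statistic, 1), abs=1e-14)
        # strong true slope: decisively significant
        assert res.pvalue < 1e-6

    def test_unknown_covariate_lists_names(self, small_params):
        cfg = sm.GeneratorConfig(n_windows=500, true_params=small_params,
                                 seed=3)
        X, y, _ = sm.simulate_mdr_dataset(cfg)
        with pytest.raises(KeyError, match="x1"):
            sm.lrt_covariate(X, y, "nope", FitConfig(restarts=1))

    def test_lrt_all_reports_every_covariate(self, small_params):
        cfg = sm.GeneratorConfig(n_windows=2000, true_params=small_params,
                                 seed=6)
        X, y, _ = sm.simulate_mdr_dataset(cfg)
        full, table = sm.lrt_all_covariates(X, y,
                                            FitConfig(restarts=1, seed=0),
                                            bh_correction=True,
                                            test_intercept=True)
        assert list(table["covariate"]) == ["intercept", "x1", "x2"]
        assert "qvalue" in table.columns
        assert ((table["pvalue"] >= 0) & (table["pvalue"] <= 1)).all()


class TestComponentMagnitude:
    def test_recovers_baseline_probability_on_average(self):
        # flat gating at logit(0.3): the weight of overlapping components is
        # weakly identified per dataset, but the fitted magnitude is
        # unbiased; check the mean over replicates within 3 MC standard
        # errors (per-fit SD is about 0.09 under these conditions)
        from scipy import special
        truth = sm.MDRParameters(intercept=float(special.logit(0.3)),
                                 slopes=np.zeros(3), mu0=-0.39, sigma0=0.85,
                                 mu1=0.9, sigma1=0.95)
        mags = []
        for rep in range(12):
            cfg = sm.GeneratorConfig(n_windows=20_000, true_params=truth,
                                     seed=500 + rep)
            X, y, _ = sm.simulate_mdr_dataset(cfg)
            fit = sm.fit_mdr(X, y, FitConfig(restarts=1, seed=rep))
            mags.append(sm.component_magnitude(fit))
        assert abs(np.mean(mags) - 0.30) < 3 * 0.09 / np.sqrt(12)

    def test_constant_probability_returns_it(self, small_params):
        fit = sm.MDRFit(params=small_params, loglik=0.0, converged=True,
                        n_restarts_used=1,
                        per_window_p=np.full(10, 0.37),
                        covariate_names=["x1", "x2"], n_windows=10)
        assert sm.component_magnitude(fit) == pytest.approx(0.37)

    def test_empty_fit_raises(self, small_params):
        fit = sm.MDRFit(params=small_params, loglik=0.0, converged=True,
                        n_restarts_used=1, per_window_p=np.empty(0),
                        covariate_names=[], n_windows=0)
        with pytest.raises(ValueError):
            sm.component_magnitude(fit)


class TestParameterValidation:
    def test_ordering_and_positivity(self):
        with pytest.raises(ValueError):
            _params(mu0=1.0, mu1=0.0)
        with pytest.raises(ValueError):
            _params(s0=-1.0)
        with pytest.raises(ValueError):
            _params(s1=0.0)

    def test_pack_unpack_roundtrip(self):
        p = _params(a=0.4, b=(1.0, -2.0), mu0=-0.3, s0=0.7, mu1=1.2, s1=1.4)
        from sweepmix.model import _unpack
        q = _unpack(_pack(p), 2)
        assert q.mu1 == pytest.approx(p.mu1, rel=1e-14)
        assert q.sigma0 == pytest.approx(p.sigma0, rel=1e-14)
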