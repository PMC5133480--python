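"""Joint copula MLE, Wald tests, univariate and reference fits."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import ndtri

from copulaqtl import (
    CopulaParams,
    MarginParams,
    empirical_kendall_tau,
    fit_joint_copula,
    fit_reference_models,
    fit_univariate,
    joint_neg_loglik,
    model_aic,
    wald_test,
)
from copulaqtl.simulate import sample_copula, simulate_genotypes


def _simulated_pair(n, params, alpha1=0.5, beta1=0.8, sigma1=1.0, sigma2=1.0,
                    alpha0=1.0, beta0=-0.5, maf=0.3, seed=0):
    rng = np.random.default_rng(seed)
    g = simulate_genotypes(n, maf, seed=rng)
    u1, u2 = sample_copula(n, params, rng)
    y1 = alpha0 + alpha1 * g + sigma1 * ndtri(u1)
    y2 = beta0 + beta1 * g + sigma2 * ndtri(u2)
    return y1, y2, g


class TestJointNegLoglik:
    def test_independence_factorization(self):
        y1, y2, g = _simulated_pair(300, CopulaParams(1.0, 1.5), seed=1)
        margins = MarginParams(1.0, 0.5, 1.1, -0.5, 0.8, 0.9)
        near_indep = CopulaParams(1e-8, 1.0)
        nll = joint_neg_loglik(margins, near_indep, y1, y2, g)
        ll1 = stats.norm.logpdf(y1, 1.0 + 0.5 * g, 1.1).sum()
        ll2 = stats.norm.logpdf(y2, -0.5 + 0.8 * g, 0.9).sum()
        assert nll == pytest.approx(-(ll1 + ll2), abs=1e-4)

    def test_matches_brute_force_summation(self):
        # Clayton slice: copula density has the closed form
        # (1+phi)(uv)^-(1+phi) (u^-phi + v^-phi - 1)^-(2+1/phi)
        phi = 1.4
        margins = MarginParams(0.2, 0.4, 1.3, -0.1, 0.7, 0.8)
        cop = CopulaParams(phi, 1.0)
        y1 = np.array([0.1, -0.5, 1.2, 0.7, -1.1])
        y2 = np.array([-0.3, 0.9, 0.4, -0.2, 1.5])
        g = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        total = 0.0
        for a, b, gi in zip(y1, y2, g):
            u = stats.norm.cdf((a - 0.2 - 0.4 * gi) / 1.3)
            v = stats.norm.cdf((b + 0.1 - 0.7 * gi) / 0.8)
            logc = (np.log1p(phi) - (1 + phi) * np.log(u * v)
                    - (2 + 1 / phi) * np.log(u**-phi + v**-phi - 1))
            total += (logc + stats.norm.logpdf(a, 0.2 + 0.4 * gi, 1.3)
                      + stats.norm.logpdf(b, -0.1 + 0.7 * gi, 0.8))
        assert joint_neg_loglik(margins, cop, y1, y2, g) == pytest.approx(-total, abs=1e-10)

    def test_permutation_invariant(self):
        y1, y2, g = _simulated_pair(200, CopulaParams(1.0, 1.2), seed=2)
        margins = MarginParams(1.0, 0.5, 1.0, -0.5, 0.8, 1.0)
        cop = CopulaParams(1.0, 1.2)
        perm = np.random.default_rng(3).permutation(200)
        assert joint_neg_loglik(margins, cop, y1, y2, g) == pytest.approx(
            joint_neg_loglik(margins, cop, y1[perm], y2[perm], g[perm]), rel=1e-12)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            MarginParams(0, 0, -1.0, 0, 0, 1.0)


class TestFitJointCopula:
    def test_single_dataset_recovery_within_reported_se(self):
        truth = dict(alpha0=1.0, alpha1=0.5, sigma1=1.0, beta0=-0.5, beta1=0.8,
                     sigma2=1.0)
        y1, y2, g = _simulated_pair(2000, CopulaParams(1.0, 1.5), seed=4)
        fit = fit_joint_copula(y1, y2, g)
        assert fit.converged and not fit.boundary
        se = np.sqrt(np.diag(fit.covariance))
        est = [fit.margins.alpha0, fit.margins.alpha1, fit.margins.sigma1,
               fit.margins.beta0, fit.margins.beta1, fit.margins.sigma2,
               fit.copula.phi, fit.copula.theta]
        for e, s, t in zip(est, se, list(truth.values()) + [1.0, 1.5]):
            assert abs(e - t) < 3.5 * s
        assert fit.aic == pytest.approx(16 - 2 * fit.loglik)

    def test_negative_dependence_uses_rotation(self):
        y1, y2, g = _simulated_pair(800, CopulaParams(1.5, 1.3, rotation=90), seed=5)
        fit = fit_joint_copula(y1, y2, g)
        assert fit.copula.rotation in (90, 270)
        assert fit.model_tau < -0.2

    def test_copula_point_estimates_match_univariate_on_average(self):
        # under the null the mean difference between copula and OLS slope
        # estimates is zero
        diffs = []
        for seed in range(60):
            y1, y2, g = _simulated_pair(81, CopulaParams(0.5, 1.0), alpha1=0.0,
                                        beta1=0.0, sigma1=15.0, maf=0.2, seed=100 + seed)
            jf = fit_joint_copula(y1, y2, g)
            uni = fit_univariate(y1, g)
            diffs.append(jf.margins.alpha1 - uni.slope)
        diffs = np.asarray(diffs)
        mcse = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3.0 * mcse

    def test_copula_loglik_dominates_independence(self):
        for seed in (6, 7, 8):
            y1, y2, g = _simulated_pair(300, CopulaParams(1.0, 1.4), seed=seed)
            jf = fit_joint_copula(y1, y2, g)
            ref = fit_reference_models(y1, y2, g)
            assert jf.loglik >= ref.independence_loglik - 1e-6

    def test_monomorphic_rejected(self):
        y1, y2, _ = _simulated_pair(100, CopulaParams(1.0, 1.0), seed=9)
        with pytest.raises(ValueError, match="monomorphic"):
            fit_joint_copula(y1, y2, np.zeros(100))

    def test_too_few_observations_rejected(self):
        y1, y2, g = _simulated_pair(10, CopulaParams(1.0, 1.0), seed=10)
        with pytest.raises(ValueError, match="at least"):
            fit_joint_copula(y1, y2, g)


class TestWald:
    def test_reported_copula_association(self):
        # 30.77 mmHg per copy with SE 6.52 under the normal reference
        _, p = wald_test(30.77, 6.52)
        assert p == pytest.approx(2.40e-6, rel=0.05)

    def test_reported_univariate_association(self):
        # 32.21 (6.63) under t(n-2) with n=81; the exact df convention of the
        # reported analysis is unstated, so agreement within a factor 1.3
        _, p = wald_test(32.21, 6.63, df=79)
        assert 6.18e-6 / 1.3 < p < 6.18e-6 * 1.3

    def test_null_point(self):
        stat, p = wald_test(0.0, 2.5)
        assert stat == 0.0 and p == 1.0

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)


class TestUnivariate:
    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.3, 150).astype(float)
        y = 1.0 + 0.4 * g + rng.normal(0, 1.2, 150)
        fit = fit_univariate(y, g)
        ref = sm.OLS(y, sm.add_constant(g)).fit()
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-10)
        assert fit.se == pytest.approx(ref.bse[1], abs=1e-10)
        assert fit.p == pytest.approx(ref.pvalues[1], abs=1e-12)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(2000):
            g = rng.binomial(2, 0.3, 60).astype(float)
            if np.unique(g).size < 2:
                continue
            y = rng.normal(size=60)
            pvals.append(fit_univariate(y, g).p)
        d, _ = stats.kstest(pvals, "uniform")
        assert d < 0.05

    def test_exact_linear_degenerate(self):
        g = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        fit = fit_univariate(2.0 * g, g)
        assert fit.slope == pytest.approx(2.0)
        assert fit.se == 0.0 and fit.degenerate

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            fit_univariate(np.arange(5.0), np.ones(5))


class TestReferenceModels:
    def test_nesting_and_parameter_counts(self):
        y1, y2, g = _simulated_pair(200, CopulaParams(1.0, 1.3), seed=13)
        ref = fit_reference_models(y1, y2, g)
        assert ref.bvn_loglik >= ref.independence_loglik
        assert ref.k_independence == 6 and ref.k_bvn == 7
        assert ref.independence_aic == pytest.approx(12 - 2 * ref.independence_loglik)
        assert ref.bvn_aic == pytest.approx(14 - 2 * ref.bvn_loglik)

    def test_rho_recovery(self):
        rng = np.random.default_rng(14)
        n = 3000
        g = rng.binomial(2, 0.3, n).astype(float)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=n)
        ref = fit_reference_models(0.3 * g + z[:, 0], 0.2 * g + z[:, 1], g)
        assert abs(ref.rho - 0.5) < 3.0 * np.sqrt((1 - 0.5**2) ** 2 / n)


class TestAicAndTau:
    def test_aic_arithmetic_and_determinism(self):
        assert model_aic(-100.0, 8) == 216.0
        assert model_aic(-100.0, 8) == model_aic(-100.0, 8)
        with pytest.raises(ValueError):
            model_aic(0.0, 0)

    def test_tau_perfect_concordance(self):
        x = np.arange(10.0)
        assert empirical_kendall_tau(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert empirical_kendall_tau(x, -x)[0] == pytest.approx(-1.0)

    def test_tau_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        n = 50
        conc = disc = 0
        for i in range(n):
            for j in range(i + 1, n):
                s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
                conc += s > 0
                disc += s < 0
        expected = (conc - disc) / (n * (n - 1) / 2)  # no ties in continuous data
        assert empirical_kendall_tau(x, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            empirical_kendall_tau(np.ones(10), np.arange(10.0))
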