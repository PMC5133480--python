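"""Joint copula model of two adjusted phenotypes conditional on a variant.

The joint distribution of adjusted systolic blood pressure (SBP_adj) and an
adjusted expression trait (GE_adj), given a genotype dosage g in {0, 1, 2},
is

    F(y1, y2 | g) = C_psi( F1(y1 | g), F2(y2 | g) )

with Gaussian margins

    y1 = alpha0 + alpha1 * g + eps,    eps  ~ N(0, sigma1^2)
    y2 = beta0  + beta1  * g + eps',   eps' ~ N(0, sigma2^2)

and C_psi the two-parameter copula of :mod:`copulaqtl.copula`.  All eight
parameters are estimated by joint maximum likelihood; the variant effects
alpha1 and beta1 are tested with large-sample Wald statistics.  Univariate
OLS fits, a working-independence fit and a bivariate-normal fit are provided
for the power and AIC comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr

from .copula import (
    PHI_MAX,
    PHI_MIN,
    THETA_MAX,
    CopulaParams,
    bb1_log_pdf,
    init_params_from_tau,
    model_kendall_tau,
)

__all__ = [
    "MarginParams",
    "JointFit",
    "UnivariateFit",
    "ReferenceFits",
    "FitOptions",
    "joint_neg_loglik",
    "fit_joint_copula",
    "wald_test",
    "fit_univariate",
    "fit_reference_models",
    "model_aic",
    "empirical_kendall_tau",
]

_LOG_2PI = math.log(2.0 * math.pi)
# theta is optimized as log(theta - 1 + eps) so the Gumbel boundary theta=1
# remains reachable
_THETA_EPS = 1e-6


@dataclass(frozen=True)
class MarginParams:
    """Gaussian margin parameters for the two phenotype regressions."""

    alpha0: float
    alpha1: float
    sigma1: float
    beta0: float
    beta1: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigma1 and sigma2 must be positive")


@dataclass
class UnivariateFit:
    """Closed-form OLS fit of one phenotype on dosage with a t(n-2) slope test."""

    intercept: float
    slope: float
    se: float
    tstat: float
    p: float
    df: int
    sigma_mle: float
    loglik: float
    degenerate: bool = False


@dataclass
class ReferenceFits:
    """Working-independence (k=6) and bivariate-normal (k=7) reference fits."""

    independence_loglik: float
    independence_aic: float
    bvn_loglik: float
    bvn_aic: float
    rho: float
    k_independence: int = 6
    k_bvn: int = 7


@dataclass
class JointFit:
    """Joint MLE of the eight-parameter copula model for one (variant, gene) pair."""

    margins: MarginParams
    copula: CopulaParams
    loglik: float
    aic: float
    covariance: np.ndarray  # 8x8, natural scale, parameter order below
    wald_alpha1: tuple[float, float]
    wald_beta1: tuple[float, float]
    model_tau: float
    converged: bool
    n_used: int
    boundary: bool = False
    cov_method: str = "hessian"

    PARAM_NAMES = ("alpha0", "alpha1", "sigma1", "beta0", "beta1", "sigma2", "phi", "theta")

    @property
    def se_alpha1(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    @property
    def se_beta1(self) -> float:
        return float(np.sqrt(self.covariance[4, 4]))


@dataclass
class FitOptions:
    """Optimizer configuration for the joint fit."""

    tol: float = 1e-8
    maxiter: int = 500
    n_min: int = 20
    n_starts: int = 3  # extra perturbed starts tried on failure
    hessian_rel_step: float = 1e-4


def _as_clean_vectors(*arrays):
    out = [np.asarray(a, dtype=float).ravel() for a in arrays]
    n = {a.size for a in out}
    if len(n) != 1:
        raise ValueError("input vectors must have equal length")
    return out


def joint_neg_loglik(margins: MarginParams, copula: CopulaParams,
                     sbp_adj, ge_adj, dosage) -> float:
    """Negative log-likelihood of the joint copula model.

    Each individual contributes ``log c(F1(y1), F2(y2)) + log f1(y1) +
    log f2(y2)`` where f1/f2 and F1/F2 are the Gaussian margin densities and
    CDFs under the two regressions.
    """
    y1, y2, g = _as_clean_vectors(sbp_adj, ge_adj, dosage)
    return _neg_loglik_arrays(
        margins.alpha0, margins.alpha1, margins.sigma1,
        margins.beta0, margins.beta1, margins.sigma2,
        copula.phi, copula.theta, copula.rotation, y1, y2, g,
    )


def _neg_loglik_arrays(a0, a1, s1, b0, b1, s2, phi, theta, rotation, y1, y2, g):
    z1 = (y1 - a0 - a1 * g) / s1
    z2 = (y2 - b0 - b1 * g) / s2
    log_f1 = -0.5 * (z1 * z1 + _LOG_2PI) - math.log(s1)
    log_f2 = -0.5 * (z2 * z2 + _LOG_2PI) - math.log(s2)
    u1 = ndtr(z1)
    u2 = ndtr(z2)
    log_c = bb1_log_pdf(u1, u2, CopulaParams(phi=phi, theta=theta, rotation=rotation))
    total = np.sum(log_c + log_f1 + log_f2)
    if not np.isfinite(total):
        return 1e300
    return float(-total)


# ---------------------------------------------------------------------------
# transformed parametrization for the optimizer:
# z = (alpha0, alpha1, log s1, beta0, beta1, log s2, log phi, log(theta-1+eps))


def _pack(a0, a1, s1, b0, b1, s2, phi, theta):
    return np.array([a0, a1, math.log(s1), b0, b1, math.log(s2),
                     math.log(phi), math.log(theta - 1.0 + _THETA_EPS)])


def _unpack(z):
    return (z[0], z[1], math.exp(z[2]), z[3], z[4], math.exp(z[5]),
            math.exp(z[6]), math.exp(z[7]) + 1.0 - _THETA_EPS)


def _transformed_objective(z, rotation, y1, y2, g):
    a0, a1, s1, b0, b1, s2, phi, theta = _unpack(z)
    theta = max(theta, 1.0)
    return _neg_loglik_arrays(a0, a1, s1, b0, b1, s2, phi, theta, rotation, y1, y2, g)


def _ols_margin(y, g):
    gbar = g.mean()
    sxx = float(np.sum((g - gbar) ** 2))
    slope = float(np.sum((g - gbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * gbar)
    resid = y - intercept - slope * g
    sigma = float(np.sqrt(np.mean(resid**2)))
    return intercept, slope, max(sigma, 1e-12), resid


def _numeric_hessian(f, z, rel_step):
    """Central-difference Hessian of f at z."""
    k = z.size
    h = rel_step * np.maximum(np.abs(z), 1.0)
    H = np.empty((k, k))
    f0 = f(z)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        fpp = f(z + ei)
        fmm = f(z - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / (h[i] ** 2)
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            fa = f(z + ei + ej)
            fb = f(z + ei - ej)
            fc = f(z - ei + ej)
            fd = f(z - ei - ej)
            H[i, j] = H[j, i] = (fa - fb - fc + fd) / (4.0 * h[i] * h[j])
    return H


def _per_obs_scores(z, rotation, y1, y2, g, rel_step):
    """Per-observation score matrix by central differences (OPG fallback)."""
    k = z.size
    n = y1.size
    h = rel_step * np.maximum(np.abs(z), 1.0)

    def per_obs_nll(zz):
        a0, a1, s1, b0, b1, s2, phi, theta = _unpack(zz)
        theta = max(theta, 1.0)
        z1 = (y1 - a0 - a1 * g) / s1
        z2 = (y2 - b0 - b1 * g) / s2
        log_f1 = -0.5 * (z1 * z1 + _LOG_2PI) - math.log(s1)
        log_f2 = -0.5 * (z2 * z2 + _LOG_2PI) - math.log(s2)
        log_c = bb1_log_pdf(ndtr(z1), ndtr(z2),
                            CopulaParams(phi=phi, theta=theta, rotation=rotation))
        return -(log_c + log_f1 + log_f2)

    S = np.empty((n, k))
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        S[:, i] = (per_obs_nll(z + ei) - per_obs_nll(z - ei)) / (2.0 * h[i])
    return S


_Z_BOUNDS = [(None, None), (None, None), (-15.0, 15.0),
             (None, None), (None, None), (-15.0, 15.0),
             (math.log(PHI_MIN), math.log(PHI_MAX)),
             (math.log(_THETA_EPS), math.log(THETA_MAX - 1.0 + _THETA_EPS))]


def fit_joint_copula(sbp_adj, ge_adj, dosage, options: FitOptions | None = None) -> JointFit:
    """Joint maximum-likelihood fit of margins and copula for one pair.

    Strategy: OLS margin estimates and a tau-inverted copula start, rotation
    chosen by the sign of the residual Kendall's tau (90 vs 270 resolved by
    maximized log-likelihood), then bounded quasi-Newton (L-BFGS-B) over the
    transformed parameter vector.  Standard errors come from the inverse
    observed information (numerical Hessian in the transformed space, mapped
    to the natural scale by the delta method), with an outer-product-of-
    gradients fallback when the Hessian is not positive definite.
    """
    opts = options or FitOptions()
    y1, y2, g = _as_clean_vectors(sbp_adj, ge_adj, dosage)
    n = y1.size
    if n < opts.n_min:
        raise ValueError(f"need at least {opts.n_min} observations, got {n}")
    if np.unique(g).size < 2:
        raise ValueError("dosage is monomorphic in the analysis sample; "
                         "the variant effect is unidentifiable")

    a0, a1, s1, r1 = _ols_margin(y1, g)
    b0, b1, s2, r2 = _ols_margin(y2, g)
    tau_emp, _ = empirical_kendall_tau(r1, r2)
    start_cop = init_params_from_tau(np.clip(tau_emp, -0.95, 0.95))
    rotations = [0] if tau_emp >= 0 else [90, 270]
    # keep the theta start strictly inside the box: at theta == 1 the
    # log(theta-1) coordinate has a vanishing gradient and the optimizer
    # could never leave the Clayton slice
    theta_start = max(start_cop.theta, 1.05)
    phi_start = start_cop.phi
    if theta_start > start_cop.theta:
        a = abs(np.clip(tau_emp, -0.95, 0.95))
        phi_start = min(max(2.0 / (theta_start * (1.0 - a)) - 2.0, PHI_MIN), PHI_MAX)
    z0 = _pack(a0, a1, s1, b0, b1, s2, phi_start, theta_start)

    rng = np.random.default_rng(0)
    best = None
    for rot in rotations:
        starts = [z0]
        result = None
        for attempt in range(1 + opts.n_starts):
            zs = starts[0] if attempt == 0 else z0 + rng.normal(0.0, 0.1, size=8)
            res = optimize.minimize(
                _transformed_objective, zs, args=(rot, y1, y2, g),
                method="L-BFGS-B", bounds=_Z_BOUNDS,
                options={"maxiter": opts.maxiter, "ftol": opts.tol},
            )
            if res.success and np.isfinite(res.fun):
                result = res
                break
            if result is None or (np.isfinite(res.fun) and res.fun < result.fun):
                result = res
        if best is None or result.fun < best[0].fun:
            best = (result, rot)

    res, rot = best
    a0, a1, s1, b0, b1, s2, phi, theta = _unpack(res.x)
    theta = max(theta, 1.0)
    margins = MarginParams(a0, a1, s1, b0, b1, s2)
    copula = CopulaParams(phi=phi, theta=theta, rotation=rot)
    loglik = -float(res.fun)
    k = 8
    converged = bool(res.success)
    boundary = bool(
        phi <= PHI_MIN * (1 + 1e-6) or phi >= PHI_MAX * (1 - 1e-6)
        or theta <= 1.0 + 10 * _THETA_EPS or theta >= THETA_MAX * (1 - 1e-6)
    )

    # covariance in transformed space, then natural scale via the Jacobian of
    # z -> natural (diagonal: 1 for location/slope params, param value for the
    # log-transformed ones)
    cov_method = "hessian"
    H = _numeric_hessian(lambda z: _transformed_objective(z, rot, y1, y2, g),
                         res.x, opts.hessian_rel_step)
    cov_z = None
    try:
        L = np.linalg.cholesky(H)
        cov_z = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        S = _per_obs_scores(res.x, rot, y1, y2, g, opts.hessian_rel_step)
        G = S.T @ S
        try:
            cov_z = np.linalg.inv(G)
            cov_method = "opg"
        except np.linalg.LinAlgError:
            cov_z = np.linalg.pinv(H)
            cov_method = "pinv"
    jac = np.array([1.0, 1.0, s1, 1.0, 1.0, s2, phi, theta - 1.0 + _THETA_EPS])
    cov = cov_z * np.outer(jac, jac)

    se_a1 = float(np.sqrt(max(cov[1, 1], 0.0)))
    se_b1 = float(np.sqrt(max(cov[4, 4], 0.0)))
    if converged and se_a1 > 0 and se_b1 > 0:
        wald_a = wald_test(a1, se_a1)
        wald_b = wald_test(b1, se_b1)
    else:
        wald_a = (math.nan, math.nan)
        wald_b = (math.nan, math.nan)
        converged = False

    return JointFit(
        margins=margins, copula=copula, loglik=loglik,
        aic=model_aic(loglik, k), covariance=cov,
        wald_alpha1=wald_a, wald_beta1=wald_b,
        model_tau=model_kendall_tau(copula), converged=converged,
        n_used=n, boundary=boundary, cov_method=cov_method,
    )


def wald_test(estimate: float, se: float, df: int | None = None) -> tuple[float, float]:
    """Two-sided Wald test of a zero null.

    ``df=None`` refers the statistic ``estimate/se`` to the standard normal
    (the large-sample reference used for the copula-model tests); an integer
    ``df`` uses Student's t (the exact OLS reference).
    """
    if not np.isfinite(se) or se <= 0:
        raise ValueError(f"se must be positive, got {se!r}")
    stat = float(estimate) / float(se)
    if df is None:
        p = 2.0 * float(ndtr(-abs(stat)))
    else:
        p = 2.0 * float(stats.t.sf(abs(stat), df))
    return stat, min(p, 1.0)


def fit_univariate(y, dosage) -> UnivariateFit:
    """Closed-form simple linear regression of a phenotype on dosage.

    Slope inference uses the exact t(n-2) reference.  A perfect fit (zero
    residual variance) is flagged degenerate with se = 0.
    """
    y, g = _as_clean_vectors(y, dosage)
    if np.unique(g).size < 2:
        raise ValueError("dosage is monomorphic; slope is unidentifiable")
    n = y.size
    intercept, slope, sigma_mle, resid = _ols_margin(y, g)
    rss = float(np.sum(resid**2))
    sxx = float(np.sum((g - g.mean()) ** 2))
    df = n - 2
    s2 = rss / df if df > 0 else 0.0
    se = math.sqrt(s2 / sxx)
    loglik = -0.5 * n * (_LOG_2PI + 1.0) - n * math.log(max(sigma_mle, 1e-300))
    if se == 0.0:
        return UnivariateFit(intercept, slope, 0.0, math.inf if slope != 0 else 0.0,
                             0.0 if slope != 0 else 1.0, df, sigma_mle, loglik,
                             degenerate=True)
    tstat = slope / se
    p = 2.0 * float(stats.t.sf(abs(tstat), df))
    return UnivariateFit(intercept, slope, se, tstat, min(p, 1.0), df,
                         sigma_mle, loglik)


def fit_reference_models(sbp_adj, ge_adj, dosage) -> ReferenceFits:
    """Working-independence and bivariate-normal reference fits.

    Both share the Gaussian margin regressions; with identical regressors in
    the two equations the bivariate-normal MLE of the coefficients equals the
    per-equation OLS estimates, with the residual moment matrix as the MLE of
    the error covariance.
    """
    y1, y2, g = _as_clean_vectors(sbp_adj, ge_adj, dosage)
    if np.unique(g).size < 2:
        raise ValueError("dosage is monomorphic; the model is unidentifiable")
    n = y1.size
    _, _, s1, r1 = _ols_margin(y1, g)
    _, _, s2, r2 = _ols_margin(y2, g)
    rho = float(np.mean(r1 * r2) / (s1 * s2))
    rho = float(np.clip(rho, -1.0 + 1e-12, 1.0 - 1e-12))
    ll_indep = (-0.5 * n * (_LOG_2PI + 1.0) - n * math.log(s1)
                - 0.5 * n * (_LOG_2PI + 1.0) - n * math.log(s2))
    # at the MLE the Mahalanobis sum collapses to n
    ll_bvn = (-n * _LOG_2PI - n * math.log(s1) - n * math.log(s2)
              - 0.5 * n * math.log1p(-rho * rho) - n)
    return ReferenceFits(
        independence_loglik=ll_indep, independence_aic=model_aic(ll_indep, 6),
        bvn_loglik=ll_bvn, bvn_aic=model_aic(ll_bvn, 7), rho=rho,
    )


def model_aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2*loglik."""
    if k < 1:
        raise ValueError("k must be at least 1")
    return 2.0 * k - 2.0 * loglik


def empirical_kendall_tau(x, y) -> tuple[float, float]:
    """Tie-corrected (tau-b) Kendall concordance with its large-sample test."""
    x, y = _as_clean_vectors(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Kendall's tau is undefined for a constant vector")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)
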