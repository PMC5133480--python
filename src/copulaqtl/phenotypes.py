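"""Phenotype definition: medication adjustment of SBP and expression residuals.

Antihypertensive treatment lowers the observed systolic blood pressure, so a
treated individual's measurement is only a lower bound on the underlying
("true") SBP — a right-censored observation.  The adjustment proceeds in two
steps:

1. Fit a right-censored Gaussian (Tobit-type) regression of observed SBP on
   age, sex and smoking, with the medication flag as the censoring
   indicator.  Untreated individuals contribute the normal density at the
   observed value; treated individuals contribute the survival probability
   P(true SBP > observed | covariates).
2. Define adjusted SBP as a residual: observed minus fitted for the
   untreated; for the treated, the conditional expectation of true SBP given
   that it exceeds the observed value (truncated-normal mean, inverse Mills
   ratio) minus the fitted value.

Expression traits are adjusted by ordinary least squares on age, sex,
smoking and medication; the residuals are the adjusted expression
phenotypes.  Samples missing any of SBP, expression or covariates are
dropped (complete-case construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, ndtr

__all__ = [
    "CovariateRecord",
    "TobitFit",
    "AdjustedPhenotypes",
    "fit_censored_regression",
    "expected_true_sbp",
    "adjust_sbp",
    "adjust_expression",
    "adjust_study",
    "records_to_design",
    "load_phenotypes",
    "load_expression",
]

_LOG_2PI = np.log(2.0 * np.pi)

# covariates entering the SBP censored regression, in design-matrix order
SBP_COVARIATES = ("age", "sex", "smoking")
# the expression regressions additionally include the medication flag
GE_COVARIATES = ("age", "sex", "smoking", "medication")


@dataclass(frozen=True)
class CovariateRecord:
    """Non-genetic covariates for one sample; 0/1 codings documented in README."""

    sample_id: str
    age: float
    sex: int
    smoking: int
    medication: int

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age!r}")
        for name in ("sex", "smoking", "medication"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")


@dataclass
class TobitFit:
    """Right-censored Gaussian regression fit (coefficients on the mmHg scale)."""

    coefficients: np.ndarray
    sigma: float
    loglik: float
    converged: bool
    se: np.ndarray | None = None

    def predict(self, design) -> np.ndarray:
        return np.asarray(design, dtype=float) @ self.coefficients


@dataclass
class AdjustedPhenotypes:
    """Row-aligned adjusted SBP and expression residuals for the analysis sample."""

    sbp_adj: np.ndarray
    ge_adj: pd.DataFrame
    sample_ids: list[str]
    tobit: TobitFit | None = None

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sbp_adj) or len(self.sample_ids) != len(self.ge_adj):
            raise ValueError("sbp_adj, ge_adj and sample_ids must be row-aligned")


def records_to_design(records, covariates=SBP_COVARIATES) -> np.ndarray:
    """Intercept-first design matrix from CovariateRecord objects or a DataFrame."""
    if isinstance(records, pd.DataFrame):
        cols = [np.asarray(records[c], dtype=float) for c in covariates]
    else:
        cols = [np.array([getattr(r, c) for r in records], dtype=float) for c in covariates]
    n = len(cols[0])
    return np.column_stack([np.ones(n)] + cols)


def _tobit_negloglik_grad(params, X, y, treated):
    beta = params[:-1]
    log_sigma = params[-1]
    sigma = np.exp(log_sigma)
    r = y - X @ beta
    z = r / sigma
    unc = ~treated

    nll = 0.0
    grad_beta = np.zeros(X.shape[1])
    grad_ls = 0.0
    if unc.any():
        zu = z[unc]
        nll += float(np.sum(0.5 * zu * zu + log_sigma + 0.5 * _LOG_2PI))
        grad_beta -= (X[unc].T @ zu) / sigma
        grad_ls += float(np.sum(1.0 - zu * zu))
    if treated.any():
        # observed is a lower bound: contribution P(true > obs) = Phi(-z) = sf(z)
        # with z = (obs - x*beta)/sigma
        zt = -z[treated]  # sf(z) = ndtr(-z)
        nll -= float(np.sum(log_ndtr(zt)))
        mills = np.exp(_norm_logpdf(zt) - log_ndtr(zt))  # phi(z)/sf(z)
        grad_beta -= (X[treated].T @ mills) / sigma
        grad_ls -= float(np.sum(mills * z[treated]))
    grad = np.append(grad_beta, grad_ls)
    return nll, grad


def _norm_logpdf(z):
    return -0.5 * (z * z + _LOG_2PI)


def fit_censored_regression(design, sbp_observed, treated) -> TobitFit:
    """MLE of the right-censored Gaussian regression of SBP on covariates.

    Parameters
    ----------
    design : (n, p) array
        Covariate matrix including the intercept column.
    sbp_observed : (n,) array
        Observed SBP in mmHg.
    treated : (n,) 0/1 array
        Medication flag; treated observations are right-censored.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(sbp_observed, dtype=float).ravel()
    t = np.asarray(treated).astype(bool).ravel()
    if X.shape[0] != y.size or y.size != t.size:
        raise ValueError("design, sbp_observed and treated must be row-aligned")
    if t.all():
        raise ValueError("all observations are censored (treated); "
                         "sigma is not identifiable")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    start = np.append(beta0, np.log(max(resid.std(), 1e-6)))
    res = optimize.minimize(
        _tobit_negloglik_grad, start, args=(X, y, t),
        jac=True, method="BFGS", options={"maxiter": 500, "gtol": 1e-8},
    )
    # Newton polish on the analytic gradient: quasi-Newton alone stalls short
    # of the tight first-order condition on poorly scaled covariates
    params = res.x
    nll, grad = _tobit_negloglik_grad(params, X, y, t)
    cov = None
    for _ in range(25):
        H = _numeric_jacobian(lambda p: _tobit_negloglik_grad(p, X, y, t)[1], params)
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H, grad)
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            break
        new = params - step
        new_nll, new_grad = _tobit_negloglik_grad(new, X, y, t)
        if not np.isfinite(new_nll) or new_nll > nll + 1e-9 * (1 + abs(nll)):
            break
        params, nll, grad = new, new_nll, new_grad
        if np.max(np.abs(grad)) < 1e-9:
            break
    beta = params[:-1]
    sigma = float(np.exp(params[-1]))
    converged = bool(np.max(np.abs(grad)) < 1e-6)
    se = None
    if cov is not None:
        se = np.sqrt(np.maximum(np.diag(cov)[:-1], 0.0))
    return TobitFit(coefficients=beta, sigma=sigma, loglik=-float(nll),
                    converged=converged, se=se)


def _numeric_jacobian(fun, x, rel_step=1e-6):
    x = np.asarray(x, dtype=float)
    f0 = fun(x)
    J = np.empty((f0.size, x.size))
    for j in range(x.size):
        h = rel_step * max(abs(x[j]), 1.0)
        xp = x.copy(); xp[j] += h
        xm = x.copy(); xm[j] -= h
        J[:, j] = (fun(xp) - fun(xm)) / (2.0 * h)
    return J


def _inverse_mills(z):
    """phi(z) / (1 - Phi(z)), evaluated stably through log space."""
    z = np.asarray(z, dtype=float)
    out = np.exp(_norm_logpdf(z) - log_ndtr(-z))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            f"inverse Mills ratio overflowed at z={z[~np.isfinite(out)][:5]!r}"
        )
    return out


def expected_true_sbp(fit: TobitFit, record, sbp_observed: float) -> float:
    """E[true SBP | true SBP > observed, covariates] for a treated individual.

    Truncated-normal mean: x*beta + sigma * phi(z)/(1 - Phi(z)) with
    z = (observed - x*beta)/sigma.  Always exceeds the observed value.
    """
    if isinstance(record, CovariateRecord):
        x = np.array([1.0, record.age, record.sex, record.smoking])
    else:
        x = np.asarray(record, dtype=float)
    xb = float(x @ fit.coefficients)
    z = (float(sbp_observed) - xb) / fit.sigma
    return xb + fit.sigma * float(_inverse_mills(z))


def adjust_sbp(fit: TobitFit, design, sbp_observed, treated) -> np.ndarray:
    """Adjusted SBP residuals.

    Untreated: observed - fitted.  Treated: expected true SBP - fitted,
    which equals sigma * phi(z)/(1 - Phi(z)) and is strictly positive.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(sbp_observed, dtype=float).ravel()
    t = np.asarray(treated).astype(bool).ravel()
    if X.shape[0] != y.size or y.size != t.size:
        raise ValueError("design, sbp_observed and treated must be row-aligned")
    xb = X @ fit.coefficients
    resid = y - xb
    if t.any():
        z = (y[t] - xb[t]) / fit.sigma
        resid = resid.copy()
        resid[t] = fit.sigma * _inverse_mills(z)
    return resid


def adjust_expression(ge_matrix, covariates) -> np.ndarray:
    """Per-transcript OLS residuals of expression on the covariate design.

    ``covariates`` must include the intercept column; residuals are
    orthogonal to every covariate column and have mean zero.
    """
    Y = np.asarray(ge_matrix, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("expression matrix and covariates must be row-aligned")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank deficient")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ coef


def drop_constant_columns(design: np.ndarray) -> np.ndarray:
    """Drop non-intercept columns with zero variance (e.g. nobody treated)."""
    X = np.asarray(design, dtype=float)
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    return X[:, keep]


def load_phenotypes(path) -> pd.DataFrame:
    """Phenotype/covariate TSV: sample_id, sbp, medication, age, sex, smoking."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "sbp", "medication", "age", "sex", "smoking"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table is missing columns: {sorted(missing)}")
    return df


def load_expression(path) -> pd.DataFrame:
    """Expression TSV (first column sample_id, remaining columns transcripts)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if df.columns[0] != "sample_id":
        raise ValueError("expression table must have sample_id as its first column")
    return df.set_index("sample_id")


def adjust_study(pheno: pd.DataFrame, expression: pd.DataFrame) -> AdjustedPhenotypes:
    """Run the full preparatory adjustment on aligned tables.

    Complete cases are taken across SBP, covariates and all transcripts; the
    censored regression uses age/sex/smoking with medication as the censoring
    indicator, and each transcript is residualized on age/sex/smoking/
    medication.
    """
    pheno = pheno.set_index("sample_id") if "sample_id" in pheno.columns else pheno
    common = pheno.index.intersection(expression.index)
    pheno = pheno.loc[common]
    expression = expression.loc[common]
    keep = pheno[["sbp", "age", "sex", "smoking", "medication"]].notna().all(axis=1)
    keep &= expression.notna().all(axis=1)
    pheno = pheno.loc[keep]
    expression = expression.loc[keep]
    if len(pheno) == 0:
        raise ValueError("no complete cases after alignment")

    X_sbp = records_to_design(pheno, SBP_COVARIATES)
    treated = pheno["medication"].to_numpy()
    fit = fit_censored_regression(X_sbp, pheno["sbp"].to_numpy(), treated)
    sbp_adj = adjust_sbp(fit, X_sbp, pheno["sbp"].to_numpy(), treated)

    X_ge = drop_constant_columns(records_to_design(pheno, GE_COVARIATES))
    ge_adj = adjust_expression(expression.to_numpy(), X_ge)
    ge_adj = pd.DataFrame(ge_adj, index=expression.index, columns=expression.columns)
    return AdjustedPhenotypes(sbp_adj=sbp_adj, ge_adj=ge_adj,
                              sample_ids=list(pheno.index), tobit=fit)
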