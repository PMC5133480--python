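"""Two-parameter Archimedean (BB1) copula family.

The family

    C(u1, u2) = { [ (u1^-phi - 1)^theta + (u2^-phi - 1)^theta ]^(1/theta) + 1 }^(-1/phi)

with phi > 0 and theta >= 1 interpolates between the Clayton copula
(theta = 1) and the Gumbel-Hougaard copula (phi -> 0), and exhibits both
lower- and upper-tail dependence.  It only models positive association;
negative association is obtained by composing with reflections of one or
both arguments ("rotations" by 90, 180 or 270 degrees).

Everything is evaluated in log space: the Archimedean generator
g(t) = (t^-phi - 1)^theta overflows double precision long before the
parameter box (phi, theta <= 50) is exhausted, while its logarithm stays
modest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CopulaParams",
    "bb1_cdf",
    "bb1_log_pdf",
    "apply_rotation",
    "conditional_cdf",
    "model_kendall_tau",
    "tail_dependence",
    "init_params_from_tau",
    "PHI_MIN",
    "PHI_MAX",
    "THETA_MIN",
    "THETA_MAX",
    "U_CLAMP",
]

# Optimization box for the dependence parameters: covers |tau| up to ~0.99
# while keeping the theta-power terms representable in log space.
PHI_MIN = 1e-4
PHI_MAX = 50.0
THETA_MIN = 1.0
THETA_MAX = 50.0

# Pseudo-observations are clamped into [U_CLAMP, 1 - U_CLAMP] before density
# evaluation; residual-based inputs can hit the boundary.
U_CLAMP = 1e-10

VALID_ROTATIONS = (0, 90, 180, 270)


@dataclass(frozen=True)
class CopulaParams:
    """Dependence parameters (phi, theta) plus a rotation tag.

    Parameters
    ----------
    phi : float
        First dependence parameter, ``phi > 0``.  Controls lower-tail
        dependence; the Clayton parameter when ``theta == 1``.
    theta : float
        Second dependence parameter, ``theta >= 1``.  Controls upper-tail
        dependence; the Gumbel-Hougaard parameter as ``phi -> 0``.
    rotation : int
        0, 90, 180 or 270 degrees.  90/270 flip the sign of the implied
        Kendall's tau (negative dependence); 180 is the survival copula.
    """

    phi: float
    theta: float
    rotation: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.phi) or self.phi <= 0:
            raise ValueError(f"phi must be a positive real, got {self.phi!r}")
        if not np.isfinite(self.theta) or self.theta < 1:
            raise ValueError(f"theta must be >= 1, got {self.theta!r}")
        if self.rotation not in VALID_ROTATIONS:
            raise ValueError(
                f"rotation must be one of {VALID_ROTATIONS}, got {self.rotation!r}"
            )


def _log_expm1(z):
    """log(exp(z) - 1) for z > 0, stable for both tiny and huge z."""
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        small = np.log(np.expm1(np.minimum(z, 30.0)))
        large = z + np.log1p(-np.exp(-np.maximum(z, 30.0)))
    return np.where(z < 30.0, small, large)


def _check_unit_interval(u, name):
    u = np.asarray(u, dtype=float)
    if np.any(np.isnan(u)) or np.any(u < 0) or np.any(u > 1):
        raise ValueError(f"{name} must lie in [0, 1]")
    return u


def _log_generator_pieces(u1, u2, phi, theta):
    """Shared log-space quantities: lx, ly, ls = log(g(u)+g(v)), lw, log(1+w)."""
    lu1 = np.log(u1)
    lu2 = np.log(u2)
    lx = theta * _log_expm1(-phi * lu1)
    ly = theta * _log_expm1(-phi * lu2)
    ls = np.logaddexp(lx, ly)
    lw = ls / theta
    l1pw = np.logaddexp(0.0, lw)
    return lu1, lu2, lx, ly, ls, lw, l1pw


def _base_log_cdf(u1, u2, phi, theta):
    *_, l1pw = _log_generator_pieces(u1, u2, phi, theta)
    return -l1pw / phi


def _base_cdf(u1, u2, phi, theta):
    # grounded boundary C(0, .) = C(., 0) = 0 handled outside the log path
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    interior = (u1 > 0) & (u2 > 0)
    a = np.where(interior, u1, 0.5)
    b = np.where(interior, u2, 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.exp(_base_log_cdf(a, b, phi, theta))
    return np.where(interior, val, 0.0)


def apply_rotation(u1, u2, rotation):
    """Reflect a point of the unit square according to the rotation tag.

    0 -> (u1, u2); 90 -> (u1, 1-u2); 180 -> (1-u1, 1-u2); 270 -> (1-u1, u2).
    Applied to samples of the base copula this yields samples of the rotated
    copula; 90/270 flip the sign of Kendall's tau, 0/180 preserve it.
    """
    if rotation not in VALID_ROTATIONS:
        raise ValueError(f"rotation must be one of {VALID_ROTATIONS}, got {rotation!r}")
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if rotation == 0:
        return u1, u2
    if rotation == 90:
        return u1, 1.0 - u2
    if rotation == 180:
        return 1.0 - u1, 1.0 - u2
    return 1.0 - u1, u2


def bb1_cdf(u1, u2, params: CopulaParams):
    """Copula CDF C(u1, u2), rotation applied.

    Vectorized over ``u1``/``u2``.  Satisfies the copula boundary conditions
    C(u, 0) = 0, C(u, 1) = u and is 2-increasing.
    """
    u1 = _check_unit_interval(u1, "u1")
    u2 = _check_unit_interval(u2, "u2")
    phi, theta, rot = params.phi, params.theta, params.rotation
    if rot == 0:
        out = _base_cdf(u1, u2, phi, theta)
    elif rot == 90:
        out = u1 - _base_cdf(u1, 1.0 - u2, phi, theta)
    elif rot == 180:
        out = u1 + u2 - 1.0 + _base_cdf(1.0 - u1, 1.0 - u2, phi, theta)
    else:  # 270
        out = u2 - _base_cdf(1.0 - u1, u2, phi, theta)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _base_log_pdf(u1, u2, phi, theta):
    """Log density of the unrotated copula, analytic mixed partial of the CDF.

    With g(t) = (t^-phi - 1)^theta, x = g(u1), y = g(u2), s = x + y and
    w = s^(1/theta):

        c = phi*theta * (u1*u2)^(-phi-1) * (x*y)^(1-1/theta)
            * s^(1/theta - 2) * (1+w)^(-1/phi - 2)
            * [ (1 - 1/theta)(1+w) + (1/theta)(1 + 1/phi) w ]
    """
    lu1, lu2, lx, ly, ls, lw, l1pw = _log_generator_pieces(u1, u2, phi, theta)
    with np.errstate(divide="ignore"):
        log_bracket = np.logaddexp(
            np.log1p(-1.0 / theta) + l1pw if theta > 1 else -np.inf + 0.0 * l1pw,
            -np.log(theta) + np.log1p(1.0 / phi) + lw,
        )
    return (
        np.log(phi)
        + np.log(theta)
        + (-phi - 1.0) * (lu1 + lu2)
        + (1.0 - 1.0 / theta) * (lx + ly)
        + (1.0 / theta - 2.0) * ls
        + (-1.0 / phi - 2.0) * l1pw
        + log_bracket
    )


def bb1_log_pdf(u1, u2, params: CopulaParams):
    """Log copula density, rotation applied.

    Inputs are clamped into ``[U_CLAMP, 1 - U_CLAMP]``; values outside
    ``[0, 1]`` raise.  The returned value is always finite.
    """
    u1 = _check_unit_interval(u1, "u1")
    u2 = _check_unit_interval(u2, "u2")
    a = np.clip(u1, U_CLAMP, 1.0 - U_CLAMP)
    b = np.clip(u2, U_CLAMP, 1.0 - U_CLAMP)
    a, b = apply_rotation(a, b, params.rotation)
    out = _base_log_pdf(a, b, params.phi, params.theta)
    return float(out) if np.ndim(out) == 0 else out


def _base_conditional_cdf(v, u, phi, theta):
    """h(v | u) = dC/du of the unrotated copula: P(U2 <= v | U1 = u)."""
    lu, _, lx, _, ls, lw, l1pw = _log_generator_pieces(u, v, phi, theta)
    log_h = (
        (-phi - 1.0) * lu
        + (1.0 - 1.0 / theta) * lx
        + (1.0 / theta - 1.0) * ls
        + (-1.0 / phi - 1.0) * l1pw
    )
    return np.exp(log_h)


def conditional_cdf(u1, u2, params: CopulaParams):
    """P(U2 <= u2 | U1 = u1) under the rotated copula."""
    u1 = np.clip(np.asarray(u1, dtype=float), U_CLAMP, 1.0 - U_CLAMP)
    u2 = np.clip(np.asarray(u2, dtype=float), U_CLAMP, 1.0 - U_CLAMP)
    phi, theta, rot = params.phi, params.theta, params.rotation
    if rot == 0:
        out = _base_conditional_cdf(u2, u1, phi, theta)
    elif rot == 90:
        out = 1.0 - _base_conditional_cdf(1.0 - u2, u1, phi, theta)
    elif rot == 180:
        out = 1.0 - _base_conditional_cdf(1.0 - u2, 1.0 - u1, phi, theta)
    else:  # 270
        out = _base_conditional_cdf(u2, 1.0 - u1, phi, theta)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def model_kendall_tau(params: CopulaParams) -> float:
    """Model-implied (signed) Kendall's tau.

    For the unrotated family tau = 1 - 2 / (theta * (phi + 2)); this reduces
    to the Clayton form phi/(phi+2) at theta=1 and to the Gumbel-Hougaard
    form 1 - 1/theta as phi -> 0.  Rotations 90/270 negate the value.
    """
    tau = 1.0 - 2.0 / (params.theta * (params.phi + 2.0))
    if params.rotation in (90, 270):
        return -tau
    return tau


def tail_dependence(params: CopulaParams) -> tuple[float, float]:
    """(lower, upper) tail-dependence coefficients of the unrotated family.

    lambda_L = 2^(-1/(theta*phi)), lambda_U = 2 - 2^(1/theta).  Rotated
    parameters are rejected: the coefficients refer to the base copula.
    """
    if params.rotation != 0:
        raise ValueError("tail dependence is reported for the unrotated base copula only")
    lower = 2.0 ** (-1.0 / (params.theta * params.phi))
    upper = 2.0 - 2.0 ** (1.0 / params.theta)
    return float(lower), float(upper)


def init_params_from_tau(tau: float) -> CopulaParams:
    """Starting parameters whose model tau matches a target Kendall's tau.

    Uses the Clayton slice (theta = 1, phi = 2|tau|/(1-|tau|)), which inverts
    tau exactly for |tau| <= 0.95; beyond that theta takes over at phi = 1.
    Negative targets select rotation 90 (the fitting layer also tries 270).
    """
    if not np.isfinite(tau) or abs(tau) >= 1:
        raise ValueError(f"tau must lie strictly inside (-1, 1), got {tau!r}")
    a = abs(tau)
    rotation = 0 if tau >= 0 else 90
    if a < 5e-3:
        return CopulaParams(phi=0.01, theta=1.0, rotation=rotation)
    if a <= 0.95:
        phi = min(max(2.0 * a / (1.0 - a), PHI_MIN), PHI_MAX)
        return CopulaParams(phi=phi, theta=1.0, rotation=rotation)
    theta = min(2.0 / (3.0 * (1.0 - a)), THETA_MAX)
    return CopulaParams(phi=1.0, theta=theta, rotation=rotation)
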