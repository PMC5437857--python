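"""Long-term low-coral-cover risk and its parameter sensitivities.

For a coral-cover threshold kappa, q_{kappa,i} is the long-run
probability that site i has coral cover <= kappa (the proportion of
time spent at or below the threshold), computed under the site's
stationary distribution N(mu_i*, Sigma*) on the ilr scale.  For a
randomly-chosen site the relevant law is N(mu*, Sigma* + Z*), giving
the regional probability q_kappa.

On the ilr plane the event {coral <= kappa} is the half-plane-like
region {y1 >= g(y2)} above the coral iso-cover curve g (see
:func:`reefvar.compositions.coral_isoline`), so after conditioning on
y2 the probability reduces to a smooth 1-D integral

    q = E_{y2} [ 1 - Phi( (g(y2) - m(y2)) / s ) ],

evaluated with fixed-order Gauss-Legendre quadrature.

Sensitivities of q_kappa to the 12 structural parameters (four elements
of B, two of a, and the lower triangles of Sigma and Z) are computed by
central finite differences of the deterministic quadrature, with a
half-step Richardson consistency check; elasticities rescale the
derivatives to relative changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .compositions import coral_isoline
from .process_model import ModelParams, SiteEffect, eigen_diagnostics
from .stationary import among_site_cov, stationary_mean, within_site_cov

__all__ = [
    "RiskResult",
    "SensitivityVector",
    "PARAM_NAMES",
    "prob_low_coral",
    "site_risk",
    "regional_risk",
    "risk_gradient",
    "risk_elasticity",
]

#: The 12 structural parameters q_kappa depends on, in reporting order.
PARAM_NAMES = (
    "b11", "b21", "b12", "b22",
    "a1", "a2",
    "sigma11", "sigma21", "sigma22",
    "zeta11", "zeta21", "zeta22",
)

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(200)
_RANGE_SD = 10.0


@dataclass(frozen=True)
class RiskResult:
    """Probability of coral cover <= kappa for one site or the region."""

    kappa: float
    q: float
    site: str = "regional"


@dataclass(frozen=True)
class SensitivityVector:
    """Derivatives (or elasticities) of q_kappa per structural parameter."""

    values: dict

    def __post_init__(self) -> None:
        if tuple(self.values) != PARAM_NAMES:
            raise ValueError("sensitivity vector must carry exactly the 12 named entries")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in PARAM_NAMES])

    def ranked(self) -> list:
        """Parameter names sorted by descending |value|."""
        return sorted(PARAM_NAMES, key=lambda k: -abs(self.values[k]))


def prob_low_coral(mu: np.ndarray, cov: np.ndarray, kappa: float) -> float:
    """P(coral <= kappa) under a bivariate normal on the ilr scale.

    ``mu`` may be of shape (2,) or (n, 2); a matching scalar or length-n
    array is returned.  Absolute quadrature accuracy is ~1e-6 or better
    (200-node Gauss-Legendre over mu2 +/- 10 SD; the integrand is smooth).
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    cov = np.asarray(cov, dtype=float).reshape(2, 2)
    if not (0.0 < kappa < 1.0):
        raise ValueError("kappa must lie in (0, 1)")
    var2 = cov[1, 1]
    if cov[0, 0] <= 0.0 or var2 <= 0.0 or np.linalg.det(cov) <= 0.0:
        raise ValueError("covariance must be positive definite")
    sd2 = np.sqrt(var2)
    slope = cov[0, 1] / var2
    cond_sd = np.sqrt(cov[0, 0] - cov[0, 1] ** 2 / var2)

    # nodes in y2, one row per mu
    half = _RANGE_SD * sd2
    y2 = mu[:, 1:2] + half * _GL_NODES[None, :]
    w = (half * _GL_WEIGHTS)[None, :] * stats.norm.pdf(y2, loc=mu[:, 1:2], scale=sd2)
    g = coral_isoline(kappa, y2)
    cond_mean = mu[:, 0:1] + slope * (y2 - mu[:, 1:2])
    tail = stats.norm.sf((g - cond_mean) / cond_sd)
    q = np.clip((w * tail).sum(axis=1), 0.0, 1.0)
    return q if q.size > 1 else float(q[0])


def site_risk(params: ModelParams, alpha: SiteEffect, kappa: float, site: str = "site") -> RiskResult:
    """Long-term P(coral <= kappa) for a fixed site: N(mu_i*, Sigma*)."""
    mu_i = stationary_mean(params.a, params.B, alpha.alpha)
    sigma_star = within_site_cov(params.B, params.Sigma)
    return RiskResult(kappa=kappa, q=float(prob_low_coral(mu_i, sigma_star, kappa)), site=site)


def regional_risk(params: ModelParams, kappa: float) -> RiskResult:
    """Long-term P(coral <= kappa) for a randomly-chosen site:
    N(mu*, Sigma* + Z*)."""
    mu = stationary_mean(params.a, params.B)
    total = within_site_cov(params.B, params.Sigma) + among_site_cov(params.B, params.Z)
    return RiskResult(kappa=kappa, q=float(prob_low_coral(mu, total, kappa)))


def _pack(params: ModelParams) -> np.ndarray:
    B, a, S, Z = params.B, params.a, params.Sigma, params.Z
    return np.array([
        B[0, 0], B[1, 0], B[0, 1], B[1, 1],
        a[0], a[1],
        S[0, 0], S[1, 0], S[1, 1],
        Z[0, 0], Z[1, 0], Z[1, 1],
    ])


def _q_of_theta(theta: np.ndarray, H: np.ndarray, nu: float, kappa: float) -> float:
    B = np.array([[theta[0], theta[2]], [theta[1], theta[3]]])
    a = theta[4:6]
    S = np.array([[theta[6], theta[7]], [theta[7], theta[8]]])
    Z = np.array([[theta[9], theta[10]], [theta[10], theta[11]]])
    p = ModelParams(a=a, B=B, Sigma=S, Z=Z, H=H, nu=nu)
    if not eigen_diagnostics(p.B)["stationary"]:
        raise ValueError("perturbed B non-stationary")
    return regional_risk(p, kappa).q


def _central_diff(theta: np.ndarray, i: int, h: float, H, nu, kappa) -> float:
    up, dn = theta.copy(), theta.copy()
    up[i] += h
    dn[i] -= h
    return (_q_of_theta(up, H, nu, kappa) - _q_of_theta(dn, H, nu, kappa)) / (2.0 * h)


def risk_gradient(
    params: ModelParams,
    kappa: float,
    step: float = 1e-4,
    richardson_rtol: float = 1e-4,
) -> SensitivityVector:
    """Gradient of the regional q_kappa in the 12 structural parameters.

    Central differences on the quadrature-based q; symmetric matrix
    entries (sigma21, zeta21) are perturbed in both off-diagonal
    positions at once.  Each derivative is recomputed at half step and
    the two Richardson-consistent estimates must agree to
    ``richardson_rtol`` relative (or 1e-10 absolute, for flat
    directions); the step is shrunk automatically if a perturbation
    breaks positive-definiteness or stationarity.
    """
    if step <= 0.0:
        raise ValueError("step must be positive")
    theta0 = _pack(params)
    out = {}
    for i, name in enumerate(PARAM_NAMES):
        scale = max(abs(theta0[i]), 1.0)
        h = step * scale
        for _ in range(40):
            try:
                d_h = _central_diff(theta0, i, h, params.H, params.nu, kappa)
                d_h2 = _central_diff(theta0, i, h / 2.0, params.H, params.nu, kappa)
            except ValueError:
                h /= 2.0
                continue
            break
        else:
            raise ValueError(f"could not find a feasible step for {name}")
        # Richardson: the h/2 estimate is 4x more accurate; require consistency
        extrap = (4.0 * d_h2 - d_h) / 3.0
        denom = max(abs(extrap), 1e-10 / richardson_rtol)
        if abs(d_h2 - d_h) / denom > 3.0 * richardson_rtol:
            raise ValueError(f"finite-difference estimates for {name} did not converge")
        out[name] = float(extrap)
    return SensitivityVector(values=out)


def risk_elasticity(params: ModelParams, kappa: float, step: float = 1e-4) -> SensitivityVector:
    """Elasticities (p / q) dq/dp of the regional q_kappa.

    Undefined when q_kappa = 0; parameters equal to zero get elasticity 0
    (no relative change is possible at zero).
    """
    q = regional_risk(params, kappa).q
    if q <= 0.0:
        raise ValueError("elasticity undefined: q_kappa is zero")
    grad = risk_gradient(params, kappa, step=step)
    theta0 = _pack(params)
    vals = {
        name: float(theta0[i] / q * grad.values[name])
        for i, name in enumerate(PARAM_NAMES)
    }
    return SensitivityVector(values=vals)
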