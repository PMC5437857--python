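"""Closed-form long-run behaviour of the hierarchical VAR(1).

When both eigenvalues of B lie inside the unit circle the latent state
of a fixed site i converges to

    x_i* ~ N(mu_i*, Sigma*),      mu_i* = (I - B)^{-1} (a + alpha_i),

with Sigma* the solution of the discrete Lyapunov equation
Sigma* = B Sigma* B' + Sigma.  Over the population of sites
(alpha ~ N(0, Z)) the stationary means scatter with covariance
Z* = (I - B)^{-1} Z (I - B)^{-T}, and the state of a randomly-chosen
site is N(mu*, Sigma* + Z*).

Two scalar summaries quantify the structure of this distribution:

* rho = sqrt(|Sigma*| / |Sigma* + Z*|), the ratio of volumes of the
  ellipsoids of concentration with and without among-site variability
  (the fraction of total long-run dispersion that would remain were all
  among-site variability removed);
* the per-component snapshot correlations
  corr(x_k, mu_{i,k}*) = sqrt(z*_kk / (z*_kk + sigma*_kk)),
  between a single stationary observation of a random site and that
  site's own stationary mean — how informative one survey is about the
  site's long-term centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .process_model import ModelParams, eigen_diagnostics

__all__ = [
    "StationarySummary",
    "stationary_mean",
    "within_site_cov",
    "among_site_cov",
    "rho_statistic",
    "snapshot_correlation",
    "stationary_summary",
    "concentration_ellipse",
]

_LYAPUNOV_TOL = 1e-10


def _require_stationary(B: np.ndarray) -> np.ndarray:
    B = np.asarray(B, dtype=float).reshape(2, 2)
    if not eigen_diagnostics(B)["stationary"]:
        raise ValueError("no stationary distribution: eigenvalues of B not inside unit circle")
    return B


@dataclass(frozen=True)
class StationarySummary:
    """Regional stationary mean and the two covariance components."""

    mu_star: np.ndarray
    sigma_star: np.ndarray
    z_star: np.ndarray

    @property
    def total_cov(self) -> np.ndarray:
        return self.sigma_star + self.z_star

    @property
    def rho(self) -> float:
        return rho_statistic(self.sigma_star, self.z_star)

    @property
    def snapshot_corr(self) -> np.ndarray:
        return snapshot_correlation(self.sigma_star, self.z_star)


def stationary_mean(a: np.ndarray, B: np.ndarray, alpha: np.ndarray | None = None) -> np.ndarray:
    """mu_i* = (I - B)^{-1} (a + alpha); alpha omitted gives the regional mu*."""
    B = _require_stationary(B)
    drift = np.asarray(a, dtype=float).reshape(2)
    if alpha is not None:
        drift = drift + np.asarray(alpha, dtype=float).reshape(2)
    return np.linalg.solve(np.eye(2) - B, drift)


def within_site_cov(B: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Stationary within-site covariance: solve Sigma* = B Sigma* B' + Sigma."""
    B = _require_stationary(B)
    Sigma = np.asarray(Sigma, dtype=float).reshape(2, 2)
    out = linalg.solve_discrete_lyapunov(B, Sigma)
    out = 0.5 * (out + out.T)
    resid = np.linalg.norm(out - B @ out @ B.T - Sigma)
    if resid > _LYAPUNOV_TOL:
        raise ValueError(f"Lyapunov solve residual {resid:.2e} exceeds tolerance")
    return out


def among_site_cov(B: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Stationary among-site covariance Z* = (I-B)^{-1} Z (I-B)^{-T}.

    This is the covariance of mu_i* = (I-B)^{-1}(a + alpha_i) over
    alpha_i ~ N(0, Z).
    """
    B = _require_stationary(B)
    Z = np.asarray(Z, dtype=float).reshape(2, 2)
    m = np.linalg.inv(np.eye(2) - B)
    out = m @ Z @ m.T
    return 0.5 * (out + out.T)


def rho_statistic(sigma_star: np.ndarray, z_star: np.ndarray) -> float:
    """rho = sqrt(|Sigma*| / |Sigma* + Z*|), in (0, 1]."""
    s = np.asarray(sigma_star, dtype=float).reshape(2, 2)
    z = np.asarray(z_star, dtype=float).reshape(2, 2)
    det_s = np.linalg.det(s)
    det_t = np.linalg.det(s + z)
    if det_s <= 0.0 or det_t <= 0.0:
        raise ValueError("covariance blocks must be positive definite")
    return float(np.sqrt(det_s / det_t))


def snapshot_correlation(sigma_star: np.ndarray, z_star: np.ndarray) -> np.ndarray:
    """Per-component correlation between one stationary draw at a random
    site and that site's stationary mean: sqrt(z*_kk / (z*_kk + sigma*_kk)).

    Writing x = mu_i* + e with mu_i* ~ N(mu*, Z*) independent of
    e ~ N(0, Sigma*), cov(x_k, mu_{i,k}*) = z*_kk while
    var(x_k) = z*_kk + sigma*_kk, which gives the closed form.
    """
    s = np.asarray(sigma_star, dtype=float).reshape(2, 2)
    z = np.asarray(z_star, dtype=float).reshape(2, 2)
    return np.sqrt(np.diag(z) / (np.diag(z) + np.diag(s)))


def stationary_summary(params: ModelParams) -> StationarySummary:
    """All long-run summaries implied by a parameter set."""
    return StationarySummary(
        mu_star=stationary_mean(params.a, params.B),
        sigma_star=within_site_cov(params.B, params.Sigma),
        z_star=among_site_cov(params.B, params.Z),
    )


def concentration_ellipse(mu: np.ndarray, cov: np.ndarray, n_points: int = 200) -> np.ndarray:
    """Boundary of the unit ellipsoid of concentration of N(mu, cov).

    Returns an (n_points, 2) array tracing {mu + 2^{1/2}... } -- precisely
    the set x with (x - mu)' cov^{-1} (x - mu) = 4, the ellipse whose
    uniform interior has the same mean and covariance as the normal.
    Intended for external plotting (e.g. after back-transformation).
    """
    mu = np.asarray(mu, dtype=float).reshape(2)
    cov = np.asarray(cov, dtype=float).reshape(2, 2)
    chol = np.linalg.cholesky(cov)
    theta = np.linspace(0.0, 2.0 * np.pi, n_points)
    circle = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    return mu + 2.0 * circle @ chol.T
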