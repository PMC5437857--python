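"""Generative layers of the hierarchical VAR(1) state-space model.

The latent (true) ilr composition x_{i,t} of site i evolves as

    x_{i,t+1} = a + alpha_i + B x_{i,t} + eps_{i,t},   eps ~ N(0, Sigma)
    alpha_i ~ N(0, Z)

and each transect observation is a heavy-tailed draw about the latent
state,

    y_{i,j,t} ~ t2(x_{i,t}, H, nu),

a bivariate Student-t with location x, scale matrix H and nu degrees of
freedom (covariance nu H / (nu - 2) for nu > 2).  All quantities are
dimensionless (ilr coordinates of proportions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "SiteEffect",
    "LatentTrajectory",
    "simulate_latent",
    "observe_transects",
    "change_matrix",
    "eigen_diagnostics",
]


def _check_spd(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"{name} must be positive definite") from err
    return m


@dataclass(frozen=True)
class ModelParams:
    """Structural parameters (a, B, Sigma, Z) plus observation (H, nu)."""

    a: np.ndarray
    B: np.ndarray
    Sigma: np.ndarray
    Z: np.ndarray
    H: np.ndarray
    nu: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float).reshape(2))
        object.__setattr__(self, "B", np.asarray(self.B, dtype=float).reshape(2, 2))
        for name in ("Sigma", "Z", "H"):
            object.__setattr__(self, name, _check_spd(getattr(self, name), name))
        if not np.all(np.isfinite(self.a)) or not np.all(np.isfinite(self.B)):
            raise ValueError("a and B must be finite")
        if not (self.nu > 2.0):
            raise ValueError("nu must exceed 2 so the observation covariance exists")

    @property
    def obs_cov(self) -> np.ndarray:
        """Covariance nu H / (nu - 2) of a single transect about x."""
        return self.nu * self.H / (self.nu - 2.0)


@dataclass(frozen=True)
class SiteEffect:
    """Site-level deviation alpha_i of the VAR intercept."""

    alpha: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float).reshape(2)
        if not np.all(np.isfinite(a)):
            raise ValueError("alpha must be finite")
        object.__setattr__(self, "alpha", a)


@dataclass
class LatentTrajectory:
    """Latent ilr states of one site over consecutive survey years."""

    site: str
    years: np.ndarray
    states: np.ndarray  # shape (n_years, 2)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.states = np.asarray(self.states, dtype=float)
        if len(self.years) != len(self.states):
            raise ValueError("one state per year required")
        if len(self.years) > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be consecutive")


def simulate_latent(
    params: ModelParams,
    alpha: SiteEffect,
    x0: np.ndarray,
    n_years: int,
    seed: int | np.random.Generator,
    site: str = "sim",
    start_year: int = 0,
) -> LatentTrajectory:
    """Iterate the VAR(1) recursion for ``n_years`` states from ``x0``.

    ``x0`` is the state in the first year; n_years - 1 transitions are
    simulated with independent N(0, Sigma) innovations.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(params.Sigma)
    drift = params.a + alpha.alpha
    x = np.empty((n_years, 2))
    x[0] = np.asarray(x0, dtype=float).reshape(2)
    for t in range(1, n_years):
        eps = chol @ rng.standard_normal(2)
        x[t] = drift + params.B @ x[t - 1] + eps
    return LatentTrajectory(site, start_year + np.arange(n_years), x)


def observe_transects(
    x: np.ndarray,
    params: ModelParams,
    n_transects: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n_transects`` i.i.d. bivariate-t transect observations.

    Uses the normal/chi-square mixture representation: y = x + L e / sqrt(w)
    with e ~ N(0, I2), w ~ chi2(nu)/nu and L the Cholesky factor of H.
    Returns an array of shape (n_transects, 2).
    """
    if n_transects < 1:
        raise ValueError("n_transects must be >= 1")
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float).reshape(2)
    chol = np.linalg.cholesky(params.H)
    z = rng.standard_normal((n_transects, 2)) @ chol.T
    w = rng.chisquare(params.nu, size=n_transects) / params.nu
    return x + z / np.sqrt(w)[:, None]


def change_matrix(B: np.ndarray) -> np.ndarray:
    """A = B - I: effect of current composition on the year-to-year change,
    so that x_{t+1} - x_t = a + alpha + A x_t + eps."""
    B = np.asarray(B, dtype=float).reshape(2, 2)
    return B - np.eye(2)


def eigen_diagnostics(B: np.ndarray) -> dict:
    """Eigen-structure of B: stationarity and oscillation flags.

    The process has a stationary distribution iff both eigenvalues of B
    lie strictly inside the unit circle; complex eigenvalues produce
    decaying oscillations on the approach to it.
    """
    B = np.asarray(B, dtype=float).reshape(2, 2)
    eig = np.linalg.eigvals(B)
    moduli = np.abs(eig)
    return {
        "eigenvalues": eig,
        "stationary": bool(np.all(moduli < 1.0)),
        "oscillatory": bool(np.any(np.abs(eig.imag) > 0.0)),
        "max_modulus": float(moduli.max()),
    }
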