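"""Bayesian estimation of the hierarchical VAR(1) state-space model.

The posterior of (a, B, Sigma, Z, H, nu), the site effects alpha_i and
the latent yearly states x_{i,t} is sampled with a Metropolis-within-
Gibbs scheme built around two exact marginalizations:

* the bivariate-t observation layer is augmented with per-transect
  Gamma(nu/2, nu/2) scale-mixture weights w, conditional on which every
  transect is Gaussian with covariance H / w;
* conditional on the weights, the latent states and the site effect of
  each site form a linear-Gaussian state space (alpha enters as a
  constant appended state), so their joint density is integrated out
  exactly by a Kalman filter.  Structural parameters are therefore
  updated by adaptive random-walk Metropolis on the *marginal*
  likelihood p(y | theta, w) — the update never conditions on the
  latent trajectories, which is what makes the chain mix at all in a
  model where states and parameters are strongly dependent.

One sweep updates, in order: (a, B) jointly; Sigma; Z; H (each against
the Kalman marginal likelihood); the latent states and site effects by
forward-filter backward-sampling; the mixture weights from their
conditional Gamma law; and nu by a 1-D Metropolis step on log(nu - 2).
Proposal scales and covariances adapt during warmup only, so the
post-warmup chain is a fixed-kernel Markov chain.

Because several transects share a site-year and a common scale matrix
H, the weighted transects of a site-year collapse into one effective
Gaussian observation (precision-weighted mean, covariance H / sum(w)),
so the filter processes one update per site *visit* rather than per
transect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .process_model import ModelParams

__all__ = [
    "PriorConfig",
    "McmcConfig",
    "Posterior",
    "fit_model",
    "hpd_interval",
    "HpdInterval",
    "alpha_generalized_variance",
    "convergence_report",
]

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative default priors for ilr-scale data of order 1.

    Elements of a and B are N(0, sd^2); each covariance matrix is
    parameterized as (scale1, scale2, correlation) with half-normal
    scales and a uniform correlation; nu - 2 is Gamma(shape, rate),
    keeping the observation covariance nu H/(nu - 2) finite.
    """

    sd_a: float = 1.0
    sd_b: float = 1.0
    scale_sd: float = 1.0
    nu_shape: float = 2.0
    nu_rate: float = 0.1
    x0_sd: float = 5.0  # diffuse prior SD for each site's first-year state


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 4
    warmup: int = 1000
    iters: int = 1000
    target_accept: float = 0.3
    substeps: int = 3  # Metropolis proposals per structural block per sweep
    store_latent: bool = True


# ---------------------------------------------------------------------------
# data preparation


class _SurveyData:
    """Ilr observations grouped by site and year offset."""

    def __init__(self, records: pd.DataFrame):
        need = {"site", "year", "y1", "y2"}
        if not need.issubset(records.columns):
            raise ValueError(f"records must carry columns {sorted(need)}")
        y = records[["y1", "y2"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite ilr values in records")

        visits = records.groupby("site")["year"].nunique()
        single = visits[visits < 2].index
        if len(single):
            warnings.warn(
                f"dropping {len(single)} site(s) with a single visit: {sorted(single)}",
                stacklevel=3,
            )
            records = records[~records["site"].isin(single)]
        if records["site"].nunique() < 2:
            raise ValueError("need at least 2 sites with >= 2 visits")

        self.sites = sorted(records["site"].unique())
        self.n_sites = len(self.sites)
        self.first_year = {}
        self.span = {}
        site_t = []
        for s in self.sites:
            yrs = records.loc[records["site"] == s, "year"]
            self.first_year[s] = int(yrs.min())
            self.span[s] = int(yrs.max() - yrs.min() + 1)
        self.t_max = max(self.span.values())

        site_idx = {s: i for i, s in enumerate(self.sites)}
        rec_site = records["site"].map(site_idx).to_numpy()
        rec_t = (
            records["year"].to_numpy(int)
            - np.array([self.first_year[s] for s in records["site"]], dtype=int)
        )
        self.y = records[["y1", "y2"]].to_numpy(dtype=float)
        self.rec_site = rec_site
        self.rec_t = rec_t
        self.cell = rec_site * self.t_max + rec_t  # flat (site, year) key
        self.n_obs = len(self.y)

        self.obs_mask = np.zeros((self.n_sites, self.t_max), dtype=bool)
        self.obs_mask[rec_site, rec_t] = True
        counts = np.zeros(self.n_sites * self.t_max)
        np.add.at(counts, self.cell, 1.0)
        self.n_per_cell = counts.reshape(self.n_sites, self.t_max)

    def weight_stats(self, w: np.ndarray):
        """Per-cell sums needed by the collapsed likelihood.

        Returns (W, Ybar, const_w, S_w_total) with W and Ybar over the
        (site, year) grid; const_w collects every term that depends on w
        but not on theta; S_w_total is the summed weighted scatter about
        the weighted means, whose trace against H^{-1} enters the
        likelihood.
        """
        flat = self.n_sites * self.t_max
        W = np.zeros(flat)
        np.add.at(W, self.cell, w)
        Sy = np.zeros((flat, 2))
        np.add.at(Sy, self.cell, w[:, None] * self.y)
        Syy = np.zeros((flat, 3))  # packed symmetric: yy11, yy21, yy22
        yy = np.stack(
            [self.y[:, 0] ** 2, self.y[:, 0] * self.y[:, 1], self.y[:, 1] ** 2], axis=1
        )
        np.add.at(Syy, self.cell, w[:, None] * yy)

        mask = W > 0
        Ybar = np.zeros_like(Sy)
        Ybar[mask] = Sy[mask] / W[mask, None]
        s_w = Syy.copy()
        s_w[mask, 0] -= W[mask] * Ybar[mask, 0] ** 2
        s_w[mask, 1] -= W[mask] * Ybar[mask, 0] * Ybar[mask, 1]
        s_w[mask, 2] -= W[mask] * Ybar[mask, 1] ** 2
        S_w_total = np.array(
            [[s_w[:, 0].sum(), s_w[:, 1].sum()], [s_w[:, 1].sum(), s_w[:, 2].sum()]]
        )
        n_cells = int(mask.sum())
        const_w = (
            np.log(w).sum()
            - np.log(W[mask]).sum()
            - (self.n_obs - n_cells) * _LOG2PI
        )
        return (
            W.reshape(self.n_sites, self.t_max),
            Ybar.reshape(self.n_sites, self.t_max, 2),
            const_w,
            S_w_total,
        )


# ---------------------------------------------------------------------------
# parameter packing: unconstrained vector <-> structural parameters


def _cov_from_u(u: np.ndarray) -> np.ndarray:
    s1, s2 = np.exp(u[0]), np.exp(u[1])
    r = np.tanh(u[2])
    return np.array([[s1 * s1, r * s1 * s2], [r * s1 * s2, s2 * s2]])


def _u_from_cov(c: np.ndarray) -> np.ndarray:
    s1, s2 = math.sqrt(c[0, 0]), math.sqrt(c[1, 1])
    r = np.clip(c[0, 1] / (s1 * s2), -0.999, 0.999)
    return np.array([math.log(s1), math.log(s2), np.arctanh(r)])


def _logprior_cov(u: np.ndarray, scale_sd: float) -> float:
    # half-normal(scale_sd) scales with log-scale Jacobian; uniform
    # correlation with tanh Jacobian
    s1, s2 = np.exp(u[0]), np.exp(u[1])
    r = np.tanh(u[2])
    return float(
        -0.5 * (s1 * s1 + s2 * s2) / scale_sd**2
        + u[0]
        + u[1]
        + np.log1p(-r * r)
    )


# ---------------------------------------------------------------------------
# collapsed Kalman likelihood, vectorized across sites


def _marginal_loglik(
    a, B, Sigma, Z, H, data: _SurveyData, W, Ybar, const_w, S_w_total, x0_var
):
    """log p(y | theta, w) with latent states and site effects integrated out.

    Runs one augmented Kalman filter (state = [x_t, alpha], 4-D) jointly
    over all sites on the padded year grid.  Also returns the posterior
    mean/covariance of each site's alpha (exact, since alpha is static).
    """
    S, T = data.n_sites, data.t_max
    det_h = H[0, 0] * H[1, 1] - H[0, 1] * H[1, 0]
    if det_h <= 0 or H[0, 0] <= 0:
        return -np.inf, None, None
    h_inv = np.array([[H[1, 1], -H[0, 1]], [-H[1, 0], H[0, 0]]]) / det_h

    m = np.zeros((S, 4))
    P = np.zeros((S, 4, 4))
    P[:, 0, 0] = P[:, 1, 1] = x0_var
    P[:, 2:, 2:] = Z

    ll = const_w - 0.5 * math.log(det_h) * (data.n_obs - np.count_nonzero(W)) \
        - 0.5 * float(np.sum(h_inv * S_w_total))

    for t in range(T):
        idx = np.flatnonzero(data.obs_mask[:, t])
        if idx.size:
            Pm = P[idx]
            mm = m[idx]
            R = H[None, :, :] / W[idx, t, None, None]
            S2 = Pm[:, :2, :2] + R
            det = S2[:, 0, 0] * S2[:, 1, 1] - S2[:, 0, 1] * S2[:, 1, 0]
            if np.any(det <= 0):
                return -np.inf, None, None
            inv = np.empty_like(S2)
            inv[:, 0, 0] = S2[:, 1, 1]
            inv[:, 1, 1] = S2[:, 0, 0]
            inv[:, 0, 1] = -S2[:, 0, 1]
            inv[:, 1, 0] = -S2[:, 1, 0]
            inv /= det[:, None, None]
            v = Ybar[idx, t] - mm[:, :2]
            quad = np.einsum("ni,nij,nj->n", v, inv, v)
            ll += float(np.sum(-_LOG2PI - 0.5 * np.log(det) - 0.5 * quad))
            K = Pm[:, :, :2] @ inv
            m[idx] = mm + np.einsum("nij,nj->ni", K, v)
            P[idx] = Pm - K @ S2 @ K.transpose(0, 2, 1)
        if t < T - 1:
            # s_{t+1} = (a, 0) + [[B, I], [0, I]] s_t + (eps, 0)
            mx = a[None, :] + m[:, :2] @ B.T + m[:, 2:]
            m = np.concatenate([mx, m[:, 2:]], axis=1)
            P11 = P[:, :2, :2]
            P12 = P[:, :2, 2:]
            P22 = P[:, 2:, 2:]
            BP12 = B[None] @ P12
            new11 = (
                B[None] @ P11 @ B.T[None]
                + BP12
                + BP12.transpose(0, 2, 1)
                + P22
                + Sigma[None]
            )
            new12 = BP12 + P22
            Pn = np.empty_like(P)
            Pn[:, :2, :2] = new11
            Pn[:, :2, 2:] = new12
            Pn[:, 2:, :2] = new12.transpose(0, 2, 1)
            Pn[:, 2:, 2:] = P22
            P = Pn
    if not np.isfinite(ll):
        return -np.inf, None, None
    return float(ll), m[:, 2:].copy(), P[:, 2:, 2:].copy()


def _ffbs_site(y_bar, w_sum, obs_t, span, a_eff, B, Sigma, H, x0_var, rng):
    """Sample x_{1..span} | alpha, theta, w, y for one site (2-D FFBS)."""
    ms = np.zeros((span, 2))
    Ps = np.zeros((span, 2, 2))
    mp = np.zeros((span, 2))
    Pp = np.zeros((span, 2, 2))
    m = np.zeros(2)
    P = np.eye(2) * x0_var
    obs_set = {int(t): k for k, t in enumerate(obs_t)}
    for t in range(span):
        mp[t], Pp[t] = m, P
        if t in obs_set:
            k = obs_set[t]
            R = H / w_sum[k]
            S2 = P + R
            inv = np.linalg.inv(S2)
            K = P @ inv
            m = m + K @ (y_bar[k] - m)
            P = P - K @ P
            P = 0.5 * (P + P.T)
        ms[t], Ps[t] = m, P
        if t < span - 1:
            m = a_eff + B @ m
            P = B @ P @ B.T + Sigma
            P = 0.5 * (P + P.T)
    x = np.empty((span, 2))
    x[-1] = rng.multivariate_normal(ms[-1], Ps[-1], method="cholesky")
    for t in range(span - 2, -1, -1):
        J = Ps[t] @ B.T @ np.linalg.inv(Pp[t + 1])
        mean = ms[t] + J @ (x[t + 1] - mp[t + 1])
        cov = Ps[t] - J @ Pp[t + 1] @ J.T
        cov = 0.5 * (cov + cov.T) + 1e-12 * np.eye(2)
        x[t] = rng.multivariate_normal(mean, cov, method="cholesky")
    return x


# ---------------------------------------------------------------------------
# posterior container and summaries


@dataclass
class Posterior:
    """Joint MCMC draws; arrays carry a leading (chain, draw) shape."""

    sites: list
    first_year: dict
    span: dict
    a: np.ndarray
    B: np.ndarray
    Sigma: np.ndarray
    Z: np.ndarray
    H: np.ndarray
    nu: np.ndarray
    alpha: np.ndarray  # (chains, draws, n_sites, 2)
    states: dict  # site -> (chains, draws, span, 2)
    accept_rates: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.nu.shape[0] * self.nu.shape[1]

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def params_mean(self) -> ModelParams:
        return ModelParams(
            a=self.flat("a").mean(axis=0),
            B=self.flat("B").mean(axis=0),
            Sigma=self.flat("Sigma").mean(axis=0),
            Z=self.flat("Z").mean(axis=0),
            H=self.flat("H").mean(axis=0),
            nu=float(self.flat("nu").mean()),
        )

    def params_draw(self, k: int) -> ModelParams:
        return ModelParams(
            a=self.flat("a")[k],
            B=self.flat("B")[k],
            Sigma=self.flat("Sigma")[k],
            Z=self.flat("Z")[k],
            H=self.flat("H")[k],
            nu=float(self.flat("nu")[k]),
        )

    def to_long_table(self) -> pd.DataFrame:
        """Draws of the structural parameters as a delimited-friendly
        long table (chain, iter, parameter, value)."""
        rows = []
        names = {
            "a": [("a1", (0,)), ("a2", (1,))],
            "B": [("b11", (0, 0)), ("b21", (1, 0)), ("b12", (0, 1)), ("b22", (1, 1))],
            "Sigma": [("sigma11", (0, 0)), ("sigma21", (1, 0)), ("sigma22", (1, 1))],
            "Z": [("zeta11", (0, 0)), ("zeta21", (1, 0)), ("zeta22", (1, 1))],
            "H": [("h11", (0, 0)), ("h21", (1, 0)), ("h22", (1, 1))],
        }
        chains, draws = self.nu.shape
        for c in range(chains):
            for d in range(draws):
                for arr_name, entries in names.items():
                    arr = getattr(self, arr_name)
                    for pname, ix in entries:
                        rows.append((c, d, pname, float(arr[(c, d) + ix])))
                rows.append((c, d, "nu", float(self.nu[c, d])))
        return pd.DataFrame(rows, columns=["chain", "iter", "parameter", "value"])

    def scalar_draws(self) -> dict:
        """Structural parameters as named (chains, draws) arrays."""
        out = {
            "a1": self.a[..., 0], "a2": self.a[..., 1],
            "b11": self.B[..., 0, 0], "b21": self.B[..., 1, 0],
            "b12": self.B[..., 0, 1], "b22": self.B[..., 1, 1],
            "sigma11": self.Sigma[..., 0, 0], "sigma21": self.Sigma[..., 1, 0],
            "sigma22": self.Sigma[..., 1, 1],
            "zeta11": self.Z[..., 0, 0], "zeta21": self.Z[..., 1, 0],
            "zeta22": self.Z[..., 1, 1],
            "h11": self.H[..., 0, 0], "h21": self.H[..., 1, 0],
            "h22": self.H[..., 1, 1],
            "nu": self.nu,
        }
        return out


# ---------------------------------------------------------------------------
# the sampler


class _Block:
    """Adaptive random-walk Metropolis block on an unconstrained vector."""

    def __init__(self, dim: int, scale: float):
        self.dim = dim
        self.log_scale = math.log(scale)
        self.chol = np.eye(dim)
        self.accepted = 0
        self.proposed = 0
        self.history = []

    def propose(self, cur: np.ndarray, rng) -> np.ndarray:
        return cur + math.exp(self.log_scale) * (self.chol @ rng.standard_normal(self.dim))

    def adapt(self, accepted: bool, it: int, target: float) -> None:
        gamma = min(0.5, 2.0 * (1.0 + it) ** -0.6)
        self.log_scale += gamma * ((1.0 if accepted else 0.0) - target)

    def refresh_cov(self) -> None:
        if len(self.history) >= 50:
            cov = np.cov(np.array(self.history[-500:]).T) + 1e-8 * np.eye(self.dim)
            self.chol = np.linalg.cholesky(cov)


def _init_state(data: _SurveyData, prior: PriorConfig, rng):
    """Moment-based starting values, jittered per chain."""
    cell_mean = np.zeros((data.n_sites, data.t_max, 2))
    for k in range(2):
        tot = np.zeros(data.n_sites * data.t_max)
        np.add.at(tot, data.cell, data.y[:, k])
        with np.errstate(invalid="ignore"):
            cell_mean[..., k] = np.where(
                data.n_per_cell > 0, tot.reshape(data.n_sites, data.t_max) / data.n_per_cell, np.nan
            )
    site_mean = np.nanmean(cell_mean, axis=1)
    grand = np.nanmean(site_mean, axis=0)
    between = np.nanvar(site_mean, axis=0) + 0.05
    within = np.nanmean(np.nanvar(cell_mean, axis=1), axis=0) + 0.05

    B0 = 0.3 * np.eye(2) + 0.05 * rng.standard_normal((2, 2))
    a0 = (np.eye(2) - B0) @ grand + 0.1 * rng.standard_normal(2)
    Sigma0 = np.diag(within) * math.exp(0.3 * rng.standard_normal())
    Z0 = np.diag(between) * math.exp(0.3 * rng.standard_normal())
    obs_var = np.zeros(2)
    for k in range(2):
        resid = data.y[:, k] - np.where(
            np.isfinite(cell_mean[data.rec_site, data.rec_t, k]),
            cell_mean[data.rec_site, data.rec_t, k],
            0.0,
        )
        obs_var[k] = np.var(resid) + 0.05
    nu0 = 4.0 + rng.uniform(0, 2)
    H0 = np.diag(obs_var) * (nu0 - 2.0) / nu0
    return {
        "ab": np.concatenate([a0, B0.ravel(order="F")]),
        "Sigma": _u_from_cov(Sigma0),
        "Z": _u_from_cov(Z0),
        "H": _u_from_cov(H0),
        "nu": nu0,
    }


def _theta_mats(state: dict):
    ab = state["ab"]
    a = ab[:2]
    B = ab[2:].reshape(2, 2, order="F")
    return a, B, _cov_from_u(state["Sigma"]), _cov_from_u(state["Z"]), _cov_from_u(state["H"])


def _logprior_ab(ab: np.ndarray, prior: PriorConfig) -> float:
    return float(
        -0.5 * np.sum(ab[:2] ** 2) / prior.sd_a**2
        - 0.5 * np.sum(ab[2:] ** 2) / prior.sd_b**2
    )


def _run_chain(data: _SurveyData, prior: PriorConfig, mcmc: McmcConfig, seed, progress=None):
    rng = np.random.default_rng(seed)
    state = _init_state(data, prior, rng)
    w = np.ones(data.n_obs)
    W, Ybar, const_w, S_w_total = data.weight_stats(w)
    x0_var = prior.x0_sd**2

    blocks = {
        "ab": _Block(6, 0.02),
        "Sigma": _Block(3, 0.05),
        "Z": _Block(3, 0.05),
        "H": _Block(3, 0.02),
        "nu": _Block(1, 0.1),
    }

    def loglik_of(state):
        a, B, Sig, Z, H = _theta_mats(state)
        return _marginal_loglik(a, B, Sig, Z, H, data, W, Ybar, const_w, S_w_total, x0_var)

    def logprior_of(state, name):
        if name == "ab":
            return _logprior_ab(state["ab"], prior)
        return _logprior_cov(state[name], prior.scale_sd)

    cur_ll, cur_am, cur_ap = loglik_of(state)
    if not np.isfinite(cur_ll):
        raise RuntimeError("non-finite likelihood at initialization")

    n_keep = mcmc.iters
    draws = {
        "a": np.empty((n_keep, 2)),
        "B": np.empty((n_keep, 2, 2)),
        "Sigma": np.empty((n_keep, 2, 2)),
        "Z": np.empty((n_keep, 2, 2)),
        "H": np.empty((n_keep, 2, 2)),
        "nu": np.empty(n_keep),
        "alpha": np.empty((n_keep, data.n_sites, 2)),
    }
    states_store = {
        s: np.empty((n_keep, data.span[s], 2)) for s in data.sites
    } if mcmc.store_latent else {}

    # per-site observation bookkeeping for FFBS / w updates
    site_obs_t = [np.flatnonzero(data.obs_mask[i]) for i in range(data.n_sites)]
    rec_order = np.argsort(data.cell, kind="stable")

    total = mcmc.warmup + mcmc.iters
    for it in range(total):
        warm = it < mcmc.warmup
        # --- structural blocks against the Kalman marginal likelihood
        for name in ("ab", "Sigma", "Z", "H"):
            blk = blocks[name]
            for _ in range(mcmc.substeps):
                prop_state = dict(state)
                prop_state[name] = blk.propose(state[name], rng)
                prop_ll, prop_am, prop_ap = loglik_of(prop_state)
                logr = (
                    prop_ll
                    + logprior_of(prop_state, name)
                    - cur_ll
                    - logprior_of(state, name)
                )
                accept = np.isfinite(prop_ll) and math.log(rng.uniform()) < logr
                if accept:
                    state = prop_state
                    cur_ll, cur_am, cur_ap = prop_ll, prop_am, prop_ap
                blk.proposed += 1
                blk.accepted += int(accept)
                if warm:
                    blk.adapt(accept, it, mcmc.target_accept)
            if warm:
                blk.history.append(state[name].copy())
                if it in (mcmc.warmup // 4, mcmc.warmup // 2, 3 * mcmc.warmup // 4):
                    blk.refresh_cov()

        a, B, Sig, Z, H = _theta_mats(state)

        # --- site effects and latent states by FFBS
        alpha = np.empty((data.n_sites, 2))
        xs = []
        for i in range(data.n_sites):
            cov = 0.5 * (cur_ap[i] + cur_ap[i].T) + 1e-12 * np.eye(2)
            alpha[i] = rng.multivariate_normal(cur_am[i], cov, method="cholesky")
            obs_t = site_obs_t[i]
            x = _ffbs_site(
                Ybar[i, obs_t],
                W[i, obs_t],
                obs_t,
                data.span[data.sites[i]],
                a + alpha[i],
                B,
                Sig,
                H,
                x0_var,
                rng,
            )
            xs.append(x)

        # --- mixture weights w | x, H, nu  (conjugate Gamma)
        x_at_obs = np.empty((data.n_obs, 2))
        for i in range(data.n_sites):
            sel = data.rec_site == i
            x_at_obs[sel] = xs[i][data.rec_t[sel]]
        resid = data.y - x_at_obs
        det_h = H[0, 0] * H[1, 1] - H[0, 1] ** 2
        h_inv = np.array([[H[1, 1], -H[0, 1]], [-H[0, 1], H[0, 0]]]) / det_h
        quad = np.einsum("ni,ij,nj->n", resid, h_inv, resid)
        nu = state["nu"]
        w = rng.gamma((nu + 2.0) / 2.0, 2.0 / (nu + quad))
        W, Ybar, const_w, S_w_total = data.weight_stats(w)

        # --- nu | w : Metropolis on log(nu - 2)
        blk = blocks["nu"]
        log_w_sum = float(np.log(w).sum())
        w_sum = float(w.sum())

        def log_post_nu(nu_val):
            half = nu_val / 2.0
            ll = data.n_obs * (half * math.log(half) - math.lgamma(half))
            ll += (half - 1.0) * log_w_sum - half * w_sum
            lp = (prior.nu_shape - 1.0) * math.log(nu_val - 2.0) - prior.nu_rate * (
                nu_val - 2.0
            )
            return ll + lp + math.log(nu_val - 2.0)  # + log-Jacobian

        eta = math.log(nu - 2.0)
        eta_prop = float(blk.propose(np.array([eta]), rng)[0])
        nu_prop = 2.0 + math.exp(eta_prop)
        accept = math.log(rng.uniform()) < log_post_nu(nu_prop) - log_post_nu(nu)
        if accept:
            state["nu"] = nu_prop
        blk.proposed += 1
        blk.accepted += int(accept)
        if warm:
            blk.adapt(accept, it, mcmc.target_accept)

        # likelihood cache is stale after the w refresh
        cur_ll, cur_am, cur_ap = loglik_of(state)

        if not warm:
            k = it - mcmc.warmup
            a, B, Sig, Z, H = _theta_mats(state)
            draws["a"][k] = a
            draws["B"][k] = B
            draws["Sigma"][k] = Sig
            draws["Z"][k] = Z
            draws["H"][k] = H
            draws["nu"][k] = state["nu"]
            draws["alpha"][k] = alpha
            if mcmc.store_latent:
                for i, s in enumerate(data.sites):
                    states_store[s][k] = xs[i]
    rates = {k: b.accepted / max(b.proposed, 1) for k, b in blocks.items()}
    return draws, states_store, rates


def fit_model(
    records: pd.DataFrame,
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
) -> Posterior:
    """Fit the hierarchical VAR(1) state-space model to transect records.

    ``records`` is a closed survey table (see :mod:`reefvar.survey_io`);
    ilr coordinates are computed here if absent.  Returns the joint
    posterior over structural parameters, site effects and latent
    yearly states (including unobserved gap years).  R-hat above 1.01
    on any structural parameter raises a warning and sets
    ``posterior.meta['diagnostics_ok'] = False``.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    if "y1" not in records.columns:
        from .survey_io import records_to_ilr

        records = records_to_ilr(records)
    data = _SurveyData(records)

    seeds = np.random.SeedSequence(seed).spawn(mcmc.chains)
    chains_draws = []
    chains_states = []
    rates = []
    for c in range(mcmc.chains):
        d, st, r = _run_chain(data, priors, mcmc, seeds[c])
        chains_draws.append(d)
        chains_states.append(st)
        rates.append(r)

    stacked = {
        k: np.stack([d[k] for d in chains_draws]) for k in chains_draws[0]
    }
    states = {}
    if mcmc.store_latent:
        for s in data.sites:
            states[s] = np.stack([st[s] for st in chains_states])
    post = Posterior(
        sites=data.sites,
        first_year=dict(data.first_year),
        span=dict(data.span),
        a=stacked["a"],
        B=stacked["B"],
        Sigma=stacked["Sigma"],
        Z=stacked["Z"],
        H=stacked["H"],
        nu=stacked["nu"],
        alpha=stacked["alpha"],
        states=states,
        accept_rates={k: float(np.mean([r[k] for r in rates])) for k in rates[0]},
        meta={
            "seed": seed,
            "chains": mcmc.chains,
            "warmup": mcmc.warmup,
            "iters": mcmc.iters,
        },
    )
    if mcmc.chains >= 2:
        report = convergence_report(post)
        bad = report[report["rhat"] > 1.01]
        post.meta["diagnostics_ok"] = bad.empty
        post.meta["max_rhat"] = float(report["rhat"].max())
        if not bad.empty:
            warnings.warn(
                "convergence diagnostics failed for "
                f"{bad['parameter'].tolist()} (max R-hat {post.meta['max_rhat']:.3f})",
                stacklevel=2,
            )
    return post


# ---------------------------------------------------------------------------
# posterior summaries


@dataclass(frozen=True)
class HpdInterval:
    lower: float
    upper: float
    mass: float


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> HpdInterval:
    """Shortest contiguous interval containing ceil(mass * n) sorted draws."""
    if not (0.0 < mass <= 1.0):
        raise ValueError("mass must lie in (0, 1]")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    k = int(math.ceil(mass * n))
    if k >= n:
        return HpdInterval(float(x[0]), float(x[-1]), mass)
    widths = x[k - 1 :] - x[: n - k + 1]
    j = int(np.argmin(widths))
    return HpdInterval(float(x[j]), float(x[j + k - 1]), mass)


def alpha_generalized_variance(posterior: Posterior, site: str) -> float:
    """Determinant of the sample covariance of a site's alpha draws."""
    i = posterior.sites.index(site)
    draws = posterior.flat("alpha")[:, i, :]
    if len(draws) < 2:
        raise ValueError("need at least 2 draws")
    return float(np.linalg.det(np.cov(draws.T)))


def convergence_report(posterior: Posterior) -> pd.DataFrame:
    """Split R-hat and bulk ESS per structural parameter (via arviz)."""
    import arviz as az

    scalars = posterior.scalar_draws()
    single_chain = posterior.nu.shape[0] < 2
    rows = []
    idata = az.from_dict(posterior={k: v for k, v in scalars.items()})
    ess = az.ess(idata)
    rhat = None if single_chain else az.rhat(idata)
    for name in scalars:
        rows.append(
            {
                "parameter": name,
                "rhat": float("nan") if single_chain else float(rhat[name].values),
                "ess_bulk": float(ess[name].values),
                "flag": (not single_chain) and float(rhat[name].values) > 1.01,
            }
        )
    return pd.DataFrame(rows)
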