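"""Scikit-learn style front end to the hierarchical reef VAR model.

:class:`ReefVAR` wraps data validation, MCMC fitting and the long-run /
risk summaries behind the familiar estimator interface: configure in
``__init__``, call :meth:`fit` on a survey table, read fitted
attributes (trailing underscore).  The lower-level module functions
(:func:`reefvar.inference.fit_model` and friends) remain available and
are what this class composes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .inference import McmcConfig, Posterior, PriorConfig, fit_model, hpd_interval
from .process_model import ModelParams, SiteEffect, eigen_diagnostics
from .risk import prob_low_coral, risk_gradient, site_risk
from .stationary import among_site_cov, rho_statistic, snapshot_correlation, stationary_mean, within_site_cov

__all__ = ["ReefVAR", "longrun_draws"]


def longrun_draws(posterior: Posterior, kappa: float = 0.1, thin: int = 1) -> pd.DataFrame:
    """Per-draw long-run summaries: rho, snapshot correlations, regional
    q_kappa, and the stationarity flag of B.

    Draws whose B has an eigenvalue on or outside the unit circle
    (expected to be rare or absent) get NaN summaries; the flag records
    them.
    """
    rows = []
    n = posterior.n_draws
    for k in range(0, n, thin):
        p = posterior.params_draw(k)
        if not eigen_diagnostics(p.B)["stationary"]:
            rows.append({"rho": np.nan, "corr1": np.nan, "corr2": np.nan,
                         "q": np.nan, "stationary": False})
            continue
        s_star = within_site_cov(p.B, p.Sigma)
        z_star = among_site_cov(p.B, p.Z)
        mu = stationary_mean(p.a, p.B)
        corr = snapshot_correlation(s_star, z_star)
        rows.append(
            {
                "rho": rho_statistic(s_star, z_star),
                "corr1": corr[0],
                "corr2": corr[1],
                "q": prob_low_coral(mu, s_star + z_star, kappa),
                "stationary": True,
            }
        )
    return pd.DataFrame(rows)


class ReefVAR(BaseEstimator):
    """Hierarchical VAR(1) state-space model of reef benthic composition.

    Parameters
    ----------
    kappa : float
        Coral-cover threshold for the risk summaries.
    chains, warmup, iters, substeps : int
        MCMC schedule (see :class:`reefvar.inference.McmcConfig`).
    seed : int
        Seed for all sampling; identical seeds give identical draws.
    priors : PriorConfig or None
        Prior configuration; None uses the weakly-informative defaults.

    Attributes
    ----------
    posterior_ : Posterior
        Joint draws of all parameters, site effects and latent states.
    params_ : ModelParams
        Posterior-mean structural parameters.
    rho_, nu_, snapshot_corr_, regional_q_ : posterior means of the
        long-run summaries (rho statistic, t degrees of freedom,
        per-component snapshot correlations, regional P(coral <= kappa)).
    site_risk_ : DataFrame with per-site posterior mean q and HPD bounds.
    """

    def __init__(
        self,
        kappa: float = 0.1,
        chains: int = 4,
        warmup: int = 1000,
        iters: int = 1000,
        substeps: int = 3,
        seed: int = 0,
        priors: PriorConfig | None = None,
    ):
        self.kappa = kappa
        self.chains = chains
        self.warmup = warmup
        self.iters = iters
        self.substeps = substeps
        self.seed = seed
        self.priors = priors

    def fit(self, X: pd.DataFrame, y=None) -> "ReefVAR":
        """Fit the model to a closed survey table (canonical columns)."""
        mcmc = McmcConfig(
            chains=self.chains, warmup=self.warmup, iters=self.iters, substeps=self.substeps
        )
        self.posterior_ = fit_model(X, priors=self.priors, mcmc=mcmc, seed=self.seed)
        self.params_ = self.posterior_.params_mean()
        self.nu_ = float(self.posterior_.flat("nu").mean())

        lr = longrun_draws(self.posterior_, kappa=self.kappa)
        ok = lr[lr["stationary"]]
        self.stationary_fraction_ = float(lr["stationary"].mean())
        self.rho_ = float(ok["rho"].mean())
        self.rho_hpd_ = hpd_interval(ok["rho"].to_numpy())
        self.snapshot_corr_ = np.array([ok["corr1"].mean(), ok["corr2"].mean()])
        self.regional_q_ = float(ok["q"].mean())
        self.regional_q_hpd_ = hpd_interval(ok["q"].to_numpy())
        self.longrun_draws_ = lr
        self.site_risk_ = self._site_risk_table()
        return self

    def _check_fitted(self):
        if not hasattr(self, "posterior_"):
            raise RuntimeError("call fit first")

    def _site_risk_table(self) -> pd.DataFrame:
        post = self.posterior_
        alpha = post.flat("alpha")  # (draws, n_sites, 2)
        n = alpha.shape[0]
        qs = np.full((n, len(post.sites)), np.nan)
        for k in range(n):
            p = post.params_draw(k)
            if not eigen_diagnostics(p.B)["stationary"]:
                continue
            s_star = within_site_cov(p.B, p.Sigma)
            mus = np.linalg.solve(np.eye(2) - p.B, (p.a[None, :] + alpha[k]).T).T
            qs[k] = prob_low_coral(mus, s_star, self.kappa)
        rows = []
        for i, s in enumerate(post.sites):
            col = qs[:, i]
            col = col[np.isfinite(col)]
            h = hpd_interval(col)
            rows.append({"site": s, "kappa": self.kappa, "q": col.mean(),
                         "q_median": float(np.median(col)),
                         "q_lower": h.lower, "q_upper": h.upper})
        return pd.DataFrame(rows)

    def predict_risk(self, alpha: np.ndarray) -> float:
        """Posterior-mean-parameter site risk for a given site effect."""
        self._check_fitted()
        return site_risk(self.params_, SiteEffect(alpha), self.kappa).q

    def sensitivity(self, kappa: float | None = None):
        """Gradient of the regional q at the posterior-mean parameters."""
        self._check_fitted()
        return risk_gradient(self.params_, kappa if kappa is not None else self.kappa)

    def summary(self) -> pd.DataFrame:
        """Posterior mean and 95% HPD interval per structural parameter."""
        self._check_fitted()
        rows = []
        for name, draws in self.posterior_.scalar_draws().items():
            flat = draws.ravel()
            h = hpd_interval(flat)
            rows.append({"parameter": name, "mean": flat.mean(),
                         "hpd_lower": h.lower, "hpd_upper": h.upper})
        return pd.DataFrame(rows)
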