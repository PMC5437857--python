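"""Posterior machinery: HPD intervals, diagnostics, small-fit behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefvar.inference import (
    McmcConfig,
    alpha_generalized_variance,
    convergence_report,
    fit_model,
    hpd_interval,
)
from reefvar.survey_io import records_to_ilr
from reefvar.synthetic_data import SurveyDesign, generate_survey


def brute_force_hpd(x, mass):
    x = np.sort(x)
    n = len(x)
    k = int(np.ceil(mass * n))
    best = None
    for j in range(n - k + 1):
        w = x[j + k - 1] - x[j]
        if best is None or w < best[0]:
            best = (w, x[j], x[j + k - 1])
    return best[1], best[2]


class TestHpdInterval:
    def test_full_mass_gives_range(self, rng):
        x = rng.normal(size=100)
        h = hpd_interval(x, 1.0)
        assert (h.lower, h.upper) == (x.min(), x.max())

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        data=st.lists(st.floats(-100, 100), min_size=20, max_size=60),
        mass=st.floats(0.3, 0.99),
    )
    def test_matches_exhaustive_window_search(self, data, mass):
        h = hpd_interval(np.array(data), mass)
        lo, hi = brute_force_hpd(np.array(data), mass)
        assert (h.lower, h.upper) == (lo, hi)

    def test_symmetric_unimodal_close_to_equal_tailed(self, rng):
        """For a symmetric unimodal sample the HPD interval nearly
        coincides with the equal-tailed interval, and is never wider."""
        x = rng.standard_normal(100_000)
        h = hpd_interval(x, 0.95)
        q025, q975 = np.quantile(x, [0.025, 0.975])
        assert h.upper - h.lower <= (q975 - q025) + 1e-12
        assert h.lower == pytest.approx(q025, abs=0.1)
        assert h.upper == pytest.approx(q975, abs=0.1)
        assert h.lower == pytest.approx(-h.upper, abs=0.15)

    def test_invalid_mass(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(30), 1.5)


class TestAlphaGeneralizedVariance:
    def _posterior_stub(self, alpha_draws):
        from reefvar.inference import Posterior

        n = len(alpha_draws)
        return Posterior(
            sites=["s1"], first_year={"s1": 2000}, span={"s1": 3},
            a=np.zeros((1, n, 2)), B=np.zeros((1, n, 2, 2)),
            Sigma=np.zeros((1, n, 2, 2)), Z=np.zeros((1, n, 2, 2)),
            H=np.zeros((1, n, 2, 2)), nu=np.zeros((1, n)),
            alpha=alpha_draws[None, :, None, :], states={},
        )

    def test_constant_draws_give_zero(self):
        post = self._posterior_stub(np.ones((50, 2)))
        assert alpha_generalized_variance(post, "s1") == 0.0

    def test_standard_normal_draws_give_unit_determinant(self, rng):
        post = self._posterior_stub(rng.standard_normal((200_000, 2)))
        assert alpha_generalized_variance(post, "s1") == pytest.approx(1.0, abs=0.02)


class TestConvergenceReport:
    def _posterior_from_scalars(self, nu_draws):
        from reefvar.inference import Posterior

        c, n = nu_draws.shape
        z = np.zeros((c, n))
        return Posterior(
            sites=["s1"], first_year={"s1": 2000}, span={"s1": 3},
            a=np.stack([nu_draws, z], axis=-1),
            B=np.zeros((c, n, 2, 2)) + nu_draws[..., None, None],
            Sigma=np.zeros((c, n, 2, 2)) + 1.0,
            Z=np.zeros((c, n, 2, 2)) + 1.0,
            H=np.zeros((c, n, 2, 2)) + 1.0,
            nu=nu_draws, alpha=np.zeros((c, n, 1, 2)), states={},
        )

    def test_iid_chains_pass(self, rng):
        post = self._posterior_from_scalars(rng.standard_normal((4, 500)))
        rep = convergence_report(post)
        row = rep[rep["parameter"] == "nu"].iloc[0]
        assert row["rhat"] < 1.01 and not row["flag"]

    def test_shifted_chains_flagged(self, rng):
        draws = rng.standard_normal((2, 500))
        draws[1] += 5.0
        rep = convergence_report(self._posterior_from_scalars(draws))
        assert rep[rep["parameter"] == "nu"].iloc[0]["flag"]

    def test_ess_reflects_autocorrelation(self, rng):
        """i.i.d. chains give ESS near the draw count; a strongly
        autocorrelated chain gives a much smaller ESS."""
        iid = rng.standard_normal((2, 300))
        rep = convergence_report(self._posterior_from_scalars(iid))
        ess_iid = rep[rep["parameter"] == "nu"].iloc[0]["ess_bulk"]
        assert 0.5 * 600 < ess_iid < 1.5 * 600
        ar = np.empty((2, 300))
        ar[:, 0] = rng.standard_normal(2)
        for t in range(1, 300):
            ar[:, t] = 0.95 * ar[:, t - 1] + np.sqrt(1 - 0.95**2) * rng.standard_normal(2)
        rep = convergence_report(self._posterior_from_scalars(ar))
        ess_ar = rep[rep["parameter"] == "nu"].iloc[0]["ess_bulk"]
        assert ess_ar < 0.5 * ess_iid


class TestFitModel:
    def test_seed_determinism(self, params):
        rec = generate_survey(params, SurveyDesign.grid(4, 6, 5), seed=2)
        cfg = McmcConfig(chains=1, warmup=40, iters=40, substeps=1)
        p1 = fit_model(rec, mcmc=cfg, seed=77)
        p2 = fit_model(rec, mcmc=cfg, seed=77)
        np.testing.assert_array_equal(p1.nu, p2.nu)
        np.testing.assert_array_equal(p1.B, p2.B)
        np.testing.assert_array_equal(p1.alpha, p2.alpha)
        for s in p1.sites:
            np.testing.assert_array_equal(p1.states[s], p2.states[s])

    def test_single_visit_site_dropped(self, params):
        rec = generate_survey(params, SurveyDesign.grid(3, 4, 5), seed=3)
        site = rec["site"].unique()[0]
        keep = ~((rec["site"] == site) & (rec["year"] > rec["year"].min()))
        cfg = McmcConfig(chains=1, warmup=10, iters=10, substeps=1)
        with pytest.warns(UserWarning, match="single visit"):
            post = fit_model(rec[keep], mcmc=cfg, seed=0)
        assert site not in post.sites

    def test_non_finite_ilr_rejected(self, params):
        rec = generate_survey(params, SurveyDesign.grid(3, 4, 5), seed=3)
        rec = records_to_ilr(rec)
        rec.loc[0, "y1"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_model(rec, mcmc=McmcConfig(chains=1, warmup=5, iters=5), seed=0)

    def test_draw_counts_and_spd_invariants(self, small_posterior):
        post = small_posterior
        assert post.nu.shape == (2, 400)
        assert np.all(post.nu > 2.0)
        for name in ("Sigma", "Z", "H"):
            draws = post.flat(name)
            eigs = np.linalg.eigvalsh(draws)
            assert np.all(eigs > 0)

    def test_latent_states_span_gap_years(self, params):
        """States must propagate through years with no observations."""
        spec_years = (2000, 2001, 2005, 2008)
        from reefvar.synthetic_data import SiteSpec

        design = SurveyDesign(
            sites=tuple(
                SiteSpec(site=f"s{i}", reef=f"r{i}", visit_years=spec_years,
                         transects=(7, 7, 7, 7))
                for i in range(3)
            )
        )
        rec = generate_survey(params, design, seed=4)
        post = fit_model(rec, mcmc=McmcConfig(chains=1, warmup=30, iters=30), seed=1)
        assert post.states["s0"].shape[-2] == 9  # 2000..2008 inclusive

    def test_posterior_predictive_scatter_scale(self, small_survey, small_posterior):
        """Transect scatter simulated from the posterior mean matches the
        training data's within-visit scatter within a factor of 2."""
        from reefvar.process_model import observe_transects

        pm = small_posterior.params_mean()
        sim = observe_transects([0.0, 0.0], pm, 20_000, seed=9)
        rec = records_to_ilr(small_survey)
        resid = rec.groupby(["site", "year"])[["y1", "y2"]].transform(lambda c: c - c.mean())
        for k, col in enumerate(["y1", "y2"]):
            # compare robust scales: heavy tails make variances unstable
            sim_iqr = np.subtract(*np.percentile(sim[:, k], [75, 25]))
            dat_iqr = np.subtract(*np.percentile(resid[col], [75, 25]))
            assert 0.5 < sim_iqr / dat_iqr < 2.0

    def test_alpha_uncertainty_declines_with_visits(self, params):
        """Site-effect generalized variance is largest for sites with
        few visits (negative rank correlation with visit count)."""
        from scipy.stats import spearmanr

        from reefvar.inference import alpha_generalized_variance
        from reefvar.synthetic_data import SiteSpec

        visits = [2, 3, 4, 6, 9, 13, 17, 20]
        specs = []
        for i, nv in enumerate(visits):
            years = tuple(range(2000, 2000 + nv))
            specs.append(SiteSpec(site=f"s{i}", reef=f"r{i}", visit_years=years,
                                  transects=(9,) * nv))
        rec = generate_survey(params, SurveyDesign(tuple(specs)), seed=21)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            post = fit_model(rec, mcmc=McmcConfig(chains=2, warmup=300, iters=300), seed=6)
        gv = [alpha_generalized_variance(post, f"s{i}") for i in range(len(visits))]
        assert spearmanr(visits, gv).statistic < 0

    def test_null_dynamics_recovered(self):
        """Data generated with B = 0 and (near-)zero among-site
        variability: every 95% HPD for a B entry must cover 0."""
        from reefvar.process_model import ModelParams

        null = ModelParams(a=[-1.0, 1.0], B=np.zeros((2, 2)),
                           Sigma=0.15 * np.eye(2), Z=1e-10 * np.eye(2),
                           H=0.15 * np.eye(2), nu=5.0)
        rec = generate_survey(null, SurveyDesign.grid(8, 12, 9), seed=31)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            post = fit_model(rec, mcmc=McmcConfig(chains=2, warmup=400, iters=400), seed=7)
        for name in ("b11", "b21", "b12", "b22"):
            draws = post.scalar_draws()[name].ravel()
            h = hpd_interval(draws, 0.95)
            assert h.lower <= 0.0 <= h.upper, f"{name}: ({h.lower:.3f}, {h.upper:.3f})"

    def test_latent_states_track_observations(self, small_survey, small_posterior):
        """Posterior-mean states stay inside the hull of the same-year
        transect cloud in at least 90% of site-years."""
        from scipy.spatial import Delaunay

        rec = records_to_ilr(small_survey)
        post = small_posterior
        inside = []
        for (site, year), grp in rec.groupby(["site", "year"]):
            pts = grp[["y1", "y2"]].to_numpy()
            if len(pts) < 4:
                continue
            t = int(year - post.first_year[site])
            xbar = post.states[site][:, :, t, :].reshape(-1, 2).mean(axis=0)
            inside.append(Delaunay(pts).find_simplex(xbar) >= 0)
        assert np.mean(inside) >= 0.9
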