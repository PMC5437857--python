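"""Low-coral-cover risk integrals and parameter sensitivities."""

import numpy as np
import pytest

from reefvar.compositions import ilr_forward, ilr_inverse
from reefvar.process_model import ModelParams, SiteEffect
from reefvar.risk import (
    PARAM_NAMES,
    prob_low_coral,
    regional_risk,
    risk_elasticity,
    risk_gradient,
    site_risk,
)
from reefvar.stationary import among_site_cov, stationary_mean, within_site_cov


class TestProbLowCoral:
    def test_point_mass_far_inside_high_coral(self):
        mu = ilr_forward(np.array([0.5, 0.25, 0.25]))
        assert prob_low_coral(mu, 1e-8 * np.eye(2), 0.1) < 1e-12

    def test_point_mass_in_low_coral_region(self):
        mu = ilr_forward(np.array([0.05, 0.45, 0.5]))
        assert prob_low_coral(mu, 1e-8 * np.eye(2), 0.1) > 1 - 1e-12

    def test_kappa_limits(self):
        mu = np.array([0.0, 0.0])
        cov = np.eye(2)
        assert prob_low_coral(mu, cov, 1e-4) < 1e-3
        assert prob_low_coral(mu, cov, 1 - 1e-6) > 0.999

    def test_monotone_in_kappa(self):
        mu = np.array([-0.5, 0.4])
        cov = np.array([[0.8, 0.2], [0.2, 0.5]])
        qs = [prob_low_coral(mu, cov, k) for k in (0.05, 0.1, 0.2, 0.5)]
        assert np.all(np.diff(qs) > 0)

    def test_against_monte_carlo_oracle(self, rng):
        """Quadrature vs plain Monte Carlo on random instances (the
        full-size 20 x 1e6 check runs in the acceptance suite)."""
        n = 200_000
        for _ in range(8):
            mu = rng.normal(0, 1.2, size=2)
            A = rng.normal(0, 0.6, size=(2, 2))
            cov = A @ A.T + 0.05 * np.eye(2)
            kappa = rng.uniform(0.05, 0.3)
            q = prob_low_coral(mu, cov, kappa)
            draws = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
            coral = ilr_inverse(draws)[:, 0]
            mc = (coral <= kappa).mean()
            se = max(np.sqrt(mc * (1 - mc) / n), 1e-7)
            assert abs(q - mc) < 3 * se + 1e-5

    def test_batched_mu_matches_scalar(self, rng):
        cov = np.array([[0.5, 0.1], [0.1, 0.4]])
        mus = rng.normal(size=(5, 2))
        batch = prob_low_coral(mus, cov, 0.1)
        singles = [prob_low_coral(m, cov, 0.1) for m in mus]
        np.testing.assert_allclose(batch, singles, atol=1e-14)

    def test_non_pd_cov_rejected(self):
        with pytest.raises(ValueError):
            prob_low_coral([0, 0], np.array([[1.0, 2.0], [2.0, 1.0]]), 0.1)


class TestSiteAndRegionalRisk:
    def test_alpha_pushing_coral_rich(self, params):
        q = site_risk(params, SiteEffect([-3.0, 0.0]), 0.1).q
        assert q < 1e-6

    def test_degenerate_hierarchy_matches_regional(self, params):
        p = ModelParams(a=params.a, B=params.B, Sigma=params.Sigma,
                        Z=1e-12 * np.eye(2), H=params.H, nu=params.nu)
        assert regional_risk(p, 0.1).q == pytest.approx(
            site_risk(p, SiteEffect(), 0.1).q, abs=1e-8
        )

    def test_regional_is_mixture_of_site_risks(self, params, rng):
        """Law of total probability: q = E_alpha[q_i(alpha)]."""
        n = 10_000
        alphas = rng.multivariate_normal(np.zeros(2), params.Z, size=n)
        s_star = within_site_cov(params.B, params.Sigma)
        mus = np.linalg.solve(np.eye(2) - params.B, (params.a + alphas).T).T
        site_qs = prob_low_coral(mus, s_star, 0.1)
        q_mix = site_qs.mean()
        q_reg = regional_risk(params, 0.1).q
        se = site_qs.std() / np.sqrt(n)
        assert abs(q_mix - q_reg) < 4 * se + 1e-4

    def test_monotone_in_kappa(self, params):
        qs = [regional_risk(params, k).q for k in (0.05, 0.1, 0.2)]
        assert np.all(np.diff(qs) > 0)

    def test_nonstationary_rejected(self, params):
        bad = ModelParams(a=params.a, B=1.2 * np.eye(2), Sigma=params.Sigma,
                          Z=params.Z, H=params.H, nu=params.nu)
        with pytest.raises(ValueError, match="stationary"):
            regional_risk(bad, 0.1)


class TestSensitivities:
    def test_gradient_matches_independent_finite_difference(self, params):
        """Cross-check two entries against a plain two-point secant with
        a different step size."""
        grad = risk_gradient(params, 0.1)
        h = 3e-3
        for name, build in [
            ("b22", lambda d: ModelParams(
                a=params.a, B=params.B + d * np.outer([0, 1], [0, 1]),
                Sigma=params.Sigma, Z=params.Z, H=params.H, nu=params.nu)),
            ("a1", lambda d: ModelParams(
                a=params.a + [d, 0], B=params.B, Sigma=params.Sigma,
                Z=params.Z, H=params.H, nu=params.nu)),
        ]:
            num = (regional_risk(build(h), 0.1).q - regional_risk(build(-h), 0.1).q) / (2 * h)
            assert grad.values[name] == pytest.approx(num, rel=1e-3, abs=1e-6)

    def test_symmetric_offdiagonal_perturbation(self, params):
        """zeta21 enters both off-diagonal slots; the derivative must
        match perturbing the full symmetric matrix."""
        grad = risk_gradient(params, 0.1)
        h = 1e-3
        d = np.array([[0.0, h], [h, 0.0]])
        up = ModelParams(a=params.a, B=params.B, Sigma=params.Sigma,
                         Z=params.Z + d, H=params.H, nu=params.nu)
        dn = ModelParams(a=params.a, B=params.B, Sigma=params.Sigma,
                         Z=params.Z - d, H=params.H, nu=params.nu)
        num = (regional_risk(up, 0.1).q - regional_risk(dn, 0.1).q) / (2 * h)
        assert grad.values["zeta21"] == pytest.approx(num, rel=1e-3)

    def test_flat_region_has_zero_gradient(self):
        p = ModelParams(a=[-3.0, 0.0], B=0.1 * np.eye(2),
                        Sigma=1e-4 * np.eye(2), Z=1e-4 * np.eye(2),
                        H=np.eye(2), nu=5.0)
        grad = risk_gradient(p, 0.1)
        assert all(abs(v) < 1e-6 for v in grad.values.values())

    def test_elasticity_consistent_with_gradient(self, params):
        q = regional_risk(params, 0.1).q
        grad = risk_gradient(params, 0.1)
        elas = risk_elasticity(params, 0.1)
        theta = {
            "b11": params.B[0, 0], "b21": params.B[1, 0],
            "b12": params.B[0, 1], "b22": params.B[1, 1],
            "a1": params.a[0], "a2": params.a[1],
            "sigma11": params.Sigma[0, 0], "sigma21": params.Sigma[1, 0],
            "sigma22": params.Sigma[1, 1],
            "zeta11": params.Z[0, 0], "zeta21": params.Z[1, 0],
            "zeta22": params.Z[1, 1],
        }
        for name in PARAM_NAMES:
            assert elas.values[name] * q / theta[name] == pytest.approx(
                grad.values[name], rel=5e-3, abs=1e-8
            )

    def test_elasticity_undefined_at_zero_q(self):
        p = ModelParams(a=[-4.0, 0.0], B=0.1 * np.eye(2),
                        Sigma=1e-6 * np.eye(2), Z=1e-6 * np.eye(2),
                        H=np.eye(2), nu=5.0)
        with pytest.raises(ValueError, match="undefined"):
            risk_elasticity(p, 0.001)

    def test_ranked_names(self, params):
        grad = risk_gradient(params, 0.1)
        ranked = grad.ranked()
        mags = [abs(grad.values[n]) for n in ranked]
        assert sorted(mags, reverse=True) == mags
        assert set(ranked) == set(PARAM_NAMES)
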