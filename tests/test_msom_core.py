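"""Model densities: occupancy link, site likelihood, priors, joint posterior."""

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import norm

from commocc.camtrap_data import DetectionMatrix, SiteCovariates
from commocc.msom_core import (
    ModelSpec,
    complete_data_log_posterior,
    log_prior_density,
    occupancy_prob,
    site_marginal_loglik,
)


class TestOccupancyProb:
    def test_zero_predictor_is_half(self):
        assert occupancy_prob(0.0, [0.0], [1.0]) == pytest.approx(0.5)

    def test_intercept_identity_at_zero_covariates(self):
        assert occupancy_prob(logit(0.6), [1.2, -0.5], [0.0, 0.0]) == pytest.approx(0.6)

    def test_hand_evaluated_linear_predictor(self):
        # 1 + 0.5*1 + (-0.2)*2 = 1.1
        assert occupancy_prob(1.0, [0.5, -0.2], [1.0, 2.0]) == pytest.approx(
            float(expit(1.1)), abs=1e-12
        )
        assert occupancy_prob(1.0, [0.5, -0.2], [1.0, 2.0]) == pytest.approx(0.7503, abs=1e-4)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            occupancy_prob(0.0, [0.5], [1.0, 2.0])

    def test_strictly_increasing_in_slope_for_positive_covariate(self):
        slopes = np.linspace(-2, 2, 9)
        vals = [occupancy_prob(0.3, [s], [0.7]) for s in slopes]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestSiteMarginalLoglik:
    def test_certainly_occupied_two_flips(self):
        # psi=1: two Bernoulli(0.5) occasions, history (1,0)
        assert site_marginal_loglik([1, 0], 1.0, 0.5) == pytest.approx(np.log(0.25))

    def test_all_zero_closed_form(self):
        assert site_marginal_loglik([0], 0.5, 0.5) == pytest.approx(np.log(0.75))

    @pytest.mark.parametrize("J", [1, 2, 3, 4])
    def test_normalizes_over_all_histories(self, J, rng):
        for _ in range(20):
            psi, p = rng.uniform(0.05, 0.95, 2)
            total = 0.0
            for h in range(2**J):
                y = [(h >> j) & 1 for j in range(J)]
                total += np.exp(site_marginal_loglik(y, psi, p))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_detection_in_zero_effort_occasion_rejected(self):
        with pytest.raises(ValueError, match="zero-effort"):
            site_marginal_loglik([1, 0], 0.5, 0.5, effort_mask=[0, 1])

    def test_effort_mask_drops_occasions(self):
        masked = site_marginal_loglik([0, 1, 0], 0.4, 0.3, effort_mask=[1, 1, 0])
        assert masked == pytest.approx(site_marginal_loglik([0, 1], 0.4, 0.3))


def null_state(K=2, mu_lpsi=0.2, sigma_lpsi=1.0, mu_lp=-1.0, sigma_lp=0.7, seed=0):
    r = np.random.default_rng(seed)
    return {
        "mu_lpsi": mu_lpsi, "sigma_lpsi": sigma_lpsi,
        "mu_lp": mu_lp, "sigma_lp": sigma_lp,
        "lpsi": r.standard_normal(K), "lp": r.standard_normal(K),
    }


class TestLogPrior:
    def test_sd_outside_uniform_support(self):
        state = null_state()
        state["sigma_lpsi"] = 6.0
        assert log_prior_density(state, ModelSpec("null")) == -np.inf

    def test_slope_mean_outside_support(self):
        spec = ModelSpec("covariate", covariates=["c1"])
        r = np.random.default_rng(1)
        state = {
            "mu_0": 0.0, "sigma_0": 1.0, "mu_lp": 0.0, "sigma_lp": 1.0,
            "mu_x": np.array([5.5]), "sigma_x": np.array([1.0]),
            "rho": 0.2, "beta0": r.standard_normal(3),
            "beta": r.standard_normal((3, 1)), "lp": r.standard_normal(3),
        }
        assert log_prior_density(state, spec) == -np.inf
        state["mu_x"] = np.array([1.0])
        assert np.isfinite(log_prior_density(state, spec))

    def test_species_term_matches_normal_pdf_oracle(self):
        # perturbing one species logit changes the prior by exactly the
        # closed-form normal log-density difference
        spec = ModelSpec("null")
        s1 = null_state(seed=3)
        s2 = {k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in s1.items()}
        s2["lpsi"][0] += 0.63
        diff = log_prior_density(s2, spec) - log_prior_density(s1, spec)
        oracle = norm.logpdf(s2["lpsi"][0], s1["mu_lpsi"], s1["sigma_lpsi"]) - norm.logpdf(
            s1["lpsi"][0], s1["mu_lpsi"], s1["sigma_lpsi"]
        )
        assert diff == pytest.approx(float(oracle), abs=1e-10)


class TestCompleteDataLogPosterior:
    @pytest.fixture()
    def fixture_232(self):
        # 2 species x 3 sites x 2 occasions
        y = np.array(
            [[[1, 0], [0, 0], [1, 1]], [[0, 0], [0, 1], [0, 0]]], dtype=np.int8
        )
        m = DetectionMatrix(
            y=y, species_ids=["a", "b"], site_ids=["A", "B", "C"],
            effort_days=np.full((3, 2), 14.0),
        )
        return m

    def test_certain_detection_contributes_zero(self, fixture_232):
        m = DetectionMatrix(
            y=np.ones_like(fixture_232.y), species_ids=["a", "b"],
            site_ids=["A", "B", "C"], effort_days=fixture_232.effort_days,
        )
        state = null_state()
        state["lp"] = np.full(2, 30.0)  # p ~ 1 (never stored clamped)
        z = np.ones((2, 3), dtype=int)
        lp_total = complete_data_log_posterior(z, state, m, spec=ModelSpec("null"))
        # subtracting occupancy and prior terms leaves a ~zero detection term
        psi_terms = float(
            (z * np.log(expit(state["lpsi"]))[:, None]
             + (1 - z) * np.log1p(-expit(state["lpsi"]))[:, None]).sum()
        )
        prior = log_prior_density(state, ModelSpec("null"))
        assert lp_total - psi_terms - prior == pytest.approx(0.0, abs=1e-10)

    def test_decomposes_into_component_terms(self, fixture_232, rng):
        """Joint equals detection + occupancy + prior computed independently."""
        m = fixture_232
        state = null_state(seed=9)
        z = np.maximum(m.y.max(axis=2), (rng.random((2, 3)) < 0.5).astype(int))
        spec = ModelSpec("null")
        total = complete_data_log_posterior(z, state, m, spec=spec)

        p = expit(state["lp"])
        psi = expit(state["lpsi"])
        det = 0.0
        occ = 0.0
        for k in range(2):
            for i in range(3):
                for j in range(2):
                    if z[k, i]:
                        det += m.y[k, i, j] * np.log(p[k]) + (1 - m.y[k, i, j]) * np.log(
                            1 - p[k]
                        )
                occ += z[k, i] * np.log(psi[k]) + (1 - z[k, i]) * np.log(1 - psi[k])
        oracle = det + occ + log_prior_density(state, spec)
        assert total == pytest.approx(oracle, abs=1e-9)

    def test_inconsistent_z_is_impossible(self, fixture_232):
        state = null_state()
        z = np.zeros((2, 3), dtype=int)  # species a was detected at sites A, C
        assert complete_data_log_posterior(z, state, fixture_232, spec=ModelSpec("null")) == -np.inf

    def test_covariate_variant_decomposition(self, fixture_232, rng):
        import pandas as pd

        m = fixture_232
        cov = SiteCovariates(
            pd.DataFrame(
                {
                    "site_id": ["A", "B", "C"],
                    "canopy_pct": [-1.0, 0.0, 1.0],
                    "dist_settlement_m": [0.5, -0.5, 0.0],
                    "livestock_n": [1.0, -1.0, 0.0],
                }
            ),
            standardized=True,
        )
        spec = ModelSpec("covariate",
                         covariates=["canopy_pct", "dist_settlement_m", "livestock_n"])
        state = {
            "mu_0": 0.1, "sigma_0": 0.8, "mu_lp": -1.0, "sigma_lp": 0.6,
            "mu_x": np.array([0.5, -0.3, 1.0]), "sigma_x": np.array([1.0, 0.7, 0.9]),
            "rho": 0.3, "beta0": rng.standard_normal(2),
            "beta": rng.standard_normal((2, 3)), "lp": rng.standard_normal(2),
        }
        z = np.maximum(m.y.max(axis=2), (rng.random((2, 3)) < 0.5).astype(int))
        total = complete_data_log_posterior(z, state, m, cov=cov, spec=spec)

        X = cov.values()
        p = expit(state["lp"])
        det = occ = 0.0
        for k in range(2):
            for i in range(3):
                psi_ik = occupancy_prob(state["beta0"][k], state["beta"][k], X[i])
                occ += z[k, i] * np.log(psi_ik) + (1 - z[k, i]) * np.log(1 - psi_ik)
                if z[k, i]:
                    for j in range(2):
                        det += m.y[k, i, j] * np.log(p[k]) + (1 - m.y[k, i, j]) * np.log(1 - p[k])
        oracle = det + occ + log_prior_density(state, spec)
        assert total == pytest.approx(oracle, abs=1e-9)
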