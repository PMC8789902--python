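"""Full-conditional correctness, variable selection, and the Gibbs cycle."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import binom, kstest

from edna_occupancy import ModelConfig, PolyaGammaSampler, fit
from edna_occupancy.data_prep import CovariateTable, build_design_matrix
from edna_occupancy.mcmc import (
    _Detections,
    _draw_beta_given_omega,
    log_marginal_given_omega,
    sample_latent_w,
    sample_latent_z,
    update_error_probs,
    update_gamma_ads,
)
from oracles import enumerate_inclusion_posterior, rw_metropolis_logistic


def _det(y, K=12):
    y = np.atleast_1d(y)
    df = pd.DataFrame({"site_id": [f"s{i}" for i in range(len(y))],
                       "sample_id": "a", "k_replicates": K, "y_positive": y})
    return _Detections.from_table(df)


class TestLatentZ:
    def test_certain_occupancy(self):
        det = _det([0, 0, 12])
        rng = np.random.default_rng(0)
        z = sample_latent_z(det, np.ones(3), 0.9, 0.1, 0.8, 0.02, rng)
        assert z.all()

    def test_uninformative_errors_return_prior(self):
        # theta11=theta10 and p11=p10: the data carry no information on z
        det = _det([0, 6, 12])
        rng = np.random.default_rng(1)
        _, prob = sample_latent_z(det, np.full(3, 0.3), 0.5, 0.5, 0.4, 0.4,
                                  rng, return_prob=True)
        np.testing.assert_allclose(prob, 0.3, rtol=1e-12)

    def test_full_conditional_matches_enumeration(self):
        """Brute-force enumeration of both numerator terms, exact binomial pmfs."""
        psi, t11, t10, p11, p10, K, y = 0.2, 0.95, 0.015, 0.8, 0.02, 12, 12
        num1 = psi * (t11 * binom.pmf(y, K, p11) + (1 - t11) * binom.pmf(y, K, p10))
        num0 = (1 - psi) * (t10 * binom.pmf(y, K, p11) + (1 - t10) * binom.pmf(y, K, p10))
        expected = num1 / (num1 + num0)
        det = _det([y])
        rng = np.random.default_rng(2)
        _, prob = sample_latent_z(det, np.array([psi]), t11, t10, p11, p10,
                                  rng, return_prob=True)
        assert prob[0] == pytest.approx(expected, rel=1e-12)
        # sampler frequency agrees within Monte-Carlo error
        hits = np.mean([sample_latent_z(det, np.array([psi]), t11, t10, p11, p10,
                                        rng)[0] for _ in range(4000)])
        assert abs(hits - expected) < 4 * np.sqrt(expected * (1 - expected) / 4000)


class TestLatentW:
    def test_equal_stage2_rates_return_theta(self):
        det = _det([0, 5, 12])
        rng = np.random.default_rng(3)
        _, prob = sample_latent_w(det, np.ones(3), 0.9, 0.1, 0.4, 0.4,
                                  rng, return_prob=True)
        np.testing.assert_allclose(prob, 0.9, rtol=1e-12)

    def test_direct_arithmetic_y0_and_yK(self):
        det = _det([0])
        rng = np.random.default_rng(4)
        _, p0 = sample_latent_w(det, np.ones(1), 0.9, 0.1, 0.8, 0.02,
                                rng, return_prob=True)
        # 0.9*0.2^12 / (0.9*0.2^12 + 0.1*0.98^12)
        assert p0[0] == pytest.approx(4.698e-8, rel=1e-3)
        det = _det([12])
        _, p12 = sample_latent_w(det, np.ones(1), 0.9, 0.1, 0.8, 0.02,
                                 rng, return_prob=True)
        assert p12[0] > 1 - 1e-15


class TestErrorProbUpdates:
    def test_empty_stratum_draws_from_prior(self):
        det = _det([], K=12)
        cfg = ModelConfig(enforce_ordering=False)
        rng = np.random.default_rng(5)
        draws = np.array([update_error_probs(det, np.array([], dtype=bool),
                                             np.array([], dtype=bool), cfg, rng)
                          for _ in range(3000)])
        assert draws[:, 0].mean() == pytest.approx(0.9, abs=0.01)  # Beta(9,1)
        assert draws[:, 1].mean() == pytest.approx(0.1, abs=0.01)  # Beta(1,9)

    def test_prior_recovery_kolmogorov_smirnov(self):
        """With no contributing data, theta/p draws follow their Beta priors."""
        det = _det([], K=12)
        cfg = ModelConfig(enforce_ordering=False)
        rng = np.random.default_rng(6)
        draws = np.array([update_error_probs(det, np.array([], dtype=bool),
                                             np.array([], dtype=bool), cfg, rng)
                          for _ in range(10_000)])
        for idx, (a, b) in [(0, (9, 1)), (1, (1, 9)), (2, (9, 1)), (3, (1, 9))]:
            assert kstest(draws[:, idx], "beta", args=(a, b)).pvalue > 1e-3

    def test_conjugate_arithmetic_full_amplification(self):
        # 100 w=1 samples all at y=K=12: p11 | data ~ Beta(9+1200, 1+0)
        det = _det([12] * 100)
        cfg = ModelConfig(enforce_ordering=False)
        rng = np.random.default_rng(7)
        p11 = np.array([update_error_probs(det, np.ones(100, bool),
                                           np.ones(100, bool), cfg, rng)[2]
                        for _ in range(3000)])
        assert p11.mean() == pytest.approx(1209 / 1210, abs=5e-4)

    def test_p10_posterior_concentration(self):
        # ~10^4 replicate trials at rate 0.02: posterior mean within 0.005
        rng_data = np.random.default_rng(8)
        hits = 0
        for seed in range(10):
            y = rng_data.binomial(12, 0.02, size=850)
            det = _det(y)
            rng = np.random.default_rng(100 + seed)
            p10 = np.mean([update_error_probs(det, np.zeros(850, bool),
                                              np.zeros(850, bool),
                                              ModelConfig(), rng)[3]
                           for _ in range(200)])
            hits += abs(p10 - 0.02) < 0.005
        assert hits >= 9

    def test_ordering_enforced(self):
        det = _det([0, 1, 6, 12])
        rng = np.random.default_rng(9)
        for _ in range(200):
            t11, t10, p11, p10 = update_error_probs(
                det, np.array([0, 0, 1, 1], bool), np.array([0, 0, 1, 1], bool),
                ModelConfig(), rng)
            assert t11 > t10 and p11 > p10


class TestBetaUpdate:
    @staticmethod
    def _gibbs_logistic(X, z, m0, v0, n_iter, seed):
        """PG-Gibbs on fixed binary z: omega | beta, then beta | omega."""
        rng = np.random.default_rng(seed)
        pg = PolyaGammaSampler(seed)
        beta = np.array(m0, dtype=float)
        chain = np.empty((n_iter, X.shape[1]))
        for i in range(n_iter):
            omega = pg.draw(X @ beta)
            beta = _draw_beta_given_omega(z, X, omega, np.asarray(m0, float),
                                          np.asarray(v0, float), rng)
            chain[i] = beta
        return chain[n_iter // 2:]

    def test_intercept_recovers_bernoulli_rate(self):
        rng = np.random.default_rng(10)
        z = rng.random(5000) < 0.3
        X = np.ones((5000, 1))
        chain = self._gibbs_logistic(X, z, [0.0], [4.0], 1200, seed=11)
        assert expit(chain[:, 0].mean()) == pytest.approx(0.3, abs=0.03)

    def test_matches_random_walk_metropolis_reference(self):
        """Same logistic posterior, two unrelated samplers (S=200)."""
        rng = np.random.default_rng(12)
        x = rng.standard_normal(200)
        x = (x - x.mean()) / x.std()
        X = np.column_stack([np.ones(200), x])
        z = rng.random(200) < expit(-0.5 + 1.0 * x)
        m0, v0 = [0.0, 0.0], [4.0, 0.25]
        ours = self._gibbs_logistic(X, z, m0, v0, 8000, seed=13)
        ref = rw_metropolis_logistic(X, z, m0, v0, 60_000,
                                     np.random.default_rng(14), step=0.25)
        for j in range(2):
            se = np.sqrt(ours[:, j].var() / 400 + ref[:, j].var() / 2000)
            assert abs(ours[:, j].mean() - ref[:, j].mean()) < 5 * se
            assert ours[:, j].std() == pytest.approx(ref[:, j].std(), rel=0.15)

    def test_public_update_draws_omega_and_zeroes_inactive_groups(self):
        from edna_occupancy.mcmc import update_beta_polya_gamma
        rng = np.random.default_rng(16)
        df = pd.DataFrame({"site_id": [f"s{i:03d}" for i in range(100)],
                           "a": rng.standard_normal(100),
                           "b": rng.standard_normal(100)})
        design = build_design_matrix(CovariateTable.from_frame(df), ["a", "b"])
        z = rng.random(100) < 0.4
        gamma = np.array([True, False])
        beta, omega = update_beta_polya_gamma(
            z, design, gamma, ModelConfig(), rng, PolyaGammaSampler(17))
        assert beta.shape == (3,) and omega.shape == (100,)
        assert beta[design.groups["b"][0]] == 0.0
        assert beta[design.groups["a"][0]] != 0.0
        assert (omega > 0).all()

    def test_singular_design_raises_helpful_error(self):
        # duplicated columns under an effectively flat prior leave the
        # precision rank-deficient (a proper prior would regularize it)
        X = np.ones((50, 2))
        z = np.zeros(50, bool)
        with pytest.raises(np.linalg.LinAlgError, match="deduplicate"):
            _draw_beta_given_omega(z, X, np.full(50, 0.25), np.zeros(2),
                                   np.array([1e320, 1e320]),
                                   np.random.default_rng(0))


class TestAddDeleteSwap:
    def _setup(self, G=3, S=120, seed=15):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"site_id": [f"s{i}" for i in range(S)],
                           **{f"x{j+1}": rng.standard_normal(S) for j in range(G)}})
        table = CovariateTable.from_frame(df)
        design = build_design_matrix(table, [f"x{j+1}" for j in range(G)])
        z = rng.random(S) < expit(-0.5 + design.X[:, 1])
        omega = np.full(S, 0.25)
        cfg = ModelConfig(expected_num_covariates=1.0)
        return design, z, omega, cfg, rng

    def test_stationary_law_matches_enumeration(self):
        """Empirical ADS stationary distribution vs exhaustive model posterior."""
        design, z, omega, cfg, rng = self._setup()
        exact = enumerate_inclusion_posterior(z, design, omega, cfg,
                                              log_marginal_given_omega)
        gamma = np.zeros(3, dtype=bool)
        counts: dict = {}
        n_moves = 30_000
        for _ in range(n_moves):
            gamma, _ = update_gamma_ads(z, design, gamma, omega, cfg, rng)
            key = tuple(gamma)
            counts[key] = counts.get(key, 0) + 1
        tv = 0.5 * sum(abs(counts.get(k, 0) / n_moves - p) for k, p in exact.items())
        assert tv < 0.03

    def test_whole_groups_move_together(self, small_fit):
        # every draw's dummy block is jointly zero or jointly present
        g = small_fit.group_names.index("landcover")
        cols = small_fit.groups["landcover"]
        excluded = ~small_fit.gamma[:, g]
        assert (small_fit.beta[np.ix_(excluded, cols)] == 0.0).all()


class TestFit:
    def test_determinism_identical_draws(self, small_survey):
        cfg = ModelConfig(n_burn=50, n_iter=100, n_thinned_draws=20, seed=77)
        a = fit(small_survey.detection, design=small_survey.design, config=cfg)
        b = fit(small_survey.detection, design=small_survey.design, config=cfg)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_ordering_invariant_in_every_draw(self, small_fit):
        assert (small_fit.theta11 > small_fit.theta10).all()
        assert (small_fit.p11 > small_fit.p10).all()

    def test_inactive_groups_have_exact_zero_coefficients(self, small_fit):
        for g, name in enumerate(small_fit.group_names):
            cols = small_fit.groups[name]
            inactive = ~small_fit.gamma[:, g]
            assert (small_fit.beta[np.ix_(inactive, cols)] == 0.0).all()

    def test_thinning_count_and_metadata(self, small_fit):
        assert small_fit.n_draws == 200
        assert small_fit.columns[0] == "intercept"

    def test_degenerate_all_zero_data_does_not_error(self):
        df = pd.DataFrame({"site_id": [f"s{i}" for i in range(30)],
                           "sample_id": "a", "k_replicates": 12, "y_positive": 0})
        cfg = ModelConfig(n_burn=100, n_iter=200, n_thinned_draws=50, seed=1)
        d = fit(df, config=cfg)
        # unidentified error rates stay near their priors; occupancy is driven low
        assert d.mean_psi.mean() < 0.2
        assert 0.6 < d.theta11.mean() < 1.0

    def test_design_rows_aligned_to_detection_site_order(self):
        """Detection sites are sorted internally; a design whose rows arrive in
        a different (e.g. non-lexicographic) order must still be matched to
        the right sites — a strong covariate stays recoverable."""
        rng = np.random.default_rng(55)
        S = 400
        ids = [f"s{i}" for i in range(S)]  # sorts s0, s1, s10, s100, ...
        x = rng.standard_normal(S)
        z = rng.random(S) < expit(-1.0 + 2.0 * x)
        w = rng.random(S) < np.where(z, 0.948, 0.015)
        y = rng.binomial(12, np.where(w, 0.808, 0.02))
        det = pd.DataFrame({"site_id": ids, "sample_id": "a",
                            "k_replicates": 12, "y_positive": y})
        table = CovariateTable.from_frame(
            pd.DataFrame({"site_id": ids, "x": x}))
        design = build_design_matrix(table, ["x"])
        cfg = ModelConfig(n_burn=400, n_iter=800, n_thinned_draws=200, seed=3,
                          expected_num_covariates=1)
        draws = fit(det, design=design, config=cfg)
        assert draws.gamma[:, 0].mean() > 0.9
        active = draws.beta[draws.gamma[:, 0], 1]
        assert active.mean() > 1.0  # positive, near the generating slope

    def test_design_with_wrong_sites_raises(self, small_survey):
        design = small_survey.design
        bad = pd.DataFrame({"site_id": [f"other{i}" for i in range(design.n_sites)],
                            "sample_id": "a", "k_replicates": 12, "y_positive": 0})
        with pytest.raises(ValueError, match="missing sites"):
            fit(bad, design=design,
                config=ModelConfig(n_burn=5, n_iter=10, n_thinned_draws=2))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(n_iter=100, n_thinned_draws=200).validate()
        with pytest.raises(ValueError):
            ModelConfig(prior_mean_theta11=1.0).validate()
        with pytest.raises(ValueError):
            ModelConfig(expected_num_covariates=5).validate(n_groups=3)

    def test_serialization_roundtrip(self, small_fit, tmp_path):
        small_fit.write_csv(tmp_path / "draws.csv")
        back = pd.read_csv(tmp_path / "draws.csv")
        assert len(back) == small_fit.n_draws
        np.testing.assert_allclose(back["theta11"], small_fit.theta11)
        assert f"beta_landcover[landcover_L02]" in back.columns or \
            any(c.startswith("beta_landcover[") for c in back.columns)
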