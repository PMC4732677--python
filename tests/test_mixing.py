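import math

import numpy as np
import pytest
from scipy import stats

from beachmix.io import DataError
from beachmix.mixing import (
    SD_FLOOR,
    DietPosterior,
    MCMCConfig,
    MixingModelSpec,
    log_posterior,
    sample_posterior,
    summarize_diet,
)

SHORT_MCMC = MCMCConfig(iterations=6_000, burn_in=1_000, thin=5, seed=7)


def _spec(
    source_means=((-12.0, -17.0, -22.0), (4.0, 7.0, 10.0)),
    source_sd=0.5,
    tef_n=(2.3, 0.3),
    alpha=None,
):
    k = len(source_means[0])
    return MixingModelSpec(
        source_means=np.asarray(source_means, float),
        source_sds=np.full((2, k), source_sd),
        tef_means=np.array([[0.0] * k, [tef_n[0]] * k]),
        tef_sds=np.array([[0.0] * k, [tef_n[1]] * k]),
        alpha=alpha,
    )


class TestLogPosterior:
    def test_matches_independent_density_computation(self):
        """Term-by-term oracle: two Normal log-pdfs + Dirichlet + uniform priors."""
        spec = _spec()
        p = np.array([0.2, 0.5, 0.3])
        resid = np.array([0.8, 1.2])
        consumer = np.array([-16.0, 9.0])

        expected = 0.0
        means = np.asarray(spec.source_means) + np.asarray(spec.tef_means)
        w = np.maximum(
            np.maximum(np.asarray(spec.source_sds), SD_FLOOR) ** 2
            + np.asarray(spec.tef_sds) ** 2,
            SD_FLOOR**2,
        )
        for j in range(2):
            mu = float(p @ means[j])
            sd = math.sqrt(float(p**2 @ w[j]) + resid[j] ** 2)
            expected += stats.norm.logpdf(consumer[j], mu, sd)
        expected += stats.dirichlet.logpdf(p, np.ones(3))
        expected += 2 * math.log(1.0 / spec.resid_sd_bound)

        assert log_posterior(p, resid, consumer, spec) == pytest.approx(expected, rel=1e-12)

    def test_zero_residual_at_mode(self):
        """Single pure source, unit residual SD: both isotopes sit at the mode."""
        spec = _spec(source_sd=0.0, tef_n=(2.3, 0.0))
        consumer = [-12.0 + 0.0, 4.0 + 2.3]
        lp = log_posterior([1.0, 0.0, 0.0], [1.0, 1.0], consumer, spec)
        prior = stats.dirichlet.logpdf([0.5, 0.25, 0.25], np.ones(3)) + 2 * math.log(1 / 20.0)
        # likelihood collapses to 2 * log(1/sqrt(2*pi)) up to the SD floor
        assert lp - prior == pytest.approx(2 * math.log(1 / math.sqrt(2 * math.pi)), abs=1e-3)

    def test_symmetric_source_relabeling(self):
        means = ((-12.0, -12.0, -22.0), (4.0, 4.0, 10.0))
        spec = _spec(source_means=means)
        a = log_posterior([0.3, 0.45, 0.25], [1.0, 1.0], [-15.0, 7.0], spec)
        b = log_posterior([0.45, 0.3, 0.25], [1.0, 1.0], [-15.0, 7.0], spec)
        assert a == pytest.approx(b, rel=1e-12)

    def test_off_simplex_rejected_and_prior_support(self):
        spec = _spec()
        with pytest.raises(DataError):
            log_posterior([0.5, 0.5, 0.5], [1.0, 1.0], [-15.0, 7.0], spec)
        assert log_posterior([0.3, 0.3, 0.4], [25.0, 1.0], [-15.0, 7.0], spec) == -math.inf


class TestSampler:
    def test_retained_draw_count_law(self):
        for it, burn, thin in [(100_000, 10_000, 15), (6_000, 1_000, 5), (100, 0, 7)]:
            cfg = MCMCConfig(iterations=it, burn_in=burn, thin=thin)
            assert cfg.n_retained == (it - burn) // thin

    def test_invalid_schedules_rejected(self):
        with pytest.raises(DataError):
            MCMCConfig(iterations=100, burn_in=100)
        with pytest.raises(DataError):
            MCMCConfig(thin=0)

    def test_simplex_conservation_and_determinism(self):
        spec = _spec()
        a = sample_posterior([-16.0, 8.5], spec, SHORT_MCMC)
        b = sample_posterior([-16.0, 8.5], spec, SHORT_MCMC)
        assert a.n_retained == SHORT_MCMC.n_retained
        assert np.all(a.draws >= 0)
        assert np.allclose(a.draws.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(a.draws, b.draws)

    def test_prior_recovery_uniform_dirichlet(self):
        """With the likelihood disabled the posterior is Dirichlet(1,1,1)."""
        spec = _spec()
        post = sample_posterior(
            [-16.0, 8.5], spec,
            MCMCConfig(iterations=40_000, burn_in=2_000, thin=4, seed=3),
            prior_only=True,
        )
        assert np.allclose(post.mean_proportions, 1.0 / 3.0, atol=0.02)

    def test_exchangeable_sources_get_equal_shares(self):
        means = ((-12.0, -12.0, -22.0), (4.0, 4.0, 10.0))
        spec = _spec(source_means=means, tef_n=(0.0, 0.0))
        post = sample_posterior(
            [-14.0, 5.2], spec,
            MCMCConfig(iterations=60_000, burn_in=5_000, thin=5, seed=4),
        )
        m = post.mean_proportions
        assert abs(m[0] - m[1]) < 0.02

    def test_two_source_posterior_matches_grid_integration(self):
        """Dual-route check: MCMC vs dense trapezoid integration (1 isotope)."""
        m = (0.0, 4.0)
        sigma = 0.5
        resid = 0.7
        consumer = 1.5
        spec = MixingModelSpec(
            source_means=np.array([[m[0], m[1]]]),
            source_sds=np.array([[sigma, sigma]]),
            tef_means=np.zeros((1, 2)),
            tef_sds=np.zeros((1, 2)),
        )
        post = sample_posterior(
            [consumer], spec,
            MCMCConfig(iterations=60_000, burn_in=5_000, thin=10, seed=8),
            fixed_resid_sd=[resid],
        )
        w = max(max(sigma, SD_FLOOR) ** 2, SD_FLOOR**2)
        p1 = np.linspace(0.0, 1.0, 20_001)
        mu = p1 * m[0] + (1 - p1) * m[1]
        var = (p1**2 + (1 - p1) ** 2) * w + resid**2
        ll = -0.5 * (np.log(2 * np.pi * var) + (consumer - mu) ** 2 / var)
        dens = np.exp(ll - ll.max())
        grid_mean = np.trapezoid(p1 * dens, p1) / np.trapezoid(dens, p1)
        assert post.mean_proportions[0] == pytest.approx(grid_mean, abs=0.02)

    def test_initialization_outside_prior_support_raises(self):
        spec = _spec()
        with pytest.raises(RuntimeError, match="initialization"):
            sample_posterior([-16.0, 8.5], spec, SHORT_MCMC, fixed_resid_sd=[25.0, 1.0])


class TestSummaries:
    def _post(self, site, crab, draws):
        draws = np.asarray(draws, float)
        return DietPosterior(
            draws=draws, resid_sd_draws=np.ones((len(draws), 2)),
            consumer_id=crab, site=site,
        )

    def test_single_individual_site_mean(self):
        post = self._post("A", "c1", [[0.2, 0.3, 0.5]] * 10)
        table = summarize_diet([post])
        row = table.iloc[0]
        assert row["mean_p_mole_crab"] == pytest.approx(0.2)
        assert row["mean_p_amphipod"] == pytest.approx(0.3)
        assert row["mean_p_coquina"] == pytest.approx(0.5)

    def test_site_mean_is_mean_over_individuals(self):
        posts = [
            self._post("A", "c1", [[1.0, 0.0, 0.0]] * 5),
            self._post("A", "c2", [[0.0, 1.0, 0.0]] * 5),
        ]
        row = summarize_diet(posts).iloc[0]
        assert row["mean_p_mole_crab"] == pytest.approx(0.5)
        assert row["mean_p_amphipod"] == pytest.approx(0.5)
        assert row["mean_p_coquina"] == 0.0
        assert row["n_consumers"] == 2

    def test_site_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        posts = []
        for i in range(4):
            raw = rng.dirichlet(np.ones(3), size=50)
            posts.append(self._post("A" if i < 2 else "B", f"c{i}", raw))
        table = summarize_diet(posts)
        sums = table[[f"mean_p_{t}" for t in ("mole_crab", "amphipod", "coquina")]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
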