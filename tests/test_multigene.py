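import numpy as np
import pytest
from scipy import stats

from nbdiag.nb_fit import DesignSpec
from nbdiag.nb_models import simulate_nb_arrays
from nbdiag.multigene import (
    CountMatrix,
    fisher_combine,
    fit_global_dispersion,
    moment_dispersion,
    per_gene_gof,
    plot_mean_dispersion,
    trend_exploration,
    uniform_qq,
)
from nbdiag.simstudy import generate_multigene_noise


@pytest.fixture
def design6():
    return DesignSpec(np.ones((6, 1)))


class TestCountMatrix:
    def test_defaults(self):
        cm = CountMatrix(np.array([[1, 2], [3, 4]]))
        np.testing.assert_array_equal(cm.lib_sizes, [4, 6])
        np.testing.assert_array_equal(cm.norm_factors, [1.0, 1.0])

    def test_filter_low_total(self):
        cm = CountMatrix(np.array([[0, 0], [3, 4]]), lib_sizes=np.array([10.0, 10.0]))
        assert cm.filtered().m == 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(np.array([[-1, 2]]))


class TestMomentDispersion:
    def test_hand_value(self):
        # ((100 + 0 + 100) - 60) / 1200
        got = moment_dispersion([10, 20, 30], [20.0, 20.0, 20.0])
        assert got == pytest.approx(140.0 / 1200.0, abs=1e-10)

    def test_poisson_dispersed_gives_zero(self):
        # sum (y - mu)^2 == sum mu exactly
        assert moment_dispersion([9, 11], [10.0, 10.0]) == pytest.approx(
            max(0.0, (1 + 1 - 20) / 200.0)
        ) == 0.0

    def test_all_zero_mu_rejected(self):
        with pytest.raises(ValueError):
            moment_dispersion([1, 2], [0.0, 0.0])

    def test_mean_estimate_tracks_truth(self, rng):
        # NB2 counts at phi = 0.1: the moment estimator averages near truth
        mu = 200.0
        Y = simulate_nb_arrays(mu, 0.1, rng, size=(2000, 10))
        est = np.array([moment_dispersion(y, np.full(10, y.mean())) for y in Y])
        assert abs(est.mean() - 0.1) < 0.02


class TestFisherCombine:
    def test_single_p_round_trips(self):
        X2, p = fisher_combine(np.array([0.5]))
        assert X2 == pytest.approx(-2 * np.log(0.5), abs=1e-4)
        assert p == pytest.approx(0.5, abs=1e-10)

    def test_all_ones(self):
        X2, p = fisher_combine(np.ones(10))
        assert X2 == 0.0
        assert p == pytest.approx(1.0)

    def test_two_pvalues_closed_form(self):
        X2, p = fisher_combine(np.array([0.1, 0.2]))
        assert X2 == pytest.approx(7.8240, abs=1e-4)
        assert p == pytest.approx(np.exp(-X2 / 2) * (1 + X2 / 2), abs=1e-10)

    def test_zero_clipped(self, caplog):
        X2, p = fisher_combine(np.array([0.0, 0.5]), R=999)
        assert np.isfinite(X2)

    def test_moments_match_chi_square(self, rng):
        # X2 on m uniform p-values ~ chi2(2m): mean 2m, variance 4m
        m, reps = 1000, 200
        X2s = np.array([fisher_combine(rng.uniform(size=m))[0] for _ in range(reps)])
        assert abs(X2s.mean() - 2 * m) < 4 * np.sqrt(4 * m / reps)
        assert abs(X2s.var() - 4 * m) < 0.25 * 4 * m


class TestUniformQQ:
    def test_exact_positions_on_diagonal(self):
        m = 20
        pos = (np.arange(1, m + 1) - 0.5) / m
        qq = uniform_qq(pos)
        np.testing.assert_allclose(qq["observed"], qq["theoretical"])

    def test_uniform_draws_within_ks_band(self, rng):
        m = 1000
        qq = uniform_qq(rng.uniform(size=m))
        crit = 1.63 / np.sqrt(m)  # KS 1% critical value
        assert np.max(np.abs(qq["observed"] - qq["theoretical"])) < crit

    def test_conservative_pvalues_sit_above_diagonal(self):
        qq = uniform_qq(np.linspace(0.6, 1.0, 50))
        assert (qq["observed"] > qq["theoretical"]).all()


class TestGlobalDispersion:
    @pytest.mark.parametrize("n,rel", [(6, 0.10), (30, 0.05)])
    def test_common_recovery(self, rng, n, rel):
        """The common-dispersion fit (joint ML with the first-order
        degrees-of-freedom adjustment) recovers the generating value; at
        n = 6 a second-order bias residual of a few percent remains."""
        cm = generate_multigene_noise(
            500, n, trend=(np.log(0.1), 0.0), sigma=0.0, rng=rng, pi_range=(1e-5, 3e-3)
        )
        g = fit_global_dispersion(cm, DesignSpec(np.ones((n, 1))), "common")
        assert np.exp(g.alpha[0]) == pytest.approx(0.1, rel=rel)

    def test_nesting_of_summed_loglik(self, design6, rng):
        cm = generate_multigene_noise(
            300, 6, trend=(-1.5, -0.7, -0.1), sigma=0.3, rng=rng, pi_range=(1e-5, 3e-3)
        )
        lls = {
            k: fit_global_dispersion(cm, design6, k).log_likelihood
            for k in ("common", "nbp", "nbq")
        }
        assert lls["nbq"] >= lls["nbp"] - 1e-4
        assert lls["nbp"] >= lls["common"] - 1e-4

    def test_nbq_with_zero_curvature_matches_nbp(self, design6, rng):
        cm = generate_multigene_noise(
            200, 6, trend=(-4.0, -0.3), sigma=0.0, rng=rng, pi_range=(1e-5, 3e-3)
        )
        gp = fit_global_dispersion(cm, design6, "nbp")
        # NBQ solution must weakly improve on NBP and be close when the
        # generating curvature is zero
        gq = fit_global_dispersion(cm, design6, "nbq")
        assert gq.log_likelihood >= gp.log_likelihood - 1e-3
        assert abs(gq.alpha[2]) < 0.1

    def test_genewise_matches_single_gene_mle(self, design6, rng):
        cm = generate_multigene_noise(
            40, 6, trend=(np.log(0.2), 0.0), sigma=0.0, rng=rng, pi_range=(1e-4, 1e-3)
        )
        g = fit_global_dispersion(cm, design6, "genewise")
        assert g.phi_gene.shape == (cm.filtered().m,)
        assert np.all(g.phi_gene >= 0)

    def test_trended_needs_enough_genes(self, design6, rng):
        cm = generate_multigene_noise(30, 6, rng=rng)
        with pytest.raises(ValueError):
            fit_global_dispersion(cm, design6, "trended")

    def test_trended_tracks_trend(self, design6, rng):
        cm = generate_multigene_noise(
            800, 6, trend=(-4.0, -0.3), sigma=0.2, rng=rng, pi_range=(1e-5, 3e-3)
        )
        g = fit_global_dispersion(cm, design6, "trended")
        lp = np.linspace(np.log(2e-5), np.log(2e-3), 7)
        np.testing.assert_allclose(g.trend(lp), -4.0 - 0.3 * lp, atol=0.8)

    def test_plugin_requires_values(self, design6, rng):
        cm = generate_multigene_noise(60, 6, rng=rng)
        with pytest.raises(ValueError):
            fit_global_dispersion(cm, design6, "plugin")


class TestPerGeneGOF:
    def test_subsample_deterministic_and_identity_at_full_size(self, design6, rng):
        cm = generate_multigene_noise(
            60, 6, trend=(np.log(0.1), 0.0), sigma=0.0, rng=rng, pi_range=(1e-4, 1e-3)
        )
        g = fit_global_dispersion(cm, design6, "common")
        a = per_gene_gof(cm, design6, g, m_star=20, R=39, seed=5)
        b = per_gene_gof(cm, design6, g, m_star=20, R=39, seed=5)
        assert a.gene_subset == b.gene_subset
        np.testing.assert_array_equal(a.p_values, b.p_values)
        full = per_gene_gof(cm, design6, g, m_star=cm.filtered().m, R=39, seed=5)
        assert full.gene_subset == cm.filtered().gene_ids

    def test_null_calibration_from_fitted_model(self, design6, rng):
        """Data regenerated from the fitted common model: the per-gene
        p-values behave uniformly (one-sided anti-conservatism bound at
        the binomial 3-SE half-width)."""
        cm0 = generate_multigene_noise(
            1000, 6, trend=(np.log(0.1), 0.0), sigma=0.0, rng=rng, pi_range=(1e-5, 3e-3)
        )
        g0 = fit_global_dispersion(cm0, design6, "common")
        mu = np.exp(g0.beta @ design6.X.T + cm0.offset)
        cm1 = CountMatrix(
            simulate_nb_arrays(mu, np.exp(g0.alpha[0]), rng), lib_sizes=cm0.lib_sizes
        )
        res = per_gene_gof(cm1, design6, g0, m_star=400, R=199, seed=17)
        frac = (res.p_values <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 400)
        assert frac <= 0.05 + 3 * se
        ks = stats.kstest(res.p_values, "uniform")
        assert ks.pvalue > 0.01


class TestTrendExploration:
    def test_strong_trend_detected_and_permutation_null(self, design6, rng):
        cm = generate_multigene_noise(
            2000, 6, trend=(-1.5, -0.7, -0.1), sigma=0.0, rng=rng, pi_range=(1e-5, 3e-3)
        )
        rep = trend_exploration(cm, design6)
        assert rep.loc[rep["degree"] == 1, "pct_explained"].iloc[0] > 30.0
        assert rep.loc[rep["degree"] == 2, "top_term_p"].iloc[0] < 0.05

    def test_shuffled_dispersion_explains_nothing(self, design6, rng):
        # pure-noise dispersions: no trend to find
        cm = generate_multigene_noise(
            1500, 6, trend=(np.log(0.15), 0.0), sigma=0.7, rng=rng, pi_range=(1e-5, 3e-3)
        )
        rep = trend_exploration(cm, design6)
        assert rep.loc[rep["degree"] == 1, "pct_explained"].iloc[0] < 5.0

    def test_too_few_positive_dispersions(self, design6, rng):
        cm = generate_multigene_noise(60, 6, rng=rng)
        with pytest.raises(ValueError):
            trend_exploration(cm, design6)

    def test_mean_dispersion_plot_written(self, design6, rng, tmp_path):
        cm = generate_multigene_noise(
            400, 6, trend=(-4.0, -0.3), sigma=0.3, rng=rng, pi_range=(1e-5, 3e-3)
        )
        fits = [fit_global_dispersion(cm, design6, k) for k in ("common", "nbp", "trended")]
        out = tmp_path / "fig.png"
        plot_mean_dispersion(cm, design6, fits, out)
        assert out.exists() and out.stat().st_size > 0
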