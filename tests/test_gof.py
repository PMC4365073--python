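import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nbdiag.nb_fit import DesignSpec, DispersionModel
from nbdiag.gof import (
    empirical_probability_plot,
    envelope,
    gof_test,
    mc_pvalue,
    pearson_stat,
    vertical_distance_stat,
)
from nbdiag.nb_models import simulate_nb_arrays


class TestMonteCarloPvalue:
    def test_hand_count(self):
        # R=4, sims {5,1,7,3}, obs 4 -> (2+1)/5
        assert mc_pvalue([5, 1, 7, 3], 4.0) == pytest.approx(0.6)

    def test_extremes(self):
        sims = np.arange(999, dtype=float)
        assert mc_pvalue(sims, 1e9) == pytest.approx(1 / 1000)
        assert mc_pvalue(sims, 0.0) == pytest.approx(1.0)

    def test_matches_rank_oracle(self, rng):
        # brute-force oracle: p = (R + 1 - strict_rank(obs)) / (R + 1)
        for _ in range(100):
            R = int(rng.integers(5, 60))
            sims = rng.normal(size=R) ** 2
            obs = rng.normal() ** 2
            rank_strict = int(np.sum(np.sort(sims) < obs))
            oracle = (R + 1 - rank_strict) / (R + 1)
            assert mc_pvalue(sims, obs) == pytest.approx(oracle)


class TestStatistics:
    def test_vertical_distance_hand_values(self):
        assert vertical_distance_stat([1.0, 2.0], [0.0, 0.0]) == pytest.approx(5.0)
        assert vertical_distance_stat([1.0, 2.0], [1.0, 2.0]) == pytest.approx(0.0)

    def test_vertical_distance_sorts_input(self):
        assert vertical_distance_stat([2.0, 1.0], [1.0, 2.0]) == pytest.approx(0.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            vertical_distance_stat([1.0], [1.0, 2.0])

    def test_pearson_stat(self):
        assert pearson_stat([3.0, 4.0]) == pytest.approx(25.0)
        assert pearson_stat(np.zeros(5)) == 0.0

    def test_pearson_is_vertical_distance_about_zero(self, rng):
        r = rng.normal(size=30)
        assert pearson_stat(r) == pytest.approx(
            vertical_distance_stat(r, np.zeros(30))
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=30), st.floats(1.01, 4.0))
    def test_pearson_monotone_under_inflation(self, r, c):
        r = np.asarray(r)
        assert pearson_stat(c * r) >= pearson_stat(r)


class TestEnvelope:
    def test_identical_rows_collapse(self):
        S = np.tile(np.linspace(-2, 2, 10), (50, 1))
        env = envelope(S)
        np.testing.assert_allclose(env.lower, env.upper)
        np.testing.assert_allclose(env.median, S[0])

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            envelope(np.random.default_rng(0).normal(size=(20, 5)))

    def test_band_ordering_and_containment(self, rng):
        S = np.sort(rng.normal(size=(300, 40)), axis=1)
        env = envelope(S)
        assert np.all(env.lower <= env.median)
        assert np.all(env.median <= env.upper)
        assert np.all(env.sim_lower <= env.lower)
        assert np.all(env.sim_upper >= env.upper)

    def test_pointwise_coverage_on_fresh_replicates(self, rng):
        # about 95% of ordered residuals from fresh null replicates fall
        # inside the pointwise envelope
        n = 45
        S = np.sort(rng.normal(size=(999, n)), axis=1)
        env = envelope(S)
        fresh = np.sort(rng.normal(size=(500, n)), axis=1)
        inside = ((fresh >= env.lower) & (fresh <= env.upper)).mean()
        assert abs(inside - 0.95) < 0.03

    def test_simultaneous_coverage_on_fresh_replicates(self, rng):
        n = 45
        S = np.sort(rng.normal(size=(999, n)), axis=1)
        env = envelope(S)
        fresh = np.sort(rng.normal(size=(500, n)), axis=1)
        whole = np.all((fresh >= env.sim_lower) & (fresh <= env.sim_upper), axis=1)
        assert whole.mean() >= 0.95 - 0.03

    def test_max_deviation_variant(self, rng):
        S = np.sort(rng.normal(size=(200, 20)), axis=1)
        env = envelope(S, method="max-deviation")
        inside = np.all((S >= env.sim_lower) & (S <= env.sim_upper), axis=1)
        assert inside.mean() >= 0.95


class TestGofTest:
    def test_deterministic_given_seed(self, rng):
        n = 45
        d = DesignSpec(np.column_stack([np.ones(n), np.linspace(4.5, 9.1, n)]))
        mu = np.exp(d.X @ np.array([20.7, -2.3]))
        y = simulate_nb_arrays(mu, 0.05, rng)
        a = gof_test(y, d, DispersionModel("nb2"), R=99, seed=4)
        b = gof_test(y, d, DispersionModel("nb2"), R=99, seed=4)
        assert a.p_vert == b.p_vert
        assert a.p_pearson == b.p_pearson
        np.testing.assert_array_equal(a.stat_vert_sim, b.stat_vert_sim)

    def test_observed_quantities_invariant_to_row_order(self, rng):
        n = 45
        d = DesignSpec(np.column_stack([np.ones(n), np.linspace(4.5, 9.1, n)]))
        mu = np.exp(d.X @ np.array([20.7, -2.3]))
        y = simulate_nb_arrays(mu, 0.05, rng)
        perm = rng.permutation(n)
        d2 = DesignSpec(d.X[perm])
        a = gof_test(y, d, DispersionModel("nb2"), R=99, seed=4)
        b = gof_test(y[perm], d2, DispersionModel("nb2"), R=99, seed=4)
        np.testing.assert_allclose(a.r_obs, b.r_obs, atol=1e-8)
        assert a.stat_pearson_obs == pytest.approx(b.stat_pearson_obs, rel=1e-8)
        # Monte Carlo p-values agree up to resampling noise
        assert abs(a.p_vert - b.p_vert) < 0.15

    def test_r_too_small_rejected(self, study_design, study_mu, rng):
        y = simulate_nb_arrays(study_mu, 0.1, rng)
        with pytest.raises(ValueError):
            gof_test(y, study_design, DispersionModel("nb2"), R=10, seed=0)


class TestProbabilityPlot:
    def _fit3_outlier_case(self, rng):
        # log-linear structure with 45 points; NB2 counts with three of the
        # 45 responses doubled, which should push residuals out of the band
        n = 45
        d = DesignSpec(np.column_stack([np.ones(n), np.linspace(4.5, 9.1, n)]))
        mu = np.exp(d.X @ np.array([20.7, -2.3]))
        y = simulate_nb_arrays(mu, 0.1, rng)
        pos = rng.choice(n, size=3, replace=False)
        y[pos] *= 2
        return y, d

    def test_outliers_flagged_and_plot_written(self, rng, tmp_path):
        y, d = self._fit3_outlier_case(rng)
        res = gof_test(y, d, DispersionModel("nb2"), R=199, seed=9)
        flags = res.envelope.flags
        assert (flags != "inside").sum() >= 1
        out = tmp_path / "plot.png"
        empirical_probability_plot(res, out)
        assert out.exists() and out.stat().st_size > 0

    def test_well_fitting_data_mostly_inside(self, rng, tmp_path):
        n = 45
        d = DesignSpec(np.column_stack([np.ones(n), np.linspace(4.5, 9.1, n)]))
        mu = np.exp(d.X @ np.array([20.7, -2.3]))
        y = simulate_nb_arrays(mu, 0.05, rng)
        res = gof_test(y, d, DispersionModel("nb2"), R=199, seed=9)
        # a correctly specified model leaves the bulk of ordered residuals
        # inside the envelope (a whole-vector excursion has ~5% probability)
        assert (res.envelope.flags == "inside").mean() > 0.85
        assert res.p_vert > 0.05
        # envelope table round-trips flags
        df = res.envelope.to_frame()
        assert (df["flag"] != "inside").sum() == (res.envelope.flags != "inside").sum()
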