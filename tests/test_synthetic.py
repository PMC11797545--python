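"""The synthetic cohort generator: distributional laws, truth recovery,
determinism."""

import numpy as np
import pytest
from scipy import stats

from otodem import (SimulationConfig, length_from_otolith, sample_ages,
                    simulate_cohort, simulate_isotopes, simulate_lengths,
                    simulate_otolith_width, simulate_scenario, vb_length)


class TestSampleAges:
    def test_high_z_collapses_to_recruit_age(self, rng):
        ages = sample_ages(200, 50.0, recruit_age=6, max_age=30, rng=rng)
        assert (ages == 6).all()

    def test_truncated_geometric_proportions(self, rng):
        """Z = ln 2 on ages 9-13 gives proportions 32:16:8:4:2."""
        n = 200_000
        ages = sample_ages(n, np.log(2), recruit_age=9, max_age=13, rng=rng)
        w = 2.0 ** -np.arange(5)
        expected = n * w / w.sum()
        observed = np.bincount(ages, minlength=14)[9:14]
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=4) > 0.01

    def test_mean_matches_analytic_expectation(self, rng):
        Z, n = 0.2, 10_000
        ages = sample_ages(n, Z, recruit_age=6, max_age=30, rng=rng)
        t = np.arange(0, 25)
        p = np.exp(-Z * t) / np.exp(-Z * t).sum()
        mean_t, var_t = (p * t).sum(), (p * t**2).sum() - (p * t).sum() ** 2
        se = np.sqrt(var_t / n)
        assert abs((ages - 6).mean() - mean_t) < 3 * se

    def test_age_law_goodness_of_fit_large_n(self, rng):
        """Chi-square GOF of 1e5 draws against the truncated exponential."""
        n, Z = 100_000, 0.3
        ages = sample_ages(n, Z, recruit_age=6, max_age=30, rng=rng)
        support = np.arange(6, 31)
        w = np.exp(-Z * (support - 6))
        expected = n * w / w.sum()
        observed = np.bincount(ages, minlength=31)[6:31]
        keep = expected >= 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        assert stats.chi2.sf(chi2, df=keep.sum() - 1) > 0.01

    def test_argument_validation(self, rng):
        with pytest.raises(ValueError):
            sample_ages(0, 0.2, rng=rng)
        with pytest.raises(ValueError):
            sample_ages(10, -0.1, rng=rng)


class TestSimulateLengths:
    def test_noiseless_baseline(self, rng):
        assert simulate_lengths([9.0], G_true=1.0, length_cv=0.0,
                                rng=rng)[0] == pytest.approx(90.40, abs=0.005)

    def test_noiseless_slow_growth(self, rng):
        assert simulate_lengths([9.0], G_true=0.8, length_cv=0.0,
                                rng=rng)[0] == pytest.approx(72.32, abs=0.005)

    def test_round_trip_growth_index(self, rng):
        from otodem import growth_index
        ages = np.arange(3, 20, dtype=float)
        L = simulate_lengths(ages, G_true=1.0, length_cv=0.0, rng=rng)
        assert np.allclose(growth_index(L, ages), 1.0)

    def test_negative_cv_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_lengths([9.0], length_cv=-0.1, rng=rng)


class TestSimulateOtolithWidth:
    def test_exact_inverse_at_modern_growth(self, rng):
        w = simulate_otolith_width([80.0], G_true=1.0, otolith_noise_cv=0.0,
                                   rng=rng)
        assert length_from_otolith(w[0]) == pytest.approx(80.0, rel=1e-12)

    def test_slow_growth_bias_is_7_7_percent(self, rng):
        w = simulate_otolith_width([80.0], G_true=0.8, otolith_noise_cv=0.0,
                                   rng=rng)
        # (1 + 0.279*0.2)**1.366 = 1.077
        assert length_from_otolith(w[0]) == pytest.approx(86.16, abs=0.01)

    def test_gamma_zero_switches_bias_off(self, rng):
        w = simulate_otolith_width([80.0], G_true=0.6, gamma=0.0,
                                   otolith_noise_cv=0.0, rng=rng)
        assert length_from_otolith(w[0]) == pytest.approx(80.0, rel=1e-12)


class TestSimulateIsotopes:
    def test_reference_at_reference_temperature(self, rng):
        assert simulate_isotopes([5.0], 3.5, t_ref=5.0, rng=rng)[0] == 3.5

    @pytest.mark.parametrize("dT, ddelta", [(1.38, -0.29), (2.4, -0.50)])
    def test_warming_lowers_d18o(self, dT, ddelta, rng):
        d = simulate_isotopes([5.0 + dT], 3.5, t_ref=5.0, rng=rng)[0]
        assert d - 3.5 == pytest.approx(ddelta, abs=0.005)


class TestSimulateCohort:
    def test_seeded_runs_bitwise_identical(self):
        cfg = SimulationConfig(n_fish=300, Z_true=0.3, seed=77)
        df1, t1 = simulate_cohort(cfg)
        df2, t2 = simulate_cohort(cfg)
        assert df1.equals(df2)
        assert t1.age_counts == t2.age_counts

    def test_chapman_robson_recovers_z(self):
        from otodem import build_age_composition, chapman_robson_z
        cfg = SimulationConfig(n_fish=5000, Z_true=0.2, seed=42,
                               recruit_age=9, max_age=40)
        df, _ = simulate_cohort(cfg)
        comp = build_age_composition(df["age"].to_numpy(), min_age=9)
        assert abs(chapman_robson_z(comp).Z - 0.2) < 0.05

    def test_growth_multiplier_recovered(self):
        from otodem import growth_index
        cfg = SimulationConfig(n_fish=600, Z_true=0.2, seed=7, G_true=0.8,
                               length_cv=0.05)
        df, _ = simulate_cohort(cfg)
        G = growth_index(df["true_length"].to_numpy(), df["age"].to_numpy())
        assert 0.78 <= G.mean() <= 0.82

    def test_noiseless_round_trip_is_identity(self, noiseless_cohort):
        """With gamma known and no noise, back-calculation plus correction
        reproduces the true lengths to numerical precision."""
        from otodem import apply_bias_correction
        df, truth = noiseless_cohort
        est = length_from_otolith(df["otolith_width"].to_numpy())
        corrected = est / (1.0 + 0.279 * (1 - truth.G_true)) ** 1.366
        assert np.allclose(corrected, df["true_length"], rtol=1e-10)
        # the linear bias model is an approximation of the same factor
        approx = apply_bias_correction(est, truth.G_true)
        assert np.allclose(approx, df["true_length"], rtol=1e-3)

    def test_ageing_error_keeps_ages_positive(self):
        cfg = SimulationConfig(n_fish=2000, Z_true=0.5, seed=13,
                               apply_ageing_error=True)
        df, _ = simulate_cohort(cfg)
        assert (df["age"] >= 1).all()
        # reader CV < 3.8%: most ages unchanged after rounding
        assert (df["age"] == df["true_age"]).mean() > 0.5

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_fish=0, Z_true=0.2, seed=1)
        with pytest.raises(ValueError):
            SimulationConfig(n_fish=10, Z_true=0.0, seed=1)
        with pytest.raises(ValueError):
            SimulationConfig(n_fish=10, Z_true=0.2, seed=1, G_true=1.6)
        with pytest.raises(ValueError):
            SimulationConfig(n_fish=10, Z_true=0.2, seed=1, recruit_age=30,
                             max_age=30)


class TestSimulateScenario:
    def test_truth_vectors_aligned(self):
        recs, truth = simulate_scenario([4.0, 351.0], n_per_period=50, seed=1)
        assert len(truth.labels) == len(truth.Z_true) == 2
        assert truth.Z_true[0] == pytest.approx(0.19 + 0.0015 * 4)
        assert set(recs["century"]) == {10, 11}

    def test_isotope_column_added(self):
        recs, _ = simulate_scenario([4.0, 351.0], n_per_period=50, seed=1,
                                    temperature_by_period=(5.0, 6.0))
        assert "delta18O" in recs.columns
        assert recs["delta18O"].notna().all()
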