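"""Observables and the two fitting procedures."""

import numpy as np
import pytest

import senodyn as sd
from senodyn.fitting import initial_guess_from_data, multi_curve_objective
from senodyn.synthetic import NoiseSpec, generate_growth_experiment, generate_msc_experiment

NOISELESS = NoiseSpec(cpd_sd=0.0, fraction_mode="gaussian", fraction_sd=0.0)


class TestCPD:
    def test_basic_values(self):
        assert sd.cpd_from_counts(800, 100) == pytest.approx(3.0)
        assert sd.cpd_from_counts(42.0, 42.0) == 0.0
        # total of the delta=0, N=2 recursion at k=3 is 6
        assert sd.cpd_from_counts(6, 1) == pytest.approx(np.log2(6))

    def test_positive_counts_required(self):
        with pytest.raises(ValueError):
            sd.cpd_from_counts(0.0, 1.0)
        with pytest.raises(ValueError):
            sd.cpd_from_counts(1.0, -2.0)


class TestPredictCurves:
    def test_reduces_to_homeostatic_for_pure_csc_homeostasis(self):
        params = sd.HierarchicalParams(0.0, 6, 0.0, 0.8, csc_fraction_0=1.0)
        days = np.linspace(0, 30, 40)
        cpd, frac = sd.predict_curves(params, days)
        expected = sd.homeostatic_cpd(6, 0.8, days)
        np.testing.assert_allclose(cpd, expected, rtol=1e-12, atol=1e-12)

    def test_day_zero_baseline(self, melanoma_params):
        cpd, frac = sd.predict_curves(melanoma_params, [0.0])
        assert cpd[0] == pytest.approx(0.0, abs=1e-12)
        assert frac[0] == pytest.approx(0.0, abs=1e-12)

    def test_interior_senescence_peak_for_small_csc_fraction(self):
        params = sd.HierarchicalParams(
            0.15, 100, 0.05, 1.1, csc_fraction_0=0.002
        )
        days = np.linspace(0, 140, 281)
        _, frac = sd.predict_curves(params, days)
        peak_day = days[int(np.argmax(frac))]
        assert 80 <= peak_day <= 100
        sen_inf, _ = sd.asymptotic_fractions(params)
        assert frac.max() > sen_inf  # true interior maximum, declining after
        assert frac[-1] < frac.max()

    def test_matches_recursion_at_integer_generations(self, melanoma_params):
        params = sd.HierarchicalParams(0.2, 8, 0.1, 1.0, csc_fraction_0=0.3)
        days = np.arange(0.0, 31.0)
        cpd, frac = sd.predict_curves(params, days)
        tr = sd.simulate_trajectory(params, k_max=30)
        np.testing.assert_allclose(cpd, tr.cpd, rtol=1e-10)
        np.testing.assert_allclose(frac, tr.senescent_fraction, rtol=1e-10)


class TestObjective:
    def _datasets(self):
        params = sd.HierarchicalParams(0.15, 50, 0.05, 1.0)
        return generate_growth_experiment(
            params, (0.05, 0.002), days=np.arange(0.0, 80.0, 4.0), noise=NOISELESS
        ), params

    def test_zero_residuals_at_the_generating_parameters(self):
        datasets, params = self._datasets()
        theta = [0.15, 50.0, 0.05, 1.0, 0.05, 0.002]
        residuals, chi2 = multi_curve_objective(theta, datasets)
        assert chi2 == pytest.approx(0.0, abs=1e-18)
        assert np.allclose(residuals, 0.0)

    def test_chi2_invariant_to_dataset_ordering(self):
        datasets, _ = self._datasets()
        theta_fwd = [0.2, 40.0, 0.1, 0.9, 0.03, 0.01]
        theta_rev = [0.2, 40.0, 0.1, 0.9, 0.01, 0.03]
        _, chi2_fwd = multi_curve_objective(theta_fwd, datasets)
        _, chi2_rev = multi_curve_objective(theta_rev, datasets[::-1])
        assert chi2_fwd == pytest.approx(chi2_rev, rel=1e-12)

    def test_single_curve_equals_plain_least_squares(self):
        datasets, _ = self._datasets()
        ds = datasets[0]
        theta = [0.2, 40.0, 0.1, 0.9, 0.03]
        residuals, chi2 = multi_curve_objective(theta, [ds])
        cpd_m, frac_m = sd.predict_curves(
            sd.HierarchicalParams(0.2, 40, 0.1, 0.9, csc_fraction_0=0.03), ds.days
        )
        direct = np.sum((cpd_m - ds.cpd) ** 2) + np.sum(
            (frac_m - ds.senescent_fraction) ** 2
        )
        assert chi2 == pytest.approx(direct, rel=1e-9)

    def test_contract_violations(self):
        datasets, _ = self._datasets()
        with pytest.raises(ValueError, match="dataset"):
            multi_curve_objective([0.1], [])
        with pytest.raises(ValueError, match="weights"):
            multi_curve_objective(
                [0.1, 10, 0.1, 1.0, 0.1, 0.1], datasets, weights={"cpd": 0, "fraction": 0}
            )
        with pytest.raises(ValueError, match="free parameters"):
            multi_curve_objective([0.1, 10.0], datasets)


class TestJointFit:
    def test_noise_free_exact_recovery(self):
        params = sd.HierarchicalParams(0.15, 60, 0.05, 1.0)
        datasets = generate_growth_experiment(
            params, (0.05, 0.002), days=np.arange(0.0, 100.0, 3.5), noise=NOISELESS
        )
        res = sd.fit_model(datasets, n_restarts=4, seed=0)
        assert res.chi2 < 1e-10
        assert res.parameters["delta"] == pytest.approx(0.15, abs=1e-4)
        assert res.parameters["n_senescence"] == pytest.approx(60, abs=0.05)
        assert res.parameters["division_rate"] == pytest.approx(1.0, abs=1e-4)

    def test_noisy_recovery_within_three_se(self, melanoma_params):
        datasets = generate_growth_experiment(
            melanoma_params,
            (0.05, 0.002),
            noise=NoiseSpec(cpd_sd=0.2, cells_scored=200, seed=21),
        )
        res = sd.fit_model(datasets, n_restarts=8, seed=2)
        truth = {
            "delta": 0.15,
            "n_senescence": 100,
            "death_prob": 0.05,
            "division_rate": 1.1,
            "f[f=0.05]": 0.05,
            "f[f=0.002]": 0.002,
        }
        for name, true_val in truth.items():
            est, se = res.parameters[name], res.stderr[name]
            assert se > 0
            assert abs(est - true_val) <= 3 * se, name

    def test_reduced_chi2_near_one_for_correct_gaussian_noise(self, melanoma_params):
        datasets = generate_growth_experiment(
            melanoma_params,
            (0.05, 0.002),
            noise=NoiseSpec(
                cpd_sd=0.2, fraction_mode="gaussian", fraction_sd=0.02, seed=5
            ),
        )
        res = sd.fit_model(datasets, n_restarts=6, seed=3)
        assert 0.5 <= res.reduced_chi2 <= 1.5

    def test_fixed_parameters_are_pinned(self, melanoma_params):
        datasets = generate_growth_experiment(
            melanoma_params, (0.05, 0.002), noise=NoiseSpec(cpd_sd=0.2, seed=9)
        )
        res = sd.fit_model(
            datasets, fixed={"death_prob": 0.05}, n_restarts=6, seed=0
        )
        assert res.parameters["death_prob"] == 0.05
        assert "death_prob" not in res.stderr
        assert res.n_free == 5

    def test_heuristic_initial_guess_is_sane(self, melanoma_params):
        datasets = generate_growth_experiment(
            melanoma_params, (0.05, 0.002), noise=NoiseSpec(cpd_sd=0.2, seed=4)
        )
        guess = initial_guess_from_data(datasets)
        assert 0.5 < guess["division_rate"] < 2.0
        assert 50 < guess["n_senescence"] < 200
        assert -0.2 < guess["delta"] < 0.6


class TestHomeostaticFit:
    def test_noise_free_recovery(self):
        ds = generate_msc_experiment(20, 0.9, noise=NOISELESS)
        res = sd.fit_homeostatic(ds, n_restarts=4, seed=0)
        assert res.parameters["n_senescence"] == pytest.approx(20.0, abs=1e-3)
        assert res.parameters["division_rate"] == pytest.approx(0.9, abs=1e-4)

    def test_noisy_recovery_within_three_se(self):
        days = np.linspace(0.0, 60.0, 25)
        ds = generate_msc_experiment(
            20, 0.9, days=days, noise=NoiseSpec(cpd_sd=0.3, seed=8)
        )
        res = sd.fit_homeostatic(ds, seed=1)
        for name, true_val in (("n_senescence", 20.0), ("division_rate", 0.9)):
            assert abs(res.parameters[name] - true_val) <= 3 * res.stderr[name]

    def test_unflattened_curve_flags_unidentifiable_senescence(self):
        # pure exponential CPD: the senescence crossover never happens
        days = np.linspace(0.0, 30.0, 12)
        ds = sd.GrowthDataset("exp", days=days, cpd=0.7 * days)
        res = sd.fit_homeostatic(ds, seed=0)
        assert any("not identifiable" in f for f in res.flags)

    def test_too_few_points_rejected(self):
        ds = sd.GrowthDataset("tiny", days=[0, 1], cpd=[0.0, 1.0])
        with pytest.raises(ValueError, match="3 points"):
            sd.fit_homeostatic(ds)

    def test_covariance_consistent_with_t_statistics(self):
        ds = generate_msc_experiment(
            15, 0.8, noise=NoiseSpec(cpd_sd=0.2, seed=3)
        )
        res = sd.fit_homeostatic(ds, seed=0)
        for i, name in enumerate(res.param_names[: res.n_free]):
            se = np.sqrt(res.covariance[i, i])
            assert res.stderr[name] == pytest.approx(se, rel=1e-9)
            assert res.t_statistics[name] == pytest.approx(
                res.parameters[name] / se, rel=1e-9
            )


class TestInitialConditionRobustness:
    def test_predictions_weakly_depend_on_initial_age_profile(self, melanoma_params):
        """Uniform-age and steady-state-age CC initializations give nearly
        the same observable curves for the melanoma-like parameters."""
        from senodyn.fitting import initial_condition_robustness

        params = sd.HierarchicalParams(0.15, 100, 0.05, 1.1, csc_fraction_0=0.002)
        days = np.arange(0.0, 141.0, 3.5)
        diff = initial_condition_robustness(params, days)
        cpd_scale = np.abs(sd.predict_curves(params, days)[0]).max()
        assert diff["max_cpd_difference"] / cpd_scale < 0.05
        # the senescence curves re-converge once the transient has passed
        assert diff["final_fraction_difference"] < 0.01

    def test_steady_state_profile_is_normalized_and_age_increasing(self):
        from senodyn.fitting import steady_state_age_profile

        profile = steady_state_age_profile(sd.HierarchicalParams(0.2, 10, 0.1))
        assert profile.sum() == pytest.approx(1.0)
        assert np.all(np.diff(profile) > 0)  # older cohorts are larger for delta < 1
        truncated = steady_state_age_profile(
            sd.HierarchicalParams(0.2, 10, 0.1), n_ages=4
        )
        assert truncated[4:].sum() == 0.0
        assert truncated.sum() == pytest.approx(1.0)
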