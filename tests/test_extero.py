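"""Exteroceptive scoring: body image, race model, psychometric estimators."""

import numpy as np
import pytest
from scipy import stats

import interobattery as ib
from interobattery.extero import (
    Z75,
    BodyImageInput,
    GaussianFit,
    PsychometricTable,
    RtConditionTable,
)

BMI_MAP = (16.0, 18.0, 20.0, 22.0, 24.0, 25.0, 27.0, 29.0, 33.0, 38.0)


class TestBodyImage:
    def test_real_bmi_formula(self):
        inp = BodyImageInput(70.0, 1.75, BMI_MAP, (0,))
        # hand evaluation: 70 / 1.75^2 = 22.857...; delta = 16 - that
        assert inp.weight / inp.height**2 == pytest.approx(22.857142857)
        assert ib.body_image_delta(inp) == pytest.approx(16.0 - 22.857142857)

    def test_matching_perception_gives_zero(self):
        inp = BodyImageInput(weight=25.0 * 1.0**2, height=1.0,
                             silhouette_bmi_values=BMI_MAP,
                             perceived_actual_ratings=(5,))
        assert ib.body_image_delta(inp) == pytest.approx(0.0)

    def test_mean_of_ratings_then_subtract(self):
        inp = BodyImageInput(24.0, 1.0, (25.0, 27.0), (0, 1))
        assert ib.body_image_delta(inp) == pytest.approx(2.0)

    def test_empty_ratings_rejected(self):
        with pytest.raises(ValueError):
            ib.body_image_delta(BodyImageInput(70, 1.75, BMI_MAP, ()))


class TestPercentCorrect:
    @pytest.mark.parametrize("k, n, expected", [(18, 20, 90.0), (0, 20, 0.0), (20, 20, 100.0)])
    def test_values(self, k, n, expected):
        assert ib.percent_correct(k, n) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ib.percent_correct(0, 0)


class TestRaceModelAuc:
    def test_no_violation_when_bimodal_slower(self):
        table = RtConditionTable(
            {"A": [300.0] * 20, "T": [310.0] * 20, "AT": [400.0] * 20}
        )
        assert ib.race_model_auc(table, "AT") == 0.0

    def test_degenerate_toy_saturates_grid(self):
        # all A = T = 300, all AT = 200: the bound is 0 at every AT quantile,
        # the actual CDF is 1 there, so violation = 1 across the 5..100 grid
        # and the trapezoid over fractions 0.05..1.00 equals 0.95.
        table = RtConditionTable(
            {"A": [300.0] * 20, "T": [300.0] * 20, "AT": [200.0] * 20}
        )
        assert ib.race_model_auc(table, "AT") == pytest.approx(0.95)

    def test_time_shift_invariance(self, rng):
        rts = {c: rng.gamma(9, 30, size=200) + 150 for c in ("A", "V", "AV")}
        a = ib.race_model_auc(RtConditionTable(rts), "AV")
        shifted = {c: v + 137.0 for c, v in rts.items()}
        b = ib.race_model_auc(RtConditionTable(shifted), "AV")
        assert a == pytest.approx(b, abs=1e-12)

    def test_missing_condition_rejected(self):
        table = RtConditionTable({"A": [300.0] * 20, "AT": [250.0] * 20})
        with pytest.raises(KeyError):
            ib.race_model_auc(table, "AT")

    def test_too_few_trials_rejected(self):
        table = RtConditionTable(
            {"A": [300.0] * 5, "T": [300.0] * 20, "AT": [250.0] * 20}
        )
        with pytest.raises(ValueError):
            ib.race_model_auc(table, "AT")


class TestGaussianBump:
    def test_recovery_of_planted_width(self):
        spec = ib.PsychSimSpec(tuple(np.arange(-200.0, 201.0, 25.0)), pse=0.0,
                               sigma=50.0, n_per_level=200,
                               function_form="gaussian_bump", seed=13)
        _, jnd = ib.fit_gaussian_bump(ib.simulate_psychometric_trials(spec))
        assert 42.5 <= jnd <= 57.5

    def test_symmetry_locates_peak(self):
        spec = ib.PsychSimSpec(tuple(np.arange(-180.0, 221.0, 25.0)), pse=20.0,
                               sigma=60.0, n_per_level=200,
                               function_form="gaussian_bump", seed=17)
        fit, _ = ib.fit_gaussian_bump(ib.simulate_psychometric_trials(spec))
        assert fit.mu == pytest.approx(20.0, abs=10.0)

    def test_all_zero_responses_rejected(self):
        table = PsychometricTable(np.arange(5.0), np.full(5, 20), np.zeros(5, int))
        with pytest.raises(ValueError):
            ib.fit_gaussian_bump(table)


class TestSpearmanKarber:
    def test_half_step_worked_example(self):
        table = PsychometricTable([1, 2, 3, 4, 5], [10] * 5, [0, 0, 5, 10, 10])
        assert ib.spearman_karber_pse(table) == pytest.approx(3.0)

    def test_unit_step_midpoint(self):
        table = PsychometricTable([1, 2, 3, 4], [10] * 4, [0, 0, 10, 10])
        assert ib.spearman_karber_pse(table) == pytest.approx(2.5)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            ib.spearman_karber_pse(PsychometricTable([1, 2], [5, 5], [0, 5]))

    def test_simulation_recovery(self):
        spec = ib.PsychSimSpec(tuple(np.arange(1.0, 8.0)), pse=4.0, sigma=1.0,
                               n_per_level=500, seed=19)
        est = ib.spearman_karber_pse(ib.simulate_psychometric_trials(spec))
        assert est == pytest.approx(4.0, abs=0.2)

    def test_agrees_with_cumulative_gaussian_mu(self):
        spec = ib.PsychSimSpec(tuple(np.arange(-120.0, 121.0, 20.0)), pse=10.0,
                               sigma=40.0, n_per_level=300, seed=23)
        table = ib.simulate_psychometric_trials(spec)
        fit, _ = ib.fit_cumulative_gaussian(table)
        sk = ib.spearman_karber_pse(table)
        assert abs(sk - fit.mu) <= 0.05 * fit.sigma


class TestCumulativeGaussian:
    def test_recovery_of_planted_width(self):
        spec = ib.PsychSimSpec(tuple(np.arange(-120.0, 121.0, 20.0)), pse=0.0,
                               sigma=40.0, n_per_level=200, seed=29)
        _, jnd = ib.fit_cumulative_gaussian(ib.simulate_psychometric_trials(spec))
        assert jnd == pytest.approx(Z75 * 40.0, rel=0.15)

    def test_quantile_identity_quarter_points(self):
        # responses consistent with p=0.25 at -27 ms and p=0.75 at +27 ms
        sigma_true = 27.0 / Z75
        levels = np.array([-81.0, -27.0, 27.0, 81.0])
        n = 400
        k = np.round(stats.norm.cdf(levels / sigma_true) * n).astype(int)
        _, jnd = ib.fit_cumulative_gaussian(PsychometricTable(levels, np.full(4, n), k))
        assert jnd == pytest.approx(27.0, abs=2.0)

    def test_location_shift_leaves_jnd_unchanged(self):
        base = ib.PsychSimSpec(tuple(np.arange(-120.0, 121.0, 20.0)), pse=0.0,
                               sigma=40.0, n_per_level=300, seed=31)
        shifted = ib.PsychSimSpec(tuple(np.arange(-90.0, 151.0, 20.0)), pse=30.0,
                                  sigma=40.0, n_per_level=300, seed=31)
        _, jnd_a = ib.fit_cumulative_gaussian(ib.simulate_psychometric_trials(base))
        _, jnd_b = ib.fit_cumulative_gaussian(ib.simulate_psychometric_trials(shifted))
        assert jnd_a == pytest.approx(jnd_b, rel=1e-6)

    def test_sign_flip_invariance(self):
        spec = ib.PsychSimSpec(tuple(np.arange(-120.0, 121.0, 20.0)), pse=5.0,
                               sigma=35.0, n_per_level=250, seed=37)
        table = ib.simulate_psychometric_trials(spec)
        flipped = PsychometricTable(
            -table.levels, table.n_presented, table.n_presented - table.n_positive
        )
        _, jnd_a = ib.fit_cumulative_gaussian(table)
        _, jnd_b = ib.fit_cumulative_gaussian(flipped)
        assert jnd_a == pytest.approx(jnd_b, rel=1e-3)

    def test_one_sided_responses_rejected(self):
        table = PsychometricTable([0, 10, 20, 30], [10] * 4, [6, 7, 9, 10])
        with pytest.raises(ValueError):
            ib.fit_cumulative_gaussian(table)


class TestSumOfConfusion:
    def test_identical_fits_give_zero(self):
        fit = GaussianFit(mu=5.0, sigma=40.0)
        assert ib.sum_of_confusion(fit, fit) == 0.0

    def test_matches_analytic_closed_form(self):
        grid = np.arange(-400.0, 400.0 + 1e-9, 10.0)
        fu = GaussianFit(mu=-30.0, sigma=50.0)
        fc = GaussianFit(mu=30.0, sigma=50.0)
        expected = np.sum(
            np.abs(stats.norm.cdf((grid - 30.0) / 50.0) - stats.norm.cdf((grid + 30.0) / 50.0))
        )
        assert ib.sum_of_confusion(fu, fc) == pytest.approx(expected)

    def test_widening_crossed_sigma_increases_sc(self):
        fu = GaussianFit(mu=0.0, sigma=40.0)
        scs = [ib.sum_of_confusion(fu, GaussianFit(mu=0.0, sigma=s))
               for s in (60.0, 90.0, 140.0)]
        assert scs[0] < scs[1] < scs[2]

    def test_empty_grid_rejected(self):
        fit = GaussianFit(mu=0.0, sigma=40.0)
        with pytest.raises(ValueError):
            ib.sum_of_confusion(fit, fit, grid=np.array([]))


class TestMentalRotation:
    def test_exact_linear_slope(self):
        trials = [(a, 500.0 + 2.0 * a, True) for a in (0, 45, 90, 135, 180)]
        assert ib.mental_rotation_slope(trials) == pytest.approx(2.0)

    def test_constant_rt_zero_slope(self):
        trials = [(a, 600.0, True) for a in (0, 45, 90)]
        assert ib.mental_rotation_slope(trials) == pytest.approx(0.0)

    def test_incorrect_trials_excluded(self):
        trials = [(a, 500.0 + 2.0 * a, True) for a in (0, 90, 180)]
        trials += [(a, 5000.0, False) for a in (0, 90, 180)]
        assert ib.mental_rotation_slope(trials) == pytest.approx(2.0)

    def test_noisy_recovery(self, rng):
        trials = [
            (a, 500.0 + 1.5 * a + rng.normal(0, 30), True)
            for a in (0, 45, 90, 135, 180)
            for _ in range(20)
        ]
        assert ib.mental_rotation_slope(trials) == pytest.approx(1.5, abs=0.3)

    def test_single_angle_rejected(self):
        with pytest.raises(ValueError):
            ib.mental_rotation_slope([(90, 500.0, True), (90, 520.0, True)])
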