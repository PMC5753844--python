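"""Virtual-cohort generator: distributional laws, screening, treatment effects."""

import math

import numpy as np
import pytest

from doseadapt import (
    DoseResponseCurve,
    PopulationModel,
    Subject,
    draw_subject,
    follow_up,
    screen,
    simulate_cohort,
    true_effect,
)


def _draw_many(pop, n, seed=1):
    g = np.random.default_rng(seed)
    subs = [draw_subject(pop, g, id=i) for i in range(n)]
    return (
        np.array([s.S for s in subs]),
        np.array([s.Y1 for s in subs]),
        np.array([s.Y2 for s in subs]),
    )


class TestDrawSubject:
    def test_zero_noise_degenerates_to_latent_mean(self):
        pop = PopulationModel(sigma_e=0.0)
        s = draw_subject(pop, np.random.default_rng(0))
        assert s.Y1 == s.Y2 == s.S

    def test_within_subject_variance_matches_sigma_e(self):
        pop = PopulationModel(sigma_e=17.9)
        S, Y1, _ = _draw_many(pop, 100_000)
        assert np.var(Y1 - S) == pytest.approx(17.9**2, rel=0.02)

    def test_repeat_measurement_correlation_is_intraclass(self):
        # corr(Y1, Y2) = Var(S) / (Var(S) + sigma_e^2) under compound symmetry
        pop = PopulationModel()
        S, Y1, Y2 = _draw_many(pop, 100_000)
        var_s = (math.exp(pop.sdlog**2) - 1) * math.exp(
            2 * pop.meanlog + pop.sdlog**2
        )
        expected = var_s / (var_s + pop.sigma_e**2)
        assert np.corrcoef(Y1, Y2)[0, 1] == pytest.approx(expected, abs=0.02)

    def test_compound_symmetry_covariance(self):
        # Cov(Y1, Y2) = Var(S): the only shared component is the latent mean
        pop = PopulationModel()
        S, Y1, Y2 = _draw_many(pop, 100_000, seed=2)
        cov = np.cov(Y1, Y2)[0, 1]
        var_s = S.var()
        se = 3 * var_s / math.sqrt(len(S))  # crude 3-SE band
        assert abs(cov - var_s) < max(se, 0.03 * var_s)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            PopulationModel(sdlog=0.0)
        with pytest.raises(ValueError):
            PopulationModel(sigma_e=-1.0)
        with pytest.raises(ValueError):
            PopulationModel(eligibility_threshold=0.0)


class TestScreen:
    @pytest.mark.parametrize(
        "y1, y2, eligible",
        [(60.0, 50.0, True), (40.0, 59.9, False), (50.0, 50.0, True)],
    )
    def test_average_threshold_inclusive(self, y1, y2, eligible):
        subj = Subject(id=0, S=50.0, Y1=y1, Y2=y2)
        assert screen(subj, 50.0) is eligible

    def test_eligibility_truncates_baseline_support(self, eligible_cohort):
        ybl = np.array([s.Ybl for s in eligible_cohort])
        assert ybl.min() >= 50.0


class TestTrueEffect:
    def test_flat_curve_is_null(self):
        curve = DoseResponseCurve("flat")
        assert all(
            true_effect(curve, j, ybl) == 0.0
            for j in range(len(curve.dose_grid) + 1)
            for ybl in (50.0, 120.0)
        )

    def test_best_dose_gets_full_absolute_effect(self):
        curve = DoseResponseCurve("non_monotone", effect_at_best=16.4)
        assert true_effect(curve, curve.best_dose_index(), 80.0) == pytest.approx(16.4)

    def test_proportional_effect_scales_with_baseline(self):
        curve = DoseResponseCurve("non_monotone", proportional="p20")
        assert true_effect(curve, curve.best_dose_index(), 80.0) == pytest.approx(16.0)

    def test_placebo_always_zero(self):
        curve = DoseResponseCurve("monotone_linear")
        assert true_effect(curve, 0, 100.0) == 0.0

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError):
            DoseResponseCurve("sigmoid")

    def test_non_monotone_peaks_between_1_and_1p2_mg(self):
        curve = DoseResponseCurve("non_monotone")
        best_mg = curve.dose_grid[curve.best_dose_index() - 1]
        assert 1.0 <= best_mg <= 1.2

    @pytest.mark.parametrize("shape", ["monotone_plateau", "monotone_linear"])
    def test_monotone_shapes_non_decreasing(self, shape):
        rel = DoseResponseCurve(shape).relative_profile()
        assert np.all(np.diff(rel) >= -1e-12)


class TestFollowUp:
    def _randomised(self, pop, seed=0, arm=1, d=16.4):
        subj = draw_subject(pop, np.random.default_rng(seed))
        subj.arm, subj.D = arm, d
        return subj

    def test_effect_applied_exactly_without_noise(self):
        pop = PopulationModel(sigma_e=0.0)
        subj = self._randomised(pop, d=16.4)
        follow_up(subj, pop, np.random.default_rng(1))
        assert subj.Yfu == pytest.approx(subj.S - 16.4)
        assert subj.Y == pytest.approx(16.4)

    def test_placebo_response_zero_without_noise(self):
        pop = PopulationModel(sigma_e=0.0)
        subj = self._randomised(pop, arm=0, d=0.0)
        follow_up(subj, pop, np.random.default_rng(1))
        assert subj.Y == pytest.approx(0.0)

    def test_requires_randomisation(self):
        pop = PopulationModel()
        subj = draw_subject(pop, np.random.default_rng(0))
        with pytest.raises(RuntimeError):
            follow_up(subj, pop, np.random.default_rng(1))

    def test_heteroscedastic_variance_increases_with_baseline(self):
        pop = PopulationModel(hetero=True)
        g = np.random.default_rng(5)
        subs = []
        for i in range(20_000):
            s = draw_subject(pop, g, id=i)
            s.arm, s.D = 0, 0.0
            follow_up(s, pop, g)
            subs.append(s)
        ybl = np.array([s.Ybl for s in subs])
        resid = np.array([s.Y3 - s.S for s in subs])
        lo, hi = np.quantile(ybl, [0.25, 0.75])
        assert resid[ybl >= hi].var() > resid[ybl <= lo].var()


class TestCohortProperties:
    def test_flat_scenario_has_no_effect_leakage(self, eligible_cohort):
        # Follow-up is unbiased for the latent mean when no effect is applied.
        # (E[Y] itself is positive for screened subjects: eligibility selects
        # positive screening noise — regression to the mean, by construction.)
        resid = np.array([s.Yfu - s.S for s in eligible_cohort])
        assert abs(resid.mean()) < 4 * resid.std() / math.sqrt(len(resid))
        y = np.array([s.Y for s in eligible_cohort])
        assert y.mean() > 0  # regression-to-the-mean direction

    def test_twin_cycle_averaging_halves_conditional_variance(self):
        # Var(Y|Ybl) under two-cycle averages at both ends is ~50% of the
        # single-cycle version: sigma_e^2 vs 2 sigma_e^2.
        pop = PopulationModel()
        curve = DoseResponseCurve("flat")
        g = np.random.default_rng(99)
        cohort = simulate_cohort(30_000, pop, curve, np.zeros(30_000, int), g)

        def resid_var(ybl, y):
            b = np.cov(ybl, y)[0, 1] / np.var(ybl)
            a = y.mean() - b * ybl.mean()
            return np.var(y - a - b * ybl)

        ybl2 = np.array([s.Ybl for s in cohort])
        y2 = np.array([s.Y for s in cohort])
        ybl1 = np.array([s.Y1 for s in cohort])
        y1 = np.array([s.Y1 - s.Y3 for s in cohort])
        reduction = 100 * (1 - resid_var(ybl2, y2) / resid_var(ybl1, y1))
        assert reduction == pytest.approx(50.0, abs=5.0)
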