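import numpy as np
import pandas as pd
import pytest
from scipy import stats

from densrisk import (
    AbsoluteRiskModel,
    FIVE_CATEGORY_THRESHOLDS,
    FOUR_CATEGORY_THRESHOLDS,
    ModelValidation,
    auc,
    calibration_slope,
    classify_risk,
    generate_cohort,
    generate_outcomes_from_model,
    nri,
    quantile_calibration,
    reclassification_matrix,
)
from densrisk import CohortConfig, DensityNormalizer


class TestCalibrationSlope:
    def test_self_calibrated_outcomes_give_slope_one(self, rng):
        p = 1 / (1 + np.exp(-rng.normal(-4.0, 0.8, 50_000)))
        y = rng.random(50_000) < p
        slope, ci = calibration_slope(p, y.astype(int))
        assert ci[0] < 1.0 < ci[1]

    def test_doubled_logit_halves_slope_and_excludes_one(self, rng):
        logit = rng.normal(-4.0, 0.8, 100_000)
        p_true = 1 / (1 + np.exp(-logit))
        y = (rng.random(100_000) < p_true).astype(int)
        p_wide = 1 / (1 + np.exp(-2 * logit))  # overdispersed predictions
        slope, ci = calibration_slope(p_wide, y)
        assert abs(slope - 0.5) < 0.05
        assert ci[1] < 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            calibration_slope([0.0, 0.5], [0, 1])
        with pytest.raises(ValueError):
            calibration_slope([0.5, 0.5], [0, 1])
        with pytest.raises(ValueError):
            calibration_slope([0.2, 0.4], [1, 1])


class TestQuantileCalibration:
    def test_equal_count_bins_with_stable_ties(self):
        p = np.array([0.2, 0.1, 0.2, 0.1, 0.3, 0.3, 0.4, 0.4, 0.5, 0.5])
        y = np.array([0, 0, 0, 0, 0, 1, 0, 1, 1, 1])
        table = quantile_calibration(p, y, n_bins=5)
        assert (table["n"] == 2).all()
        assert len(table) == 5

    def test_zero_cases_poisson_lower_bound_is_zero(self):
        p = np.linspace(0.01, 0.2, 100)
        y = np.zeros(100, dtype=int)
        y[-1] = 1  # a single case in the top bin
        table = quantile_calibration(p, y, n_bins=5)
        assert table["observed_low"].iloc[0] == 0.0
        # exact Poisson interval for one observed case in a bin of 20
        assert table["observed_high"].iloc[-1] == pytest.approx(
            stats.chi2.ppf(0.975, 4) / 2 / 20
        )

    def test_calibrated_sample_bins_cover_predicted(self, rng):
        p = rng.uniform(0.01, 0.2, 50_000)
        y = (rng.random(50_000) < p).astype(int)
        table = quantile_calibration(p, y)
        # observed proportions agree with predicted within 4 binomial SEs in
        # every bin (per-bin 95% intervals alone would miss ~1 bin in 4 runs)
        se = np.sqrt(table["mean_predicted"] * (1 - table["mean_predicted"])
                     / table["n"])
        assert (np.abs(table["observed"] - table["mean_predicted"]) < 4 * se).all()
        # and the exact Poisson intervals are consistent with those margins
        assert (table["observed_low"] <= table["observed"]).all()
        assert (table["observed_high"] >= table["observed"]).all()

    def test_merges_when_too_few_distinct(self):
        p = np.repeat([0.1, 0.2], 10)
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        with pytest.warns(UserWarning, match="distinct"):
            table = quantile_calibration(p, y, n_bins=5)
        assert len(table) == 2


class TestAuc:
    def test_toy_value_with_tie(self):
        a, _ = auc([0.8, 0.6, 0.6, 0.4], [1, 1, 0, 0])
        assert a == pytest.approx(0.875)

    def test_perfect_separation(self):
        a, ci = auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert a == 1.0
        assert ci[1] <= 1.0

    def test_matches_all_pairs_brute_force(self, rng):
        p = np.round(rng.random(800), 2)  # rounding creates ties
        y = (rng.random(800) < 0.3).astype(int)
        a, _ = auc(p, y)
        pos, neg = p[y == 1], p[y == 0]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
            pos[:, None] == neg[None, :]
        ).sum()
        assert a == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        p = rng.random(500)
        y = (rng.random(500) < p).astype(int)
        a1, _ = auc(p, y)
        a2, _ = auc(np.exp(3 * p), y)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestClassification:
    def test_boundaries(self):
        cats = classify_risk([0.0166, 0.0167, 0.005, 0.5])
        np.testing.assert_array_equal(cats, [1, 2, 0, 3])

    def test_five_category_split(self):
        cats = classify_risk([0.0035, 0.003, 0.009], FIVE_CATEGORY_THRESHOLDS)
        np.testing.assert_array_equal(cats, [1, 0, 1])

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            classify_risk([0.1], (0.0, 0.5))
        with pytest.raises(ValueError):
            classify_risk([0.1], (0.5, 0.5))


class TestNri:
    def test_identical_classifications_zero(self):
        c = [0, 1, 2, 1]
        assert nri(c, c, [1, 0, 1, 0]) == 0.0

    def test_arithmetic_example(self):
        # 10 cases: 2 up, 1 down; 20 non-cases: 3 down, 1 up
        old_c, new_c = np.ones(10, int), np.ones(10, int)
        new_c[:2] += 1
        new_c[2] -= 1
        old_n, new_n = np.ones(20, int), np.ones(20, int)
        new_n[:3] -= 1
        new_n[3] += 1
        val = nri(np.r_[old_c, old_n], np.r_[new_c, new_n],
                  np.r_[np.ones(10, int), np.zeros(20, int)])
        assert val == pytest.approx(0.2)

    def test_maximum_attained(self):
        old = np.r_[np.ones(5, int), np.ones(5, int)]
        new = np.r_[np.full(5, 2), np.zeros(5, int)]
        assert nri(old, new, np.r_[np.ones(5, int), np.zeros(5, int)]) == 2.0

    def test_antisymmetric(self, rng):
        old = rng.integers(0, 4, 200)
        new = rng.integers(0, 4, 200)
        y = rng.integers(0, 2, 200)
        if y.sum() in (0, 200):
            y[0] = 1 - y[0]
        assert nri(old, new, y) == pytest.approx(-nri(new, old, y))


def test_reclassification_margins(rng):
    old = rng.integers(0, 4, 300)
    new = rng.integers(0, 4, 300)
    mat = reclassification_matrix(old, new, 4)
    np.testing.assert_array_equal(mat.sum(axis=1), np.bincount(old, minlength=4))
    np.testing.assert_array_equal(mat.sum(axis=0), np.bincount(new, minlength=4))


class TestModelValidation:
    def test_full_battery_on_simulated_cohort(self):
        cohort = generate_cohort(CohortConfig(n_women=12_000, seed=33))
        params = {
            ("stratus", "age_bmi"): DensityNormalizer("stratus", "age_bmi").fit(cohort),
            ("stratus", "age_only"): DensityNormalizer("stratus", "age_only").fit(cohort),
        }
        model = AbsoluteRiskModel(md_input="stratus", input_combination=("md",),
                                  normalization=params)
        baseline = AbsoluteRiskModel(md_input="birads", input_combination=("md",))
        report = ModelValidation(model, cohort, baseline_model=baseline).run()
        assert report.category_proportions.sum() == pytest.approx(1.0, abs=1e-12)
        assert 0.4 < report.auc < 0.9
        assert report.reclassification.sum() == report.n
        assert -2.0 <= report.nri <= 2.0
        assert report.quantile_table.shape[0] == 5
        assert "calibration slope" in report.summary()

    def test_self_generated_outcomes_are_calibrated_and_miscalibrated_rejected(self):
        model = AbsoluteRiskModel(md_input="birads", input_combination=("md",))
        pop = model.sample_population(120_000, seed=35)
        out = generate_outcomes_from_model(pop, model, horizon=5, seed=36)
        p = out["predicted_risk"].to_numpy()
        y = out["outcome"].to_numpy()
        slope, ci = calibration_slope(p, y)
        assert ci[0] < 1.0 < ci[1]
        # a deliberately overdispersed rival: doubled log-odds
        logit = np.log(p / (1 - p))
        p_bad = 1 / (1 + np.exp(-2 * logit + np.mean(logit)))
        slope_b, ci_b = calibration_slope(p_bad, y)
        assert ci_b[1] < 1.0
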