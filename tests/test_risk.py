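import math

import numpy as np
import pandas as pd
import pytest

from densrisk import (
    AbsoluteRiskModel,
    DensityNormalizer,
    RateTable,
    RiskFactorDistributions,
)
from conftest import mc_absolute_risk

AGES = np.arange(0, 81)


def flat_incidence(rate=0.01):
    return RateTable(AGES, [2010], np.full((81, 1), rate))


def zero_mortality():
    return RateTable(AGES, [2010], np.zeros((81, 1)))


def all_pre_distributions():
    # menopause far in the future so every projection age is premenopausal
    return RiskFactorDistributions(menopause_age_mean=85.0, menopause_age_sd=1.0,
                                   menopause_age_bounds=(80.0, 90.0))


class TestLinearPredictor:
    def test_empty_input_combination_is_zero(self):
        m = AbsoluteRiskModel(md_input="birads", input_combination=())
        assert m.linear_predictor({}, 50.0) == 0.0

    def test_density_term_is_log_hr_times_z(self):
        m = AbsoluteRiskModel(md_input="stratus", input_combination=("md",))
        lp = m.linear_predictor(
            {"z": 1.0, "menopause_status": "pre", "age_menopause": 60.0}, 45.0
        )
        assert lp == pytest.approx(math.log(1.48), abs=1e-12)

    def test_additivity_over_factors(self):
        md = AbsoluteRiskModel(md_input="stratus", input_combination=("md",))
        fh = AbsoluteRiskModel(md_input="stratus", input_combination=("fh",))
        both = AbsoluteRiskModel(md_input="stratus", input_combination=("md", "fh"))
        prof = {"z": 0.7, "menopause_status": "post", "age_menopause": 48.0,
                "fh_category": 2}
        assert both.linear_predictor(prof, 55.0) == pytest.approx(
            md.linear_predictor(prof, 55.0) + fh.linear_predictor(prof, 55.0)
        )

    def test_menopause_switch_mid_projection(self):
        m = AbsoluteRiskModel(md_input="stratus", input_combination=("md",))
        prof = {"z": 1.0, "menopause_status": "pre", "age_menopause": 52.0}
        assert m.linear_predictor(prof, 51.0) == pytest.approx(math.log(1.48))
        assert m.linear_predictor(prof, 52.0) == pytest.approx(math.log(1.41))

    def test_both_density_representations_rejected(self):
        m = AbsoluteRiskModel(md_input="birads", input_combination=("md",))
        with pytest.raises(ValueError, match="both supplied"):
            m.linear_predictor({"birads": 2, "z": 1.0}, 50.0)

    def test_missing_factor_reported(self):
        m = AbsoluteRiskModel(md_input="birads", input_combination=("md", "fh"))
        with pytest.raises(ValueError, match="birads"):
            m.linear_predictor({"fh_category": 0}, 50.0)


class TestPopulationMeanRR:
    def test_no_factors_gives_one(self):
        m = AbsoluteRiskModel(md_input="birads", input_combination=())
        assert m.population_mean_rr(50.0) == 1.0

    def test_lognormal_mean_closed_form_all_premenopausal(self):
        beta = math.log(1.48)
        m = AbsoluteRiskModel(md_input="stratus", input_combination=("md",),
                              distributions=all_pre_distributions())
        assert m.population_mean_rr(45.0) == pytest.approx(
            math.exp(beta**2 / 2), rel=1e-12
        )
        assert m.population_mean_rr(45.0) == pytest.approx(1.0799, abs=2e-4)

    def test_birads_arithmetic(self):
        d = RiskFactorDistributions(
            birads_probs={"lt50": (0.1, 0.4, 0.4, 0.1), "ge50": (0.1, 0.4, 0.4, 0.1)}
        )
        m = AbsoluteRiskModel(
            md_input="birads", input_combination=("md",), distributions=d,
            birads_log_rr=tuple(math.log(r) for r in (1.0, 1.5, 2.0, 3.0)),
        )
        assert m.population_mean_rr(45.0) == pytest.approx(1.8, rel=1e-12)

    def test_menopause_mixture_between_pre_and_post_values(self):
        m = AbsoluteRiskModel(md_input="stratus", input_combination=("md",))
        b_pre, b_post = math.log(1.48), math.log(1.41)
        lo, hi = sorted([math.exp(b_pre**2 / 2), math.exp(b_post**2 / 2)])
        assert lo < m.population_mean_rr(51.0) < hi


class TestConstrainedBaseline:
    def test_null_model_baseline_equals_population_rates(self):
        m = AbsoluteRiskModel(incidence=flat_incidence(0.004), md_input="birads",
                              input_combination=())
        assert m.baseline(50.0, 2010) == pytest.approx(0.004, rel=1e-12)

    def test_multiplicative_rescaling_leaves_hazards_unchanged(self):
        base = AbsoluteRiskModel(md_input="birads", input_combination=("md",))
        shifted = AbsoluteRiskModel(
            md_input="birads", input_combination=("md",),
            birads_log_rr=tuple(b + math.log(2) for b in base.birads_log_rr),
        )
        prof = {"birads": 3, "birth_year": 1965.0}
        for a in (45.0, 55.0, 70.0):
            h0 = base.baseline(a, 2010) * math.exp(base.linear_predictor(prof, a))
            h1 = shifted.baseline(a, 2010) * math.exp(shifted.linear_predictor(prof, a))
            assert h1 == pytest.approx(h0, rel=1e-12)
        assert shifted.baseline(50.0, 2010) == pytest.approx(
            base.baseline(50.0, 2010) / 2, rel=1e-12
        )


class TestAbsoluteRisk:
    def test_constant_hazard_closed_form(self):
        m = AbsoluteRiskModel(incidence=flat_incidence(0.01),
                              mortality=zero_mortality(),
                              md_input="birads", input_combination=())
        r = m.absolute_risk({}, 50.0, 5)
        assert r == pytest.approx(1 - 0.99**5, rel=1e-12)

    def test_zero_hazard_gives_zero(self):
        m = AbsoluteRiskModel(incidence=flat_incidence(0.0), md_input="birads",
                              input_combination=())
        assert m.absolute_risk({}, 50.0, 5) == 0.0

    def test_matches_monte_carlo_oracle(self):
        m = AbsoluteRiskModel(md_input="birads", input_combination=("md",))
        prof = {"birads": 3, "birth_year": 1966.0}
        exact = m.absolute_risk(prof, 46.0, 10)
        est, se = mc_absolute_risk(m, prof, 46.0, 10, n=200_000, seed=3)
        assert abs(exact - est) < 3 * se

    def test_projection_capped_at_80(self):
        m = AbsoluteRiskModel(incidence=flat_incidence(0.01),
                              mortality=zero_mortality(),
                              md_input="birads", input_combination=())
        assert m.absolute_risk({}, 78.0, 30) == pytest.approx(1 - 0.99**2, rel=1e-12)

    def test_risk_curve_monotone_and_bounded_by_no_mortality(self):
        m = AbsoluteRiskModel(md_input="stratus", input_combination=("md",))
        prof = {"z": 1.5, "menopause_status": "pre", "age_menopause": 51.0,
                "birth_year": 1972.0}
        with_m = m.risk_curve(prof, 41.0)["cumulative_risk"].to_numpy()
        without = m.risk_curve(prof, 41.0, competing_mortality=False)[
            "cumulative_risk"].to_numpy()
        assert (np.diff(with_m) >= 0).all()
        assert (without >= with_m - 1e-15).all()


class TestPredict:
    def test_higher_z_higher_risk(self, small_cohort):
        norm = DensityNormalizer("stratus", "age_bmi")
        params = norm.fit(small_cohort)
        m = AbsoluteRiskModel(md_input="stratus", input_combination=("md",),
                              normalization={("stratus", "age_bmi"): params,
                                             ("stratus", "age_only"):
                                             DensityNormalizer("stratus", "age_only")
                                             .fit(small_cohort)})
        woman = {"z": 0.0, "menopause_status": "post", "age_menopause": 50.0,
                 "birth_year": 1960.0}
        r_lo = m.absolute_risk({**woman, "z": -1.0}, 56.0, 5)
        r_mid = m.absolute_risk(woman, 56.0, 5)
        r_hi = m.absolute_risk({**woman, "z": 1.0}, 56.0, 5)
        assert r_lo < r_mid < r_hi

    def test_batch_equals_looped_single_calls(self, small_cohort):
        params = {
            ("stratus", "age_bmi"): DensityNormalizer("stratus", "age_bmi").fit(small_cohort),
            ("stratus", "age_only"): DensityNormalizer("stratus", "age_only").fit(small_cohort),
        }
        m = AbsoluteRiskModel(md_input="stratus",
                              input_combination=("md", "qrf", "fh"),
                              normalization=params)
        sub = small_cohort.head(40).copy()
        sub["birth_year"] = 2012.0 - sub["age_entry"]
        batch = m.predict(sub, horizon=5).frame["risk"].to_numpy()
        for i, (_, row) in enumerate(sub.iterrows()):
            prof = row.to_dict()
            prof["z"] = None  # force the raw-density path in both routes
            single = m.absolute_risk(prof, row["age_entry"] + 1.0, 5)
            assert abs(batch[i] - single) < 1e-12

    def test_row_failures_do_not_abort_batch(self):
        m = AbsoluteRiskModel(md_input="birads", input_combination=("md",))
        cohort = pd.DataFrame(
            {"id": [1, 2, 3], "age_entry": [45.0, 50.0, 55.0],
             "birads": [2.0, np.nan, 4.0]}
        )
        preds = m.predict(cohort)
        assert np.isnan(preds.frame["risk"].iloc[1])
        assert np.isfinite(preds.frame["risk"].iloc[[0, 2]]).all()
        assert 2 in preds.errors

    def test_missing_bmi_dispatches_to_age_only_params(self, small_cohort):
        params = {
            ("stratus", "age_bmi"): DensityNormalizer("stratus", "age_bmi").fit(small_cohort),
            ("stratus", "age_only"): DensityNormalizer("stratus", "age_only").fit(small_cohort),
        }
        m = AbsoluteRiskModel(md_input="stratus", input_combination=("md",),
                              normalization=params)
        sub = small_cohort.head(10).copy()
        sub.loc[sub.index[:5], "bmi"] = np.nan
        preds = m.predict(sub)
        assert np.isfinite(preds.frame["risk"]).all()


class TestPgsAdjustedSwitch:
    def test_switch_changes_only_density_term(self):
        kwargs = dict(md_input="stratus", normalization={})
        with_pgs = AbsoluteRiskModel(input_combination=("md", "pgs"), **kwargs)
        without = AbsoluteRiskModel(input_combination=("md",), **kwargs)
        prof = {"z": 1.0, "menopause_status": "pre", "age_menopause": 60.0,
                "pgs": 0.0}
        delta = with_pgs.linear_predictor(prof, 45.0) - without.linear_predictor(prof, 45.0)
        assert delta == pytest.approx(math.log(1.45) - math.log(1.48), abs=1e-12)


class TestRangeAndSerialization:
    def test_continuous_density_spans_wider_risk_range_than_matched_categories(self):
        # categorical comparator: 4 equiprobable categories whose log-RRs are
        # the within-quartile means of beta*z, rescaled to match the mean and
        # variance of the continuous log-RR
        beta = math.log(1.48)
        q = np.array([-1.2715678, -0.3246628, 0.3246628, 1.2715678])
        q = q / np.sqrt(np.mean(q**2))
        cat = AbsoluteRiskModel(
            md_input="birads", input_combination=("md",),
            birads_log_rr=tuple(beta * v for v in q),
            distributions=RiskFactorDistributions(
                birads_probs={"lt50": (0.25,) * 4, "ge50": (0.25,) * 4},
                menopause_age_mean=85.0, menopause_age_sd=1.0,
                menopause_age_bounds=(80.0, 90.0),
            ),
        )
        cont = AbsoluteRiskModel(md_input="stratus", input_combination=("md",),
                                 distributions=all_pre_distributions())
        pop_cat = cat.sample_population(50_000, seed=4)
        pop_cont = cont.sample_population(50_000, seed=4)
        r_cat = cat.predict(pop_cat).frame["risk"]
        r_cont = cont.predict(pop_cont).frame["risk"]
        range_cat = r_cat.quantile(0.99) - r_cat.quantile(0.01)
        range_cont = r_cont.quantile(0.99) - r_cont.quantile(0.01)
        assert range_cont > range_cat

    def test_dict_round_trip_preserves_predictions(self, small_cohort):
        params = {
            ("stratus", "age_bmi"): DensityNormalizer("stratus", "age_bmi").fit(small_cohort),
            ("stratus", "age_only"): DensityNormalizer("stratus", "age_only").fit(small_cohort),
        }
        m = AbsoluteRiskModel(md_input="stratus", input_combination=("md", "fh"),
                              normalization=params)
        again = AbsoluteRiskModel.from_dict(m.to_dict())
        sub = small_cohort.head(30)
        np.testing.assert_array_equal(
            m.predict(sub).frame["risk"].to_numpy(),
            again.predict(sub).frame["risk"].to_numpy(),
        )
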