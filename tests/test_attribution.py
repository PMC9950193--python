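import numpy as np
import pandas as pd
import pytest

from radonburden.attribution import (
    attributable_cases,
    attributable_fraction,
    avoidable_cases,
    capped_gm,
    derive_group_err,
    joint_effect,
    mitigate,
    paf,
    relative_risk,
    run_scenario,
)
from radonburden.data_model import (
    ERRSpec,
    ScenarioConfig,
    SmokingRelativeRisks,
    StratifiedTable,
    ValidationError,
    full_cross,
)
from radonburden.exposure import build_exposure_sets, geometric_mean


class TestRelativeRisk:
    @pytest.mark.parametrize(
        "x,err,expected",
        [(0.0, 8.4, 1.0), (100.0, 8.4, 1.084), (250.0, 16.0, 1.40)],
    )
    def test_linear_model_values(self, x, err, expected):
        assert relative_risk(x, ERRSpec(err)) == pytest.approx(expected)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            relative_risk(-1.0, ERRSpec(8.4))

    def test_af_increasing_and_concave_on_grid(self):
        x = np.linspace(0, 1000, 201)
        af = attributable_fraction(x, ERRSpec(16.0))
        d1 = np.diff(af)
        assert (d1 > 0).all()          # increasing
        assert (np.diff(d1) < 0).all()  # concave


class TestAttributableAndAvoidable:
    def test_national_cases_at_universal_floor(self):
        # 2694 cases at a universal 25 Bq m-3: 55.4 (ERR 8.4%), 103.6 (16%)
        assert attributable_cases(2694, 25.0, ERRSpec(8.4)) == pytest.approx(
            55.4, abs=0.05
        )
        assert attributable_cases(2694, 25.0, ERRSpec(16.0)) == pytest.approx(
            103.6, abs=0.05
        )

    def test_zero_exposure_attributes_nothing(self):
        assert attributable_cases(1000, 0.0, ERRSpec(16.0)) == 0.0

    def test_avoidable_zero_at_floor(self):
        assert avoidable_cases(500, 25.0, 25.0, ERRSpec(16.0)) == 0.0

    def test_avoidable_direct_evaluation(self):
        # 1000 * (0.20/1.20 - 0.04/1.04) with ERR 16%, x 125, floor 25
        expected = 1000 * (0.20 / 1.20 - 0.04 / 1.04)
        assert avoidable_cases(1000, 125.0, 25.0, ERRSpec(16.0)) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(128.2, abs=0.05)

    def test_avoidable_plus_counterfactual_is_attributable(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            L = rng.uniform(0, 500)
            x = rng.uniform(0, 800)
            floor = rng.uniform(0, 100)
            err = ERRSpec(rng.uniform(1, 40))
            lhs = avoidable_cases(L, x, floor, err) + attributable_cases(
                L, floor, err
            )
            assert lhs == pytest.approx(attributable_cases(L, x, err), abs=1e-10)

    def test_signed_below_floor(self):
        assert avoidable_cases(100, 10.0, 25.0, ERRSpec(16.0)) < 0


class TestPaf:
    def test_published_fraction(self):
        assert paf(170, 2694) == pytest.approx(0.063, abs=5e-4)

    @pytest.mark.parametrize("num,den,expected", [(0, 10, 0.0), (10, 10, 1.0)])
    def test_bounds(self, num, den, expected):
        assert paf(num, den) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            paf(1, 0)


class TestMitigate:
    def _measurements(self, values, region="R1", dwelling="house"):
        n = len(values)
        return pd.DataFrame(
            {"region": region, "dwelling": dwelling,
             "survey_id": ["1991", "2006"] * (n // 2) + ["1991"] * (n % 2),
             "concentration": values}
        )

    def test_capping_recomputes_gm(self):
        meas = pd.DataFrame(
            {"region": "R1", "dwelling": "house", "survey_id": "1991",
             "concentration": [50.0, 150.0, 400.0]}
        )
        meas = pd.concat(
            [meas, meas.assign(survey_id="2006")], ignore_index=True
        )
        mitigated = mitigate(meas, 200.0)
        gm = mitigated.lookup("1991")[("R1", "house")]
        assert gm == pytest.approx((50 * 150 * 200) ** (1 / 3))
        assert gm == pytest.approx(114.5, abs=0.05)

    def test_action_level_above_max_is_identity(self):
        meas = self._measurements([40.0, 90.0, 180.0, 60.0])
        base = build_exposure_sets(meas)
        mitigated = mitigate(meas, 1000.0)
        pd.testing.assert_frame_equal(base.data, mitigated.data)

    def test_gm_only_without_model_is_configuration_error(self, dataset):
        with pytest.raises(ValidationError, match="gsd"):
            mitigate(dataset.exposure, 200.0)

    def test_lognormal_capped_gm_matches_simulation(self):
        gm, gsd, cap = 90.0, 2.5, 200.0
        rng = np.random.default_rng(0)
        draws = np.minimum(
            rng.lognormal(np.log(gm), np.log(gsd), 200_000), cap
        )
        assert capped_gm(gm, gsd, cap) == pytest.approx(
            geometric_mean(draws), rel=5e-3
        )

    def test_degenerate_gsd_caps_the_gm_itself(self):
        assert capped_gm(90.0, 1.0, 50.0) == 50.0
        assert capped_gm(40.0, 1.0, 50.0) == 40.0

    def test_prevented_cases_nonincreasing_in_action_level(self, model, scenario16):
        curve = model.mitigation_curve((100.0, 200.0, 300.0), scenario16)
        prevented = curve["prevented"].to_numpy()
        assert prevented[0] >= prevented[1] >= prevented[2] >= 0


class TestGroupErr:
    def test_published_pair_recovered(self):
        e_s, e_n = derive_group_err(16.0, 10.0 / 17.0, 1.0 / 7.0)
        assert round(e_s, 1) == 10.0
        assert round(e_n, 1) == 17.0

    def test_unit_ratio_collapses_to_average(self):
        for w in (0.0, 0.3, 1.0):
            assert derive_group_err(16.0, 1.0, w) == pytest.approx((16.0, 16.0))

    def test_zero_weight_gives_average_to_nonsmokers(self):
        e_s, e_n = derive_group_err(16.0, 0.5, 0.0)
        assert e_n == pytest.approx(16.0)
        assert e_s == pytest.approx(8.0)

    def test_weighted_average_identity_holds(self):
        w, ratio = 0.22, 0.7
        e_s, e_n = derive_group_err(12.5, ratio, w)
        assert w * e_s + (1 - w) * e_n == pytest.approx(12.5)
        assert e_s / e_n == pytest.approx(ratio)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            derive_group_err(16.0, -1.0, 0.5)
        with pytest.raises(ValidationError):
            derive_group_err(16.0, 0.5, 1.5)


class TestRunScenario:
    def test_matches_hand_composed_formulas_per_stratum(self, dataset, scenario16):
        res = run_scenario(
            dataset.population, dataset.cases, dataset.exposure,
            dataset.smoking_truth, scenario16,
        )
        df = res.strata
        for row in df.sample(30, random_state=0).itertuples():
            att = attributable_cases(row.cases, row.gm, ERRSpec(16.0))
            cf = attributable_cases(row.cases, 25.0, ERRSpec(16.0))
            assert row.attributable == pytest.approx(att, abs=1e-12)
            assert row.avoidable == pytest.approx(att - cf, abs=1e-12)

    def test_zero_err_attributes_nothing(self, dataset):
        res = run_scenario(
            dataset.population, dataset.cases, dataset.exposure,
            dataset.smoking_truth, ScenarioConfig(err_spec=ERRSpec(0.0)),
        )
        assert res.totals()["attributable"] == 0.0
        assert res.totals()["avoidable"] == 0.0

    def test_zero_floor_makes_avoidable_equal_attributable(self, dataset):
        res = run_scenario(
            dataset.population, dataset.cases, dataset.exposure,
            dataset.smoking_truth,
            ScenarioConfig(err_spec=ERRSpec(16.0), counterfactual_floor=0.0),
        )
        assert np.allclose(
            res.strata["avoidable"], res.strata["attributable"], atol=1e-12
        )

    def test_margins_sum_to_national_total(self, dataset, scenario16):
        res = run_scenario(
            dataset.population, dataset.cases, dataset.exposure,
            dataset.smoking_truth, scenario16,
        )
        total = res.totals()["avoidable"]
        for margin in ("region", "age_group", "sex", "dwelling"):
            assert res.margin(margin)["avoidable"].sum() == pytest.approx(
                total, rel=1e-12
            )
        assert res.smoking_margin()["avoidable"].sum() == pytest.approx(
            total, rel=1e-12
        )

    def test_group_specific_err_interpolates_between_uniform_runs(
        self, dataset
    ):
        base = ScenarioConfig(err_spec=ERRSpec(16.0))
        uniform = run_scenario(
            dataset.population, dataset.cases, dataset.exposure,
            dataset.smoking_truth, base,
        ).totals()["avoidable"]
        lo = run_scenario(
            dataset.population, dataset.cases, dataset.exposure,
            dataset.smoking_truth, base, group_err=(10.0, 10.0),
        ).totals()["avoidable"]
        split = run_scenario(
            dataset.population, dataset.cases, dataset.exposure,
            dataset.smoking_truth, base, group_err=(10.0, 17.0),
        ).totals()["avoidable"]
        assert lo < split < uniform


class TestJointEffect:
    def test_components_sum_and_never_joint_zero(self, dataset, scenario16):
        res = joint_effect(
            dataset.population, dataset.cases, dataset.exposure,
            dataset.smoking_truth, scenario16,
        )
        by = res.by_group()
        for cat in ("current", "former", "never"):
            assert by.loc[cat, "radon_alone"] + by.loc[
                cat, "joint_with_smoking"
            ] == pytest.approx(by.loc[cat, "avoidable_total"], abs=1e-9)
        assert by.loc["never", "joint_with_smoking"] == pytest.approx(0.0, abs=1e-9)

    def test_unit_smoking_rr_kills_the_joint_term(self, dataset, scenario16):
        rr1 = SmokingRelativeRisks(current=1.0, former=1.0)
        res = joint_effect(
            dataset.population, dataset.cases, dataset.exposure,
            dataset.smoking_truth, scenario16, smoking_rr=rr1,
        )
        joint_cols = [c for c in res.strata if c.startswith("joint_")]
        assert np.allclose(res.strata[joint_cols].to_numpy(), 0.0, atol=1e-9)

    def test_radon_alone_share_tracks_inverse_smoking_rr(self, scenario16):
        """With equal group populations the radon-alone share of a group's
        avoidable burden is the inverse of its smoking RR."""
        regions = ["R1"]
        pop = full_cross(regions, 30_000.0, quantity="population")
        cases = full_cross(regions, 90.0, quantity="cases")
        prevalence = pd.DataFrame(
            [
                {"age_group": a, "sex": s, "dwelling": d,
                 "current": 1 / 3, "former": 1 / 3, "never": 1 / 3}
                for a in pop.age_groups for s in ("men", "women")
                for d in ("flat", "house")
            ]
        )
        gms = pd.DataFrame(
            [
                {"region": "R1", "dwelling": d, "survey_id": s,
                 "gm_concentration": 120.0}
                for d in ("flat", "house") for s in ("1991", "2006")
            ]
        )
        res = joint_effect(
            pop, cases, build_exposure_sets(gms), prevalence, scenario16,
        )
        by = res.by_group()
        share = by["radon_alone"] / by["avoidable_total"]
        assert share["current"] == pytest.approx(1 / 15, rel=1e-9)
        assert share["former"] == pytest.approx(1 / 4, rel=1e-9)
        assert share["never"] == pytest.approx(1.0, rel=1e-9)
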