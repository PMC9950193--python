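import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from radonburden.attribution import attributable_fraction
from radonburden.exposure import geometric_mean
from radonburden.synthetic import (
    SyntheticConfig,
    expected_avoidable,
    expected_cases_frame,
    generate_cases,
    generate_dataset,
    generate_population,
    generate_radon_surveys,
    generate_smoking_series,
    smoking_truth_table,
    true_exposure_sets,
)


class TestPopulation:
    def test_house_share_in_published_band(self):
        pop = generate_population(SyntheticConfig())
        share = pop.aggregate("dwelling")["house"] / pop.total()
        assert 0.60 <= share <= 0.66

    def test_single_region_has_28_strata(self):
        assert len(generate_population(SyntheticConfig(n_regions=1))) == 28

    def test_age_distribution_decreases_beyond_middle_age(self):
        pop = generate_population(SyntheticConfig())
        by_age = pop.aggregate("age_group")
        assert by_age["55-64"] > by_age["65-74"] > by_age["75-84"] > by_age["85+"]

    def test_same_seed_reproduces_dataset(self):
        a = generate_dataset(SyntheticConfig(n_regions=3, seed=11))
        b = generate_dataset(SyntheticConfig(n_regions=3, seed=11))
        pd.testing.assert_frame_equal(a.population.data, b.population.data)
        pd.testing.assert_frame_equal(a.cases.data, b.cases.data)
        pd.testing.assert_frame_equal(a.measurements, b.measurements)

    def test_different_seeds_differ(self):
        a = generate_dataset(SyntheticConfig(n_regions=3, seed=1))
        b = generate_dataset(SyntheticConfig(n_regions=3, seed=2))
        assert not a.cases.data["value"].equals(b.cases.data["value"])


class TestRadonSurveys:
    def test_pooled_flat_gm_near_published_1991_value(self):
        meas, _ = generate_radon_surveys(SyntheticConfig(seed=0))
        flats = meas.query("dwelling == 'flat' and survey_id == '1991'")
        gm = geometric_mean(flats["concentration"])
        assert abs(gm - 62.0) / 62.0 < 0.15

    def test_house_to_flat_gm_contrast_roughly_twofold(self):
        truth = true_exposure_sets(SyntheticConfig())
        avg = truth.lookup("average").unstack("dwelling")
        ratio = avg["house"] / avg["flat"]
        assert (ratio > 1.2).all()
        nat = avg.mean()
        assert nat["house"] / nat["flat"] == pytest.approx(90 / 50, rel=0.25)

    def test_second_survey_scaled_below_first(self):
        truth = true_exposure_sets(SyntheticConfig())
        a = truth.lookup("1991")
        b = truth.lookup("2006").reindex(a.index)
        assert (b < a).all()

    def test_degenerate_gsd_collapses_to_cell_gm(self):
        cfg = SyntheticConfig(
            n_regions=2, seed=3, radon_gsd_flat=1.0, radon_gsd_house=1.0
        )
        meas, truth = generate_radon_surveys(cfg)
        merged = meas.merge(
            truth.data, on=["region", "dwelling", "survey_id"]
        )
        assert np.allclose(merged["concentration"], merged["gm_concentration"])

    def test_sample_gm_equals_log_mean_oracle(self):
        meas, _ = generate_radon_surveys(SyntheticConfig(n_regions=2, seed=4))
        cell = meas.query(
            "region == 'R01' and dwelling == 'house' and survey_id == '1991'"
        )["concentration"]
        assert geometric_mean(cell) == pytest.approx(
            np.exp(np.mean(np.log(cell))), abs=1e-12
        )


class TestSmokingSeries:
    def test_flats_exceed_houses_by_two_points_every_year(self):
        series = generate_smoking_series(SyntheticConfig())
        by_row = series.pivot_table(
            index=["year", "age_group", "sex"], columns="dwelling",
            values="current",
        )
        # strictly higher in flats in every stratum ...
        assert (by_row["flat"] > by_row["house"]).all()
        # ... and the annual contrast is at least two percentage points
        by_year = series.pivot_table(
            index="year", columns="dwelling", values="current"
        )
        assert ((by_year["flat"] - by_year["house"]) >= 0.02).all()

    def test_rows_are_proper_distributions(self):
        series = generate_smoking_series(SyntheticConfig())
        sums = series[["current", "former", "never"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_oldest_band_left_missing(self):
        series = generate_smoking_series(SyntheticConfig())
        assert "85+" not in set(series["age_group"])

    def test_men_decline_women_rise(self):
        series = generate_smoking_series(SyntheticConfig())
        trend = series.groupby(["sex", "year"])["current"].mean()
        assert trend["men"].is_monotonic_decreasing
        assert trend["women"].is_monotonic_increasing


class TestCases:
    def test_null_err_decouples_rates_from_radon(self):
        cfg = SyntheticConfig(seed=9, true_err_per_100bq=0.0)
        ds = generate_dataset(cfg)
        df = ds.cases.data.merge(
            ds.population.data, on=["region", "age_group", "sex", "dwelling"],
            suffixes=("_cases", "_pop"),
        )
        df = df[df["age_group"].isin(["65-74", "75-84"])]
        df["rate"] = df["value_cases"] / df["value_pop"]
        df = df.join(ds.true_gm.rename("gm"), on=["region", "dwelling"])
        slope = stats.linregress(df["gm"], df["rate"]).slope
        # with beta = 0 the dose-response slope is consistent with zero
        se = stats.linregress(df["gm"], df["rate"]).stderr
        assert abs(slope) < 3 * se

    def test_current_to_never_incidence_ratio_is_smoking_rr(self):
        cfg = SyntheticConfig()
        ds = generate_dataset(cfg)
        df = expected_cases_frame(
            ds.population, ds.true_gm, ds.smoking_truth, cfg
        )
        # equal radon within a stratum: expected incidence ratio = RR = 15
        inc_cur = df["expected_current"] / (df["population"] * df["current"])
        inc_nev = df["expected_never"] / (df["population"] * df["never"])
        assert np.allclose(inc_cur / inc_nev, 15.0, rtol=1e-9)

    def test_doubling_beta_doubles_attributable_at_first_order(self):
        cfg = replace(SyntheticConfig(), true_err_per_100bq=1.0)
        cfg2 = replace(cfg, true_err_per_100bq=2.0)
        ds = generate_dataset(cfg)
        m1, _ = expected_avoidable(
            ds.population, ds.true_gm, ds.smoking_truth, cfg, floor=0.0
        )
        m2, _ = expected_avoidable(
            ds.population, ds.true_gm, ds.smoking_truth, cfg2, floor=0.0
        )
        # AF is concave, so the ratio is slightly below 2 but near it
        assert 1.9 < m2 / m1 <= 2.0

    def test_national_expected_count_matches_study_scale(self):
        cfg = SyntheticConfig()
        ds = generate_dataset(cfg)
        expected = expected_cases_frame(
            ds.population, ds.true_gm, ds.smoking_truth, cfg
        )["expected_total"].sum()
        assert expected == pytest.approx(2694, rel=0.02)

    def test_mismatched_strata_rejected(self, dataset):
        cfg = dataset.config
        truncated_gm = dataset.true_gm.iloc[:-2]
        with pytest.raises(Exception, match="GM|exposure"):
            generate_cases(
                dataset.population, truncated_gm, dataset.smoking_truth, cfg
            )
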