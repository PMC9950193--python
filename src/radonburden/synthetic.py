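"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a national setting: ~5.28 million people in 20
regions, 63% living in houses, indoor radon lognormal within each
(region, dwelling) cell with roughly two-fold higher geometric means in
houses (national GMs near 90 Bq m-3 in houses and 50 in flats, split into
two surveys with the second lower than the first), current smoking more
prevalent among flat dwellers (14% vs 10%) — the inverse smoking-radon
correlation that dwelling type induces — and Poisson lung-cancer counts
generated under baseline incidence x smoking relative risk x linear radon
relative risk.

Because the cases are generated from the same linear-ERR model the
attribution engine inverts, the expected avoidable burden has a closed
form (:func:`expected_avoidable`), which downstream parameter-recovery
tests check against the pipeline's estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    AGE_GROUPS,
    DWELLINGS,
    SEXES,
    SMOKING_CATEGORIES,
    ERRSpec,
    SmokingRelativeRisks,
    StratifiedTable,
    ValidationError,
    default_regions,
    full_cross,
)
from .exposure import ExposureSet, build_exposure_sets
from .attribution import attributable_fraction

# Demographic profiles (fractions). Age structure decreasing with age;
# flats are relatively more common among the young and the very old; the
# oldest bands skew female.
_AGE_SHARE = {
    "0-34": 0.402, "35-44": 0.127, "45-54": 0.127, "55-64": 0.134,
    "65-74": 0.124, "75-84": 0.063, "85+": 0.023,
}
_FLAT_SHARE_BY_AGE = {
    "0-34": 0.39, "35-44": 0.39, "45-54": 0.30, "55-64": 0.32,
    "65-74": 0.35, "75-84": 0.42, "85+": 0.49,
}
_MEN_SHARE_BY_AGE = {
    "0-34": 0.51, "35-44": 0.51, "45-54": 0.50, "55-64": 0.50,
    "65-74": 0.47, "75-84": 0.42, "85+": 0.33,
}
# Lung-cancer incidence age profile (multiplier on the baseline rate):
# ~80% of cases occur at ages 65+.
_INCIDENCE_AGE_MULT = {
    "0-34": 0.004, "35-44": 0.05, "45-54": 0.5, "55-64": 2.4,
    "65-74": 6.5, "75-84": 11.0, "85+": 12.0,
}
_INCIDENCE_SEX_MULT = {"men": 1.35, "women": 0.72}
# Current-smoking age profile (multiplier on the dwelling base rate) and
# the former/current ratio rising with age (older cohorts have quit).
_SMOKING_AGE_MULT = {
    "0-34": 0.80, "35-44": 1.35, "45-54": 1.50, "55-64": 1.30,
    "65-74": 0.85, "75-84": 0.60, "85+": 0.40,
}
_FORMER_OVER_CURRENT = {
    "0-34": 0.35, "35-44": 0.90, "45-54": 1.40, "55-64": 2.00,
    "65-74": 2.90, "75-84": 3.60, "85+": 4.00,
}
_SMOKING_SEX_MULT = {"men": 1.15, "women": 0.85}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study population.

    Concentrations are in Bq m-3, prevalences per 1, the baseline
    never-smoker incidence in cases per 100,000 person-years. The radon
    GMs are national averages over the two surveys; per-survey levels are
    obtained by splitting each cell's average in the ratio of the
    published national survey GMs (houses 109:78, flats 62:37), and
    regional GMs follow a smooth log-gradient spanning the observed
    regional extremes (flats ~32-86, houses ~44-194).
    """

    n_regions: int = 20
    seed: int = 0
    population_total: float = 5_281_077.0
    radon_gm_house: float = 90.0
    radon_gm_flat: float = 50.0
    radon_gsd_house: float = 2.7
    radon_gsd_flat: float = 2.1
    survey_gms_house: tuple[float, float] = (109.0, 78.0)
    survey_gms_flat: tuple[float, float] = (62.0, 37.0)
    regional_span_house: tuple[float, float] = (44.0, 194.0)
    regional_span_flat: tuple[float, float] = (32.0, 86.0)
    smoking_prev_flat: float = 0.14
    smoking_prev_house: float = 0.10
    smoking_rr: SmokingRelativeRisks = field(default_factory=SmokingRelativeRisks)
    true_err_per_100bq: float = 16.0
    true_err_small_cell: float = 31.0
    small_cell_fraction: float = 0.14
    baseline_incidence_never: float = 6.65
    survey_size: int = 3000
    years: tuple[int, int] = (2000, 2015)
    reference_smoking_year: int = 2007

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValidationError("need at least one region")
        for name in ("radon_gm_house", "radon_gm_flat", "radon_gsd_house",
                     "radon_gsd_flat", "population_total"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.radon_gsd_house < 1 or self.radon_gsd_flat < 1:
            raise ValidationError("geometric SDs must be >= 1")
        for name in ("smoking_prev_flat", "smoking_prev_house", "small_cell_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")

    @property
    def regions(self) -> list[str]:
        return default_regions(self.n_regions)


def _region_weights(n: int) -> np.ndarray:
    """Uneven regional population weights (a few large districts)."""
    w = np.exp(-1.5 * np.arange(n) / max(n - 1, 1))
    return w / w.sum()


def generate_population(config: SyntheticConfig) -> StratifiedTable:
    """Full-cross population table (persons, real-valued)."""
    regions = config.regions
    w = dict(zip(regions, _region_weights(config.n_regions)))

    def value(region, age, sex, dwelling):
        flat = _FLAT_SHARE_BY_AGE[age]
        dw = flat if dwelling == "flat" else 1.0 - flat
        men = _MEN_SHARE_BY_AGE[age]
        sx = men if sex == "men" else 1.0 - men
        return config.population_total * w[region] * _AGE_SHARE[age] * sx * dw

    return full_cross(regions, value, quantity="population", units="persons")


def _regional_log_profile(config: SyntheticConfig) -> dict[str, dict[str, float]]:
    """Per-(region, dwelling) average-of-surveys GMs.

    A log-linear gradient over the region index spans the configured
    regional extremes, recentred (population-weighted) so the national GM
    matches the configured national value per dwelling type.
    """
    regions = config.regions
    w = _region_weights(config.n_regions)
    out: dict[str, dict[str, float]] = {}
    spans = {"flat": config.regional_span_flat, "house": config.regional_span_house}
    nat = {"flat": config.radon_gm_flat, "house": config.radon_gm_house}
    for dwelling, (lo, hi) in spans.items():
        if config.n_regions == 1:
            logs = np.array([np.log(nat[dwelling])])
        else:
            logs = np.linspace(np.log(lo), np.log(hi), config.n_regions)
            logs = logs + (np.log(nat[dwelling]) - np.sum(w * logs))
        out[dwelling] = dict(zip(regions, np.exp(logs)))
    return out


def true_exposure_sets(config: SyntheticConfig) -> ExposureSet:
    """The generator's true per-cell survey GMs (and their average)."""
    profile = _regional_log_profile(config)
    pairs = {"flat": config.survey_gms_flat, "house": config.survey_gms_house}
    rows = []
    for dwelling in DWELLINGS:
        a, b = pairs[dwelling]
        factors = {"1991": 2 * a / (a + b), "2006": 2 * b / (a + b)}
        for region, gm_avg in profile[dwelling].items():
            for survey, f in factors.items():
                rows.append(
                    {"region": region, "dwelling": dwelling, "survey_id": survey,
                     "gm_concentration": gm_avg * f}
                )
    return build_exposure_sets(pd.DataFrame(rows))


def generate_radon_surveys(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, ExposureSet]:
    """Simulated measurement campaigns plus the true exposure sets.

    Measurements are lognormal around each cell's true survey GM with a
    per-dwelling GSD (houses more variable than flats); the number of
    detectors per cell is proportional to the cell's population share,
    with a minimum of 3.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    truth = true_exposure_sets(config)
    w = dict(zip(config.regions, _region_weights(config.n_regions)))
    flat_meas_share = 0.4  # detectors split roughly like the housing stock
    sigmas = {
        "flat": np.log(config.radon_gsd_flat),
        "house": np.log(config.radon_gsd_house),
    }
    rows = []
    surveys = truth.data.loc[truth.data["survey_id"] != "average"]
    for rec in surveys.itertuples(index=False):
        share = flat_meas_share if rec.dwelling == "flat" else 1 - flat_meas_share
        n = max(3, int(round(config.survey_size * w[rec.region] * share)))
        draws = rng.lognormal(
            mean=np.log(rec.gm_concentration), sigma=sigmas[rec.dwelling], size=n
        )
        rows.append(
            pd.DataFrame(
                {"region": rec.region, "dwelling": rec.dwelling,
                 "survey_id": rec.survey_id, "concentration": draws}
            )
        )
    return pd.concat(rows, ignore_index=True), truth


def _current_prevalence(config, age, sex, dwelling, year) -> float:
    base = (
        config.smoking_prev_flat if dwelling == "flat" else config.smoking_prev_house
    )
    if sex == "men":  # mild decline for men, mild rise for women
        year_mult = 1.0 + 0.010 * (config.reference_smoking_year - year)
    else:
        year_mult = 1.0 - 0.008 * (config.reference_smoking_year - year)
    return base * _SMOKING_AGE_MULT[age] * _SMOKING_SEX_MULT[sex] * year_mult


def _prevalence_row(config, age, sex, dwelling, year) -> dict[str, float]:
    cur = _current_prevalence(config, age, sex, dwelling, year)
    former = min(cur * _FORMER_OVER_CURRENT[age], 0.6)
    never = 1.0 - cur - former
    if never < 0:
        raise ValidationError("smoking profile yields never-prevalence < 0")
    return {"current": cur, "former": former, "never": never}


def generate_smoking_series(config: SyntheticConfig) -> pd.DataFrame:
    """Annual prevalence tables for the configured year range.

    Current smoking is higher in flats than houses in every stratum, men
    decline and women rise mildly over the years, and the 85+ band is
    absent — downstream imputation has to fill it, as with real surveys.
    """
    rows = []
    y0, y1 = config.years
    for year in range(y0, y1 + 1):
        for age in AGE_GROUPS[:-1]:  # 85+ deliberately missing
            for sex in SEXES:
                for dwelling in DWELLINGS:
                    rows.append(
                        {"year": year, "age_group": age, "sex": sex,
                         "dwelling": dwelling,
                         **_prevalence_row(config, age, sex, dwelling, year)}
                    )
    return pd.DataFrame(rows)


def smoking_truth_table(config: SyntheticConfig, year: int | None = None) -> pd.DataFrame:
    """Complete (all-ages) prevalence table used as the generating truth."""
    year = config.reference_smoking_year if year is None else year
    rows = [
        {"age_group": age, "sex": sex, "dwelling": dwelling,
         **_prevalence_row(config, age, sex, dwelling, year)}
        for age in AGE_GROUPS for sex in SEXES for dwelling in DWELLINGS
    ]
    return pd.DataFrame(rows)


def expected_cases_frame(
    population: StratifiedTable,
    exposure_gm: pd.Series,
    smoking_truth: pd.DataFrame,
    config: SyntheticConfig,
    endpoint: str = "all_lung",
) -> pd.DataFrame:
    """Expected cases per stratum x smoking category under the DGP.

    E[cases] = N * p_smoking * I_never * RR_smoking * (1 + beta X / 100)
    with age and sex incidence multipliers on I_never. Returns the stratum
    frame with columns expected_current/former/never and the cell GM.
    """
    df = population.data.rename(columns={"value": "population"}).copy()
    df = df.join(exposure_gm.rename("gm"), on=["region", "dwelling"])
    if df["gm"].isna().any():
        raise ValidationError("exposure GM missing for some (region, dwelling) cell")
    keys = ["age_group", "sex", "dwelling"]
    df = df.merge(smoking_truth[keys + list(SMOKING_CATEGORIES)], on=keys,
                  how="left", validate="many_to_one")
    if df[list(SMOKING_CATEGORIES)].isna().any().any():
        raise ValidationError("smoking truth table does not cover all strata")
    if endpoint == "all_lung":
        base = config.baseline_incidence_never / 1e5
        beta = config.true_err_per_100bq / 100.0
    elif endpoint == "small_cell":
        base = config.small_cell_fraction * config.baseline_incidence_never / 1e5
        beta = config.true_err_small_cell / 100.0
    else:
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    age_mult = df["age_group"].map(_INCIDENCE_AGE_MULT).to_numpy()
    sex_mult = df["sex"].map(_INCIDENCE_SEX_MULT).to_numpy()
    rr_radon = 1.0 + beta * df["gm"].to_numpy() / 100.0
    rr_smoke = config.smoking_rr.as_series()
    incidence_never = base * age_mult * sex_mult * rr_radon
    for cat in SMOKING_CATEGORIES:
        df[f"expected_{cat}"] = (
            df["population"].to_numpy() * df[cat].to_numpy()
            * incidence_never * rr_smoke[cat]
        )
    df["expected_total"] = sum(df[f"expected_{c}"] for c in SMOKING_CATEGORIES)
    return df


def generate_cases(
    population: StratifiedTable,
    exposure_gm: pd.Series,
    smoking_truth: pd.DataFrame,
    config: SyntheticConfig,
    endpoint: str = "all_lung",
    rng: np.random.Generator | None = None,
) -> StratifiedTable:
    """Poisson case counts per stratum (smoking class summed out).

    Counts are drawn per stratum and smoking class and then summed over
    classes, mirroring that the cancer registry does not record smoking.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2 if endpoint == "all_lung" else 3])
        )
    df = expected_cases_frame(population, exposure_gm, smoking_truth, config, endpoint)
    counts = np.zeros(len(df))
    for cat in SMOKING_CATEGORIES:
        counts += rng.poisson(df[f"expected_{cat}"].to_numpy())
    out = df[["region", "age_group", "sex", "dwelling"]].copy()
    out["value"] = counts
    return StratifiedTable(
        out, quantity=f"cases_{endpoint}", units="cases",
        regions=tuple(config.regions),
    )


def expected_avoidable(
    population: StratifiedTable,
    exposure_gm: pd.Series,
    smoking_truth: pd.DataFrame,
    config: SyntheticConfig,
    floor: float = 25.0,
    endpoint: str = "all_lung",
) -> tuple[float, float]:
    """Closed-form mean and Monte Carlo SD of the national avoidable count.

    The attribution estimator applied to Poisson counts L_s is
    sum_s L_s * w_s with w_s = AF(X_s) - AF(floor), so its expectation is
    sum_s E[L_s] w_s and its variance sum_s E[L_s] w_s^2.
    """
    df = expected_cases_frame(population, exposure_gm, smoking_truth, config, endpoint)
    err = (
        config.true_err_per_100bq if endpoint == "all_lung"
        else config.true_err_small_cell
    )
    w = attributable_fraction(df["gm"].to_numpy(), err) - attributable_fraction(
        floor, err
    )
    mean = float(np.sum(df["expected_total"].to_numpy() * w))
    var = float(np.sum(df["expected_total"].to_numpy() * w**2))
    return mean, np.sqrt(var)


@dataclass
class SyntheticDataset:
    """Complete synthetic inputs for one seed."""

    config: SyntheticConfig
    population: StratifiedTable
    cases: StratifiedTable
    cases_small_cell: StratifiedTable
    measurements: pd.DataFrame
    exposure: ExposureSet          # true survey GMs + average
    smoking_series: pd.DataFrame   # annual tables, 85+ missing
    smoking_truth: pd.DataFrame    # generating truth incl. 85+

    @property
    def true_gm(self) -> pd.Series:
        return self.exposure.lookup("average")


def generate_dataset(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """One-call generation of all four input tables plus the truth objects."""
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    population = generate_population(config)
    measurements, exposure = generate_radon_surveys(config)
    series = generate_smoking_series(config)
    truth = smoking_truth_table(config)
    gm = exposure.lookup("average")
    cases = generate_cases(population, gm, truth, config, "all_lung")
    cases_sc = generate_cases(population, gm, truth, config, "small_cell")
    return SyntheticDataset(
        config=config, population=population, cases=cases,
        cases_small_cell=cases_sc, measurements=measurements,
        exposure=exposure, smoking_series=series, smoking_truth=truth,
    )
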