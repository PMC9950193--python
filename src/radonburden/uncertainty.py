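"""Monte Carlo propagation of ERR, smoking-year and survey uncertainty.

Each run draws (1) one ERR coefficient from its normal uncertainty
distribution, applied identically across all strata, (2) one calendar
year, uniformly from the configured range, whose smoking prevalence table
drives the smoking margin, and (3) per (region, dwelling) cell one of the
two survey GMs with probability 1/2 (the "strictly bimodal" radon
distribution). The avoidable-case aggregates are recomputed per run;
negative aggregates are truncated to zero (radon is not protective) and
the mean with the 2.5% and 97.5% empirical quantiles of the resulting
distribution is reported per margin.

Five named simulations (A-E) correspond to published ERR uncertainty
distributions: A [8.4, 3.3^2] (uncorrected European pooled estimate),
B [16, 6.6^2] (corrected), C [9.5, 2.3^2] and D [17, 6.1^2] (European +
North American pooled, uncorrected/corrected) for all lung cancers, and
E [27, 13.7^2] for small cell carcinomas. A "methods_text" preset carries
the slightly different parameter readings (A mean 8, C sd 2.43, D sd 6.18)
that circulate for the same distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allocation import allocation_shares
from .data_model import (
    SMOKING_CATEGORIES,
    SmokingRelativeRisks,
    StratifiedTable,
    ValidationError,
)
from .exposure import SURVEY_IDS, ExposureSet
from .smoking import DataError, assemble_prevalence

_TABLE_PARAMS = {
    "A": (8.4, 3.3, "all_lung"),
    "B": (16.0, 6.6, "all_lung"),
    "C": (9.5, 2.3, "all_lung"),
    "D": (17.0, 6.1, "all_lung"),
    "E": (27.0, 13.7, "small_cell"),
}
_TEXT_PARAMS = {
    "A": (8.0, 3.3, "all_lung"),
    "B": (16.0, 6.6, "all_lung"),
    "C": (9.5, 2.43, "all_lung"),
    "D": (17.0, 6.18, "all_lung"),
    "E": (27.0, 13.7, "small_cell"),
}


@dataclass(frozen=True)
class SimulationSpec:
    """One Monte Carlo simulation: an ERR prior plus sampling policy."""

    err_mean: float
    err_sd: float
    sim_id: str = "custom"
    endpoint: str = "all_lung"
    reps: int = 10_000
    year_range: tuple[int, int] = (2000, 2015)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")
        if not self.err_sd > 0:
            raise ValidationError("ERR sd must be positive")


def simulation_spec(
    sim_id: str,
    reps: int = 10_000,
    seed: int = 0,
    year_range: tuple[int, int] = (2000, 2015),
    preset: str = "table",
) -> SimulationSpec:
    """Named simulation A-E from the published parameter sets."""
    params = {"table": _TABLE_PARAMS, "methods_text": _TEXT_PARAMS}.get(preset)
    if params is None:
        raise ValidationError(f"unknown preset {preset!r}; use 'table' or 'methods_text'")
    if sim_id not in params:
        raise ValidationError(f"unknown simulation {sim_id!r}; use one of A-E")
    mean, sd, endpoint = params[sim_id]
    return SimulationSpec(
        err_mean=mean, err_sd=sd, sim_id=sim_id, endpoint=endpoint,
        reps=reps, year_range=year_range, seed=seed,
    )


def summarize(draws, quantiles: tuple[float, float] = (0.025, 0.975)) -> tuple[float, float, float]:
    """(mean, lower, upper) of a draw vector.

    Quantiles use the linear-interpolation definition (numpy's default),
    so for draws 1..M the p-quantile is 1 + p (M - 1).
    """
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot summarise an empty draw vector")
    lo, hi = np.quantile(x, quantiles, method="linear")
    return float(x.mean()), float(lo), float(hi)


@dataclass
class UncertaintyResult:
    """Mean and 95% uncertainty interval of avoidable cases per margin."""

    table: pd.DataFrame           # index (margin, level); mean, lower, upper
    truncated: pd.Series          # runs truncated to zero per margin level
    spec: SimulationSpec
    draws: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            f"Simulation {self.spec.sim_id}: ERR ~ N({self.spec.err_mean:g}, "
            f"{self.spec.err_sd:g}^2), {self.spec.reps} runs, endpoint "
            f"{self.spec.endpoint}",
            "-" * 60,
            f"{'margin':<22}{'mean':>10}{'2.5%':>10}{'97.5%':>10}",
        ]
        for (margin, level), row in self.table.iterrows():
            lines.append(
                f"{margin + ': ' + level:<22}{row['mean']:>10.1f}"
                f"{row['lower']:>10.1f}{row['upper']:>10.1f}"
            )
        return "\n".join(lines)


def prepare_year_tables(
    smoking_series: pd.DataFrame,
    year_range: tuple[int, int],
    flat_share=0.5,
) -> dict[int, pd.DataFrame]:
    """Fully processed (imputed, dwelling-filled) prevalence per year."""
    years = range(year_range[0], year_range[1] + 1)
    available = set(smoking_series["year"].unique())
    missing = [y for y in years if y not in available]
    if missing:
        raise DataError(
            f"smoking series lacks year(s) {missing}; "
            f"available: {sorted(available)}"
        )
    return {
        y: assemble_prevalence(smoking_series, reference_year=y, lag=0,
                               flat_share=flat_share)
        for y in years
    }


def run_simulation(
    spec: SimulationSpec,
    population: StratifiedTable,
    cases: StratifiedTable,
    exposure: ExposureSet,
    smoking_series: pd.DataFrame | None = None,
    floor: float = 25.0,
    smoking_rr: SmokingRelativeRisks = SmokingRelativeRisks(),
    flat_share=0.5,
    survey_ids: Sequence[str] = SURVEY_IDS,
    sample_surveys: bool = True,
    per_cell_survey: bool = True,
    truncation: str = "margin",
    keep_draws: bool = False,
    chunk: int = 2000,
) -> UncertaintyResult:
    """Propagate parameter uncertainty into the avoidable-case distribution.

    ``truncation`` is ``"margin"`` (negative *aggregates* set to zero, the
    reported policy), ``"stratum"`` (truncate before summing; changes the
    sums) or ``"none"``. ``sample_surveys=False`` pins exposure to the
    average of the two surveys, which together with a single-year range
    and a tiny ``err_sd`` collapses the simulation onto the deterministic
    point estimate.
    """
    if truncation not in ("margin", "stratum", "none"):
        raise ValidationError("truncation must be 'margin', 'stratum' or 'none'")
    rng = np.random.default_rng(spec.seed)
    df = cases.data.rename(columns={"value": "cases"}).copy()
    L = df["cases"].to_numpy(float)
    cell = df.set_index(["region", "dwelling"]).index
    gm_a = exposure.lookup(survey_ids[0]).reindex(cell).to_numpy(float)
    gm_b = exposure.lookup(survey_ids[1]).reindex(cell).to_numpy(float)
    gm_avg = 0.5 * (gm_a + gm_b)
    if np.isnan(gm_a).any() or np.isnan(gm_b).any():
        raise ValidationError("both surveys must cover every (region, dwelling) cell")

    # per-year allocation shares for the smoking margin (precomputed so a
    # missing year fails before the loop starts)
    share_by_year: dict[int, np.ndarray] = {}
    if smoking_series is not None:
        keys = ["age_group", "sex", "dwelling"]
        for year, table in prepare_year_tables(
            smoking_series, spec.year_range, flat_share
        ).items():
            prev = df[keys].merge(table[keys + list(SMOKING_CATEGORIES)], on=keys,
                                  how="left", validate="many_to_one")
            if prev[list(SMOKING_CATEGORIES)].isna().any().any():
                raise DataError(f"smoking table for {year} does not cover all strata")
            share_by_year[year] = allocation_shares(prev, smoking_rr).to_numpy()

    years = np.arange(spec.year_range[0], spec.year_range[1] + 1)
    margins: dict[tuple[str, str], list[np.ndarray]] = {}
    masks = {("overall", "total"): np.ones(len(df), bool)}
    for d in ("flat", "house"):
        masks[("dwelling", d)] = (df["dwelling"] == d).to_numpy()
    for s in ("men", "women"):
        masks[("sex", s)] = (df["sex"] == s).to_numpy()

    def _accumulate(key, values):
        margins.setdefault(key, []).append(values)

    done = 0
    while done < spec.reps:
        m = min(chunk, spec.reps - done)
        err = rng.normal(spec.err_mean, spec.err_sd, size=m)
        year_idx = rng.integers(0, len(years), size=m)
        if sample_surveys:
            if per_cell_survey:
                pick = rng.integers(0, 2, size=(m, len(L))).astype(bool)
            else:
                pick = np.repeat(
                    rng.integers(0, 2, size=(m, 1)).astype(bool), len(L), axis=1
                )
            X = np.where(pick, gm_a[None, :], gm_b[None, :])
        else:
            X = np.broadcast_to(gm_avg, (m, len(L)))
        beta = err[:, None] / 100.0
        denom_obs = 1.0 + beta * X / 100.0
        denom_floor = 1.0 + beta * floor / 100.0
        af_obs = 1.0 - 1.0 / np.where(np.abs(denom_obs) < 1e-12, 1e-12, denom_obs)
        af_floor = 1.0 - 1.0 / np.where(
            np.abs(denom_floor) < 1e-12, 1e-12, denom_floor
        )
        avoid = L[None, :] * (af_obs - af_floor)
        if truncation == "stratum":
            avoid = np.clip(avoid, 0.0, None)
        for key, mask in masks.items():
            _accumulate(key, avoid[:, mask].sum(axis=1))
        if share_by_year:
            cats = np.zeros((m, len(SMOKING_CATEGORIES)))
            for yi in np.unique(year_idx):
                sel = year_idx == yi
                cats[sel] = avoid[sel] @ share_by_year[years[yi]]
            for j, cat in enumerate(SMOKING_CATEGORIES):
                _accumulate(("smoking", cat), cats[:, j])
        done += m

    rows, trunc, draw_cols = [], {}, {}
    for key, chunks in margins.items():
        vec = np.concatenate(chunks)
        n_neg = int((vec < 0).sum())
        if truncation == "margin":
            vec = np.clip(vec, 0.0, None)
        mean, lo, hi = summarize(vec)
        rows.append({"margin": key[0], "level": key[1],
                     "mean": mean, "lower": lo, "upper": hi})
        trunc[key] = n_neg if truncation == "margin" else 0
        if keep_draws:
            draw_cols[f"{key[0]}:{key[1]}"] = vec
    table = pd.DataFrame(rows).set_index(["margin", "level"])
    return UncertaintyResult(
        table=table,
        truncated=pd.Series(trunc),
        spec=spec,
        draws=pd.DataFrame(draw_cols) if keep_draws else None,
    )
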