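"""Radon exposure assessment: geometric means per (region, dwelling) cell.

Indoor radon is summarised per region and dwelling type by the geometric
mean (GM) of measured activity concentrations, the standard summary for
approximately lognormal indoor exposure. Three exposure sets drive the
analysis: the two national measurement surveys and their arithmetic
average, plus a "strictly bimodal" sampler over the two surveys used by
the uncertainty engine. Every resident of a (region, dwelling) cell is
assigned that cell's GM; exposure is assumed independent of age, sex and
smoking within the cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import DWELLINGS, SchemaError, ValidationError

EXPOSURE_COLUMNS = ["region", "dwelling", "survey_id", "gm_concentration"]
SURVEY_IDS = ("1991", "2006")
AVERAGE_ID = "average"


def geometric_mean(measurements) -> float:
    """GM = exp(mean(log x)) of strictly positive concentrations."""
    x = np.asarray(measurements, dtype=float)
    if x.size == 0:
        raise ValidationError("geometric mean of empty input is undefined")
    if (x <= 0).any():
        raise ValidationError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(x))))


@dataclass
class ExposureSet:
    """GM radon concentration (Bq m-3) per (region, dwelling, survey_id)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in EXPOSURE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"exposure table missing column(s): {missing}")
        df = df[EXPOSURE_COLUMNS].copy()
        df["survey_id"] = df["survey_id"].astype(str)
        if (df["gm_concentration"] <= 0).any():
            raise ValidationError("geometric mean concentrations must be positive")
        if df.duplicated(["region", "dwelling", "survey_id"]).any():
            raise ValidationError("duplicate (region, dwelling, survey_id) record")
        self.data = df.reset_index(drop=True)

    def survey(self, survey_id: str) -> pd.DataFrame:
        """Per-(region, dwelling) GMs for one survey, as a two-key frame."""
        sel = self.data.loc[self.data["survey_id"] == str(survey_id)]
        if sel.empty:
            raise ValidationError(
                f"no records for survey {survey_id!r}; "
                f"available: {sorted(self.data['survey_id'].unique())}"
            )
        return sel.drop(columns="survey_id").reset_index(drop=True)

    def lookup(self, survey_id: str) -> pd.Series:
        """GM indexed by (region, dwelling) for merging onto strata."""
        return self.survey(survey_id).set_index(["region", "dwelling"])[
            "gm_concentration"
        ]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ExposureSet":
        return cls(pd.read_csv(path, dtype={"region": str, "survey_id": str}))


def gms_from_measurements(measurements: pd.DataFrame) -> ExposureSet:
    """Collapse raw measurements to per-cell survey GMs.

    ``measurements`` needs columns region, dwelling, survey_id,
    concentration (one row per measured dwelling).
    """
    for col in ("region", "dwelling", "survey_id", "concentration"):
        if col not in measurements.columns:
            raise SchemaError(f"measurement table missing column {col!r}")
    if (measurements["concentration"] <= 0).any():
        raise ValidationError("measured concentrations must be positive")
    gm = (
        measurements.groupby(["region", "dwelling", "survey_id"], sort=True)[
            "concentration"
        ]
        .apply(geometric_mean)
        .rename("gm_concentration")
        .reset_index()
    )
    return ExposureSet(gm)


def build_exposure_sets(
    source: pd.DataFrame | ExposureSet,
    survey_ids: Sequence[str] = SURVEY_IDS,
) -> ExposureSet:
    """Assemble the three exposure sets: each survey plus their average.

    ``source`` is either raw measurements (with a ``concentration`` column)
    or already-aggregated per-survey GMs; the operation is idempotent on the
    latter. The "average" set is the arithmetic mean of the two survey GMs
    per (region, dwelling) cell — averaging is done on the GM summaries, not
    on pooled raw measurements. Both surveys must cover every cell.
    """
    if isinstance(source, ExposureSet):
        gms = source.data
    elif "concentration" in source.columns:
        gms = gms_from_measurements(source).data
    else:
        gms = ExposureSet(source).data
    gms = gms.loc[gms["survey_id"] != AVERAGE_ID]
    wide = gms.pivot_table(
        index=["region", "dwelling"],
        columns="survey_id",
        values="gm_concentration",
    )
    missing_surveys = [s for s in survey_ids if s not in wide.columns]
    if missing_surveys:
        raise ValidationError(f"no records at all for survey(s) {missing_surveys}")
    wide = wide[list(survey_ids)]
    if wide.isna().any().any():
        cell = wide.loc[wide.isna().any(axis=1)].iloc[0]
        region, dwelling = cell.name
        absent = [s for s in survey_ids if pd.isna(cell[s])]
        raise ValidationError(
            f"cell (region={region}, dwelling={dwelling}) missing survey(s) {absent}"
        )
    long = wide.reset_index().melt(
        id_vars=["region", "dwelling"],
        var_name="survey_id",
        value_name="gm_concentration",
    )
    avg = wide.mean(axis=1).rename("gm_concentration").reset_index()
    avg["survey_id"] = AVERAGE_ID
    return ExposureSet(pd.concat([long, avg], ignore_index=True))


def sample_bimodal(
    exposure: ExposureSet,
    rng: np.random.Generator,
    survey_ids: Sequence[str] = SURVEY_IDS,
    per_cell: bool = True,
) -> pd.Series:
    """Draw one GM per (region, dwelling) cell from the two surveys.

    Each cell's concentration is the 1991 GM or the 2006 GM with
    probability 1/2 each. With ``per_cell=False`` a single survey is picked
    for all cells at once (the more correlated alternative, kept behind this
    switch because the published procedure does not say which was used).
    Returns a GM Series indexed by (region, dwelling).
    """
    a = exposure.lookup(survey_ids[0])
    b = exposure.lookup(survey_ids[1]).reindex(a.index)
    if b.isna().any():
        raise ValidationError("surveys do not cover the same (region, dwelling) cells")
    if per_cell:
        pick = rng.integers(0, 2, size=len(a)).astype(bool)
    else:
        pick = np.repeat(bool(rng.integers(0, 2)), len(a))
    return pd.Series(np.where(pick, a.to_numpy(), b.to_numpy()), index=a.index)


@dataclass(frozen=True)
class SeasonalCorrection:
    """Multiplicative correction factors by measurement-period label.

    Single-period measurements are corrected to annual averages by a
    positive factor per period; the identity mapping is the default (the
    published coefficient tables are treated as external configuration).
    """

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        for period, f in self.factors.items():
            if not f > 0:
                raise ValidationError(f"seasonal factor for {period!r} must be > 0")

    def __call__(self, measurement: float, period: str) -> float:
        return apply_seasonal_correction(measurement, period, self)


def apply_seasonal_correction(
    measurement: float, period: str, table: SeasonalCorrection
) -> float:
    """Scale a single-period measurement by its seasonal factor."""
    if period not in table.factors:
        raise KeyError(
            f"unknown measurement period {period!r}; "
            f"configured: {sorted(table.factors)}"
        )
    return measurement * table.factors[period]
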