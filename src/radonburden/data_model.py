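"""Shared domain types and delimited-text I/O for stratified tables.

The atomic unit of every computation is the stratum: a (region, age group,
sex, dwelling type) cell. Population counts, lung-cancer case counts and
smoking prevalences are all carried as :class:`StratifiedTable` objects,
thin validated wrappers around a pandas DataFrame with one row per stratum.

All values are real-valued internally; rounding to integers happens only
when reports are rendered, so additive identities (avoidable = attributable
minus counterfactual, margins summing to totals) hold exactly upstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Category sets. Age groups follow the seven-band stratification used for
# national lung-cancer incidence; the youngest two bands may be supplied
# collapsed as "0-44" (the form in which published population tables often
# print them), which is recorded in the table metadata.
AGE_GROUPS = ("0-34", "35-44", "45-54", "55-64", "65-74", "75-84", "85+")
AGE_GROUPS_COLLAPSED = ("0-44", "45-54", "55-64", "65-74", "75-84", "85+")
SEXES = ("men", "women")
DWELLINGS = ("flat", "house")
SMOKING_CATEGORIES = ("current", "former", "never")
ENDPOINTS = ("all_lung", "small_cell")

#: Midpoint ages (years) used when fitting trends against age group.
AGE_MIDPOINTS = {
    "0-34": 17.5,
    "0-44": 22.5,
    "35-44": 40.0,
    "45-54": 50.0,
    "55-64": 60.0,
    "65-74": 70.0,
    "75-84": 80.0,
    "85+": 90.0,
}

STRATUM_COLUMNS = ["region", "age_group", "sex", "dwelling"]


class SchemaError(ValueError):
    """A required column is missing or has the wrong form."""


class ValidationError(ValueError):
    """Values violate a domain invariant (negative count, duplicate key...)."""


def default_regions(n: int) -> list[str]:
    """Region labels R01..Rnn (stand-ins for hospital districts)."""
    if n < 1:
        raise ValidationError("need at least one region")
    return [f"R{i + 1:02d}" for i in range(n)]


def _check_levels(df: pd.DataFrame, column: str, allowed: Sequence[str]) -> None:
    bad = set(df[column].unique()) - set(allowed)
    if bad:
        raise ValidationError(
            f"column {column!r} contains unknown levels {sorted(bad)!r}; "
            f"allowed: {list(allowed)}"
        )


@dataclass
class StratifiedTable:
    """Nonnegative values indexed by (region, age_group, sex, dwelling).

    Parameters
    ----------
    data
        DataFrame with columns region, age_group, sex, dwelling, value.
    quantity
        Name of the measured quantity ("population", "cases", ...).
    units
        Units of ``value`` ("persons", "cases", "per-1").
    regions
        Declared region labels; defaults to those present in ``data``.
    collapsed_ages
        True when the 0-34/35-44 bands are supplied merged as 0-44.
    """

    data: pd.DataFrame
    quantity: str = "value"
    units: str = ""
    regions: tuple[str, ...] | None = None
    collapsed_ages: bool = False

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in STRATUM_COLUMNS + ["value"] if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        df = df[STRATUM_COLUMNS + ["value"]].copy()
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        age_levels = AGE_GROUPS_COLLAPSED if self.collapsed_ages else AGE_GROUPS
        if self.regions is None:
            self.regions = tuple(sorted(df["region"].astype(str).unique()))
        _check_levels(df, "region", self.regions)
        _check_levels(df, "age_group", age_levels)
        _check_levels(df, "sex", SEXES)
        _check_levels(df, "dwelling", DWELLINGS)
        if (df["value"] < 0).any():
            bad = df.loc[df["value"] < 0].iloc[0]
            raise ValidationError(
                f"negative value {bad['value']} in stratum "
                f"({bad['region']}, {bad['age_group']}, {bad['sex']}, {bad['dwelling']})"
            )
        if df.duplicated(STRATUM_COLUMNS).any():
            dup = df.loc[df.duplicated(STRATUM_COLUMNS)].iloc[0]
            raise ValidationError(
                "duplicate stratum key "
                f"({dup['region']}, {dup['age_group']}, {dup['sex']}, {dup['dwelling']})"
            )
        self.data = df.reset_index(drop=True)

    @property
    def age_groups(self) -> tuple[str, ...]:
        return AGE_GROUPS_COLLAPSED if self.collapsed_ages else AGE_GROUPS

    def __len__(self) -> int:
        return len(self.data)

    def total(self) -> float:
        return float(self.data["value"].sum())

    def aggregate(self, by: str | Sequence[str]) -> pd.Series:
        """Sum values over all strata sharing the given margin column(s)."""
        cols = [by] if isinstance(by, str) else list(by)
        unknown = set(cols) - set(STRATUM_COLUMNS)
        if unknown:
            raise SchemaError(f"cannot aggregate by non-stratum column(s) {sorted(unknown)}")
        return self.data.groupby(cols, sort=True)["value"].sum()

    def align_like(self, other: "StratifiedTable") -> pd.DataFrame:
        """Inner-merge of this table's values onto another's strata.

        Raises :class:`ValidationError` if the stratum sets differ.
        """
        merged = other.data[STRATUM_COLUMNS].merge(
            self.data, on=STRATUM_COLUMNS, how="left", validate="one_to_one"
        )
        if merged["value"].isna().any() or len(merged) != len(self.data):
            raise ValidationError(
                f"strata of {self.quantity!r} table do not match {other.quantity!r} table"
            )
        return merged

    def to_csv(self, path) -> None:
        write_stratified_table(self, path)


def read_stratified_table(
    path,
    quantity: str = "value",
    units: str = "",
    endpoint: str | None = None,
) -> StratifiedTable:
    """Read a stratified CSV (region, age_group, sex, dwelling, value).

    If the file carries an ``endpoint`` column (cases tables), ``endpoint``
    selects which one to load.
    """
    df = pd.read_csv(path, dtype={c: str for c in STRATUM_COLUMNS})
    if endpoint is not None:
        if "endpoint" not in df.columns:
            raise SchemaError("requested an endpoint but file has no 'endpoint' column")
        if endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {endpoint!r}; allowed: {ENDPOINTS}")
        df = df.loc[df["endpoint"] == endpoint].drop(columns="endpoint")
    elif "endpoint" in df.columns:
        raise SchemaError(
            "file has an 'endpoint' column; pass endpoint='all_lung' or 'small_cell'"
        )
    collapsed = "0-44" in set(df.get("age_group", pd.Series(dtype=str)))
    return StratifiedTable(df, quantity=quantity, units=units, collapsed_ages=collapsed)


def write_stratified_table(table: StratifiedTable, path) -> None:
    table.data.to_csv(path, index=False)


def full_cross(
    regions: Sequence[str],
    values_fn: Callable[[str, str, str, str], float] | float = 0.0,
    quantity: str = "value",
    units: str = "",
    collapsed_ages: bool = False,
) -> StratifiedTable:
    """Build the complete R x ages x 2 x 2 stratum table.

    ``values_fn`` is either a constant or a callable
    ``f(region, age_group, sex, dwelling) -> value``.
    """
    ages = AGE_GROUPS_COLLAPSED if collapsed_ages else AGE_GROUPS
    idx = pd.MultiIndex.from_product(
        [list(regions), list(ages), list(SEXES), list(DWELLINGS)],
        names=STRATUM_COLUMNS,
    )
    df = idx.to_frame(index=False)
    if callable(values_fn):
        df["value"] = [
            values_fn(r, a, s, d)
            for r, a, s, d in zip(df.region, df.age_group, df.sex, df.dwelling)
        ]
    else:
        df["value"] = float(values_fn)
    return StratifiedTable(
        df, quantity=quantity, units=units,
        regions=tuple(regions), collapsed_ages=collapsed_ages,
    )


@dataclass(frozen=True)
class SmokingRelativeRisks:
    """Lung-cancer relative risks by smoking status, never smokers = 1.

    Defaults are the literature values used for case allocation: 15 for
    current and 4 for former smokers.
    """

    current: float = 15.0
    former: float = 4.0
    never: float = 1.0

    def __post_init__(self) -> None:
        if not (self.current >= self.former >= self.never == 1.0):
            raise ValidationError(
                "smoking RRs must satisfy current >= former >= never = 1"
            )

    def as_series(self) -> pd.Series:
        return pd.Series(
            {"current": self.current, "former": self.former, "never": self.never}
        )


@dataclass(frozen=True)
class ERRSpec:
    """Excess relative risk per 100 Bq m-3, on the percent scale.

    ``err_per_100bq=8.4`` means RR rises by 8.4% for every 100 Bq m-3 of
    radon. An optional normal uncertainty (mean, sd on the same scale)
    feeds the Monte Carlo engine.
    """

    err_per_100bq: float
    sd: float | None = None
    endpoint: str = "all_lung"

    def __post_init__(self) -> None:
        if not np.isfinite(self.err_per_100bq):
            raise ValidationError("ERR point estimate must be finite")
        if self.sd is not None and not self.sd > 0:
            raise ValidationError("ERR sd must be positive when given")
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")

    @property
    def beta(self) -> float:
        """ERR per 100 Bq m-3 as a fraction (8.4 -> 0.084)."""
        return self.err_per_100bq / 100.0


# Literature risk coefficients (percent per 100 Bq m-3) from the European
# pooled residential study: uncorrected, measurement-error corrected, and
# the small-cell carcinoma estimate.
ERR_UNCORRECTED = ERRSpec(8.4)
ERR_CORRECTED = ERRSpec(16.0)
ERR_SMALL_CELL = ERRSpec(31.0, endpoint="small_cell")


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of one attribution scenario.

    ``counterfactual_floor`` is the universal reference concentration
    (Bq m-3) treated as unavoidable; ``action_level``, when set, caps the
    exposure distribution to simulate mitigation.
    """

    err_spec: ERRSpec = ERR_CORRECTED
    counterfactual_floor: float = 25.0
    action_level: float | None = None
    exposure_set: str = "average"
    smoking_lag_years: int = 10
    reference_year: int = 2017

    def __post_init__(self) -> None:
        if self.counterfactual_floor < 0:
            raise ValidationError("counterfactual floor must be >= 0")
        if self.action_level is not None and not (
            self.action_level > self.counterfactual_floor
        ):
            raise ValidationError("action level must exceed the counterfactual floor")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["err_spec"] = dataclasses.asdict(self.err_spec)
        return d


def validate_prevalence_frame(df: pd.DataFrame, tol: float = 1e-9) -> None:
    """Check current/former/never columns form per-row distributions."""
    for col in SMOKING_CATEGORIES:
        if col not in df.columns:
            raise SchemaError(f"smoking table missing column {col!r}")
        vals = df[col].to_numpy(float)
        if ((vals < -tol) | (vals > 1 + tol)).any():
            raise ValidationError(f"prevalence column {col!r} outside [0, 1]")
    sums = df[list(SMOKING_CATEGORIES)].sum(axis=1).to_numpy(float)
    if np.abs(sums - 1.0).max() > tol:
        raise ValidationError(
            "smoking prevalences do not sum to 1 "
            f"(max deviation {np.abs(sums - 1.0).max():.3g})"
        )
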