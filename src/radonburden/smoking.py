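"""Lagged smoking prevalence by stratum, with imputation of uncovered strata.

Smoking exposure relevant to lung-cancer incidence in a reference year is
taken from the prevalence survey ten years earlier (a 10-year lag).
National surveys do not cover the oldest age band (85+), whose prevalences
are imputed by extrapolating per-sex, per-category linear age trends; nor
do they give dwelling-type-specific prevalence for seniors and
adolescents, which is carried over from donor age bands (55-64 for ages
65+, 45-54 for adolescents) as a flat/house *ratio* applied to the
recipient band's own overall level, so the overall prevalence of each
band is preserved.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AGE_GROUPS,
    AGE_MIDPOINTS,
    SEXES,
    SMOKING_CATEGORIES,
    SchemaError,
    ValidationError,
    validate_prevalence_frame,
)

SMOKING_COLUMNS = ["year", "age_group", "sex", "dwelling", "current", "former", "never"]

#: Default dwelling carry-over: donor age band -> recipient bands.
DEFAULT_CARRYOVER = {
    "55-64": ("65-74", "75-84", "85+"),
    "45-54": ("0-34", "35-44"),
}


class DataError(ValueError):
    """Requested data that the series does not contain."""


def _check_columns(series: pd.DataFrame, require_year: bool = True) -> None:
    needed = SMOKING_COLUMNS if require_year else SMOKING_COLUMNS[1:]
    missing = [c for c in needed if c not in series.columns]
    if missing:
        raise SchemaError(f"smoking table missing column(s): {missing}")


def lag_prevalence(
    series: pd.DataFrame, reference_year: int, lag: int = 10
) -> pd.DataFrame:
    """Prevalence table for the year ``reference_year - lag``.

    With the default 10-year lag and reference year 2017 this returns the
    2007 table — prevalence a decade earlier is taken to represent smoking
    exposure during the aetiologically relevant window.
    """
    _check_columns(series)
    year = reference_year - lag
    out = series.loc[series["year"] == year]
    if out.empty:
        raise DataError(
            f"no smoking prevalence for year {year}; "
            f"available years: {sorted(series['year'].unique())}"
        )
    return out.reset_index(drop=True)


def _linear_extrapolate(ages: np.ndarray, values: np.ndarray, target: float) -> float:
    slope, intercept = np.polyfit(ages, values, 1)
    return float(slope * target + intercept)


def impute_oldest_age(
    series: pd.DataFrame,
    target_group: str = "85+",
    fit_fn=None,
) -> pd.DataFrame:
    """Fill the oldest age band by extrapolating per-sex age trends.

    For each sex and smoking category a trend of prevalence against
    age-band midpoint is fitted (dwellings pooled by simple averaging; six
    fits in total for the three categories by two sexes) and evaluated at
    the 85+ midpoint. Extrapolations are clamped to [0, 1] and the three
    categories renormalised to sum to one. The imputed values are emitted
    for both dwelling types; use :func:`fill_dwelling_specific` to restore
    a dwelling split.

    ``fit_fn(ages, values, target_age) -> float`` replaces the default
    linear fit if supplied.
    """
    _check_columns(series)
    fit = fit_fn or _linear_extrapolate
    if (series["age_group"] == target_group).any():
        raise ValidationError(f"series already contains age group {target_group!r}")
    target_mid = AGE_MIDPOINTS[target_group]
    new_rows = []
    for (year, sex), grp in series.groupby(["year", "sex"], sort=True):
        pooled = grp.groupby("age_group", sort=False)[list(SMOKING_CATEGORIES)].mean()
        pooled = pooled.loc[[a for a in AGE_GROUPS if a in pooled.index]]
        if len(pooled) < 3:
            raise ValidationError(
                f"need >= 3 age groups to impute {target_group!r} for "
                f"(year={year}, sex={sex}); found {len(pooled)}"
            )
        ages = np.array([AGE_MIDPOINTS[a] for a in pooled.index])
        est = {
            cat: min(1.0, max(0.0, fit(ages, pooled[cat].to_numpy(float), target_mid)))
            for cat in SMOKING_CATEGORIES
        }
        total = sum(est.values())
        if total <= 0:
            raise ValidationError(
                f"imputation degenerate for (year={year}, sex={sex}): all categories 0"
            )
        est = {cat: v / total for cat, v in est.items()}
        for dwelling in sorted(grp["dwelling"].unique()):
            new_rows.append(
                {"year": year, "age_group": target_group, "sex": sex,
                 "dwelling": dwelling, **est}
            )
    out = pd.concat([series, pd.DataFrame(new_rows)], ignore_index=True)
    return out.sort_values(["year", "sex", "dwelling", "age_group"]).reset_index(
        drop=True
    )


def _flat_share(flat_share, age_group: str, sex: str) -> float:
    if isinstance(flat_share, Mapping):
        try:
            w = float(flat_share[(age_group, sex)])
        except KeyError as exc:
            raise DataError(
                f"no flat-share for (age_group={age_group}, sex={sex})"
            ) from exc
    else:
        w = float(flat_share)
    if not 0.0 <= w <= 1.0:
        raise ValidationError(f"flat share {w} outside [0, 1]")
    return w


def flat_shares_from_population(population) -> dict[tuple[str, str], float]:
    """Flat population shares per (age_group, sex) from a population table."""
    counts = population.aggregate(["age_group", "sex", "dwelling"]).unstack("dwelling")
    shares = counts["flat"] / counts.sum(axis=1)
    return {idx: float(v) for idx, v in shares.items()}


def fill_dwelling_specific(
    series: pd.DataFrame,
    flat_share: float | Mapping[tuple[str, str], float] = 0.5,
    carryover: Mapping[str, Sequence[str]] = DEFAULT_CARRYOVER,
) -> pd.DataFrame:
    """Carry donor age bands' dwelling contrast onto recipient bands.

    For each recipient band the donor's flat/house prevalence ratio (per
    sex and category) is applied to the recipient's own overall level,
    weighting by the recipient's flat population share so that the overall
    prevalence is preserved exactly: solving p_flat = r * p_house and
    w * p_flat + (1 - w) * p_house = overall. The transfer is applied to
    the current and former categories; never smokers take the complement,
    which preserves that category's overall as well.
    """
    _check_columns(series)
    out = series.copy()
    for (year, sex), grp in series.groupby(["year", "sex"], sort=True):
        by_age = {a: g.set_index("dwelling") for a, g in grp.groupby("age_group")}
        for donor, recipients in carryover.items():
            if donor not in by_age:
                raise DataError(
                    f"donor age group {donor!r} absent for (year={year}, sex={sex})"
                )
            d = by_age[donor]
            if not {"flat", "house"} <= set(d.index):
                raise DataError(
                    f"donor {donor!r} lacks dwelling-specific rows for "
                    f"(year={year}, sex={sex})"
                )
            for rec in recipients:
                if rec not in by_age:
                    continue  # band absent entirely; nothing to split
                r_grp = by_age[rec]
                w = _flat_share(flat_share, rec, sex)
                mask = (
                    (out["year"] == year) & (out["sex"] == sex)
                    & (out["age_group"] == rec)
                )
                new = {}
                for cat in ("current", "former"):
                    ratio = d.loc["flat", cat] / d.loc["house", cat]
                    overall = (
                        w * r_grp.loc["flat", cat] + (1 - w) * r_grp.loc["house", cat]
                    )
                    p_house = overall / (w * ratio + (1 - w))
                    new[cat] = {"flat": ratio * p_house, "house": p_house}
                for dwelling in ("flat", "house"):
                    never = 1.0 - new["current"][dwelling] - new["former"][dwelling]
                    if never < -1e-12:
                        raise ValidationError(
                            f"dwelling carry-over for {rec!r} "
                            f"(year={year}, sex={sex}) yields never < 0"
                        )
                    sel = mask & (out["dwelling"] == dwelling)
                    out.loc[sel, "current"] = new["current"][dwelling]
                    out.loc[sel, "former"] = new["former"][dwelling]
                    out.loc[sel, "never"] = max(never, 0.0)
    return out


def assemble_prevalence(
    series: pd.DataFrame,
    reference_year: int,
    lag: int = 10,
    flat_share: float | Mapping[tuple[str, str], float] = 0.5,
    carryover: Mapping[str, Sequence[str]] = DEFAULT_CARRYOVER,
    impute_missing_oldest: bool = True,
) -> pd.DataFrame:
    """Lag, impute and dwelling-fill: the full prevalence pipeline.

    Returns a validated table with every age band present for the lagged
    year, columns age_group, sex, dwelling, current, former, never.
    """
    table = lag_prevalence(series, reference_year, lag)
    if impute_missing_oldest and not (table["age_group"] == "85+").any():
        table = impute_oldest_age(table)
    carry = {
        d: tuple(r for r in rs if (table["age_group"] == r).any())
        for d, rs in carryover.items()
    }
    # only re-split bands the surveys leave without a dwelling contrast
    carry = {
        d: tuple(
            r for r in rs
            if _band_needs_split(table, r)
        )
        for d, rs in carry.items()
    }
    carry = {d: rs for d, rs in carry.items() if rs}
    if carry:
        table = fill_dwelling_specific(table, flat_share=flat_share, carryover=carry)
    out = table.drop(columns="year").reset_index(drop=True)
    validate_prevalence_frame(out)
    return out


def _band_needs_split(table: pd.DataFrame, age_group: str) -> bool:
    sel = table.loc[table["age_group"] == age_group]
    if sel.empty:
        return False
    pivot = sel.pivot_table(
        index=["year", "sex"], columns="dwelling", values="current"
    )
    if "flat" not in pivot.columns or "house" not in pivot.columns:
        return True
    return bool(np.allclose(pivot["flat"], pivot["house"]))
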