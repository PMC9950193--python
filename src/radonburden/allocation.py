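"""Allocation of registered lung-cancer cases to smoking categories.

Cancer registries do not record smoking, so each stratum's case count L_s
is split over current, former and never smokers in proportion to
relative-risk-weighted prevalence: with prevalence p_i and lung-cancer
relative risk RR_i (vs never smokers), the weight is P_i = p_i * RR_i and

    L_i = P_i * L_s / sum_j P_j.

Allocation is performed independently within every (region, age, sex,
dwelling) stratum before any aggregation, so the split reflects that
stratum's own smoking prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    SMOKING_CATEGORIES,
    SmokingRelativeRisks,
    StratifiedTable,
    ValidationError,
)


class AllocationError(ValueError):
    """Weights degenerate (all zero) — no allocation possible."""


@dataclass(frozen=True)
class AllocationWeights:
    """Relative-risk-weighted smoking prevalences for one stratum."""

    prevalence: tuple[float, float, float]  # (current, former, never), sums to 1
    rr: SmokingRelativeRisks = SmokingRelativeRisks()

    def __post_init__(self) -> None:
        p = np.asarray(self.prevalence, dtype=float)
        if p.shape != (3,):
            raise ValidationError("prevalence must be (current, former, never)")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("prevalences must be nonnegative and sum to 1")

    @property
    def weights(self) -> np.ndarray:
        p = np.asarray(self.prevalence, dtype=float)
        rr = np.array([self.rr.current, self.rr.former, self.rr.never])
        return p * rr


def allocate_cases(L_s: float, weights: AllocationWeights) -> pd.Series:
    """Split a stratum's case count over smoking categories.

    Returns real-valued counts indexed current/former/never that sum to
    ``L_s`` exactly.
    """
    if L_s < 0:
        raise ValidationError("case count must be nonnegative")
    w = weights.weights
    total = w.sum()
    if total <= 0:
        raise AllocationError("all allocation weights are zero")
    return pd.Series(L_s * w / total, index=list(SMOKING_CATEGORIES))


def allocation_shares(prevalence: pd.DataFrame, rr: SmokingRelativeRisks) -> pd.DataFrame:
    """Vectorised per-row allocation shares from a prevalence frame.

    ``prevalence`` carries current/former/never columns; the returned frame
    has the same index with shares summing to 1 per row.
    """
    w = prevalence[list(SMOKING_CATEGORIES)].to_numpy(float) * rr.as_series().to_numpy()
    totals = w.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise AllocationError("a stratum has all-zero allocation weights")
    return pd.DataFrame(
        w / totals, index=prevalence.index, columns=list(SMOKING_CATEGORIES)
    )


def allocate_table(
    cases: StratifiedTable,
    prevalence: pd.DataFrame,
    rr: SmokingRelativeRisks = SmokingRelativeRisks(),
) -> pd.DataFrame:
    """Per-stratum allocation of a full cases table.

    ``prevalence`` holds age_group, sex, dwelling, current, former, never
    (prevalence varies by age, sex and dwelling; it is broadcast over
    regions). Returns the stratum frame with added columns current/former/
    never carrying allocated case counts, conserving each stratum's total.
    """
    keys = ["age_group", "sex", "dwelling"]
    merged = cases.data.merge(
        prevalence[keys + list(SMOKING_CATEGORIES)],
        on=keys, how="left", validate="many_to_one",
    )
    if merged[list(SMOKING_CATEGORIES)].isna().any().any():
        bad = merged.loc[merged["current"].isna(), keys].iloc[0]
        raise ValidationError(
            f"no smoking prevalence for stratum ({bad['age_group']}, "
            f"{bad['sex']}, {bad['dwelling']})"
        )
    shares = allocation_shares(merged, rr)
    out = merged[["region", "age_group", "sex", "dwelling", "value"]].copy()
    for cat in SMOKING_CATEGORIES:
        out[cat] = out["value"] * shares[cat]
    return out


def smoking_specific_incidence(
    cases_by_category: pd.Series, population_by_category: pd.Series
) -> pd.Series:
    """Incidence per 100,000 persons by smoking category."""
    cases = cases_by_category.astype(float)
    pop = population_by_category.astype(float).reindex(cases.index)
    if pop.isna().any():
        raise ValidationError("population missing for some smoking categories")
    zero_pop = (pop <= 0) & (cases > 0)
    if zero_pop.any():
        raise ValidationError(
            f"zero population with nonzero cases for {list(cases.index[zero_pop])}"
        )
    rates = np.where(pop > 0, 1e5 * cases / pop.where(pop > 0, 1.0), 0.0)
    return pd.Series(rates, index=cases.index)
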