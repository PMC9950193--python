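"""Rendering of report tables: counts with percentages, rounded outputs.

Internal quantities are real-valued; only here are they rounded, using
round-half-away-from-zero, so sums of rounded entries need not equal the
rounded total (footnoted on every table). Rendering is pure: the same
result always yields byte-identical text.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .allocation import allocate_table, smoking_specific_incidence
from .attribution import AttributionResult
from .data_model import (
    SMOKING_CATEGORIES,
    SmokingRelativeRisks,
    StratifiedTable,
)
from .uncertainty import UncertaintyResult

logger = logging.getLogger("radonburden")

ROUNDING_FOOTNOTE = (
    "Due to rounding, sums in each category do not necessarily add to "
    "total and percentages to 100."
)


def round_half_away(x):
    """Round half away from zero (0.5 -> 1, -0.5 -> -1)."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return int(out) if out.ndim == 0 else out.astype(int)


def _n_pct(n: float, total: float) -> str:
    pct = 0 if total == 0 else round_half_away(100.0 * n / total)
    return f"{round_half_away(n)} ({pct})"


def render_table1(
    population: StratifiedTable,
    cases: StratifiedTable,
    prevalence: pd.DataFrame,
    smoking_rr: SmokingRelativeRisks = SmokingRelativeRisks(),
    small_cell: StratifiedTable | None = None,
) -> dict[str, pd.DataFrame]:
    """Population/case counts by demographic group, with derived incidence.

    Returns ``counts`` (n (%) by age, sex and smoking, per dwelling and
    quantity) and ``incidence`` (cases per 100,000 by sex, dwelling and
    smoking category). Strata with zero population but nonzero cases are
    suppressed from the incidence block with a logged warning.
    """
    sources: dict[str, StratifiedTable] = {"population": population, "cases": cases}
    if small_cell is not None:
        sources["small_cell"] = small_cell
    blocks = []
    for name, tab in sources.items():
        by_dw = tab.aggregate("dwelling")
        for margin in ("age_group", "sex"):
            agg = tab.aggregate([margin, "dwelling"]).unstack("dwelling")
            cells = {
                dw: agg[dw].map(lambda v, t=by_dw[dw]: _n_pct(v, t))
                for dw in agg.columns
            }
            block = pd.DataFrame(cells)
            block.index = pd.MultiIndex.from_product([[margin], block.index])
            block.columns = pd.MultiIndex.from_product([[name], block.columns])
            blocks.append(block)

    alloc_pop = allocate_smoking_margin(population, prevalence, smoking_rr,
                                        weight_by="population")
    alloc_cases = allocate_table(cases, prevalence, smoking_rr)
    smoking_blocks = {}
    for name, alloc in (("population", alloc_pop), ("cases", alloc_cases)):
        agg = alloc.groupby("dwelling")[list(SMOKING_CATEGORIES)].sum().T
        tot = agg.sum(axis=0)
        block = agg.apply(lambda col: col.map(lambda v: _n_pct(v, tot[col.name])))
        block.index = pd.MultiIndex.from_product([["smoking"], block.index])
        block.columns = pd.MultiIndex.from_product([[name], block.columns])
        smoking_blocks[name] = block
    counts = pd.concat(
        [pd.concat([b for b in blocks], axis=0)]
        + list(smoking_blocks.values()),
        axis=0,
    ).groupby(level=[0, 1], sort=False).first()

    # incidence per 100,000
    pop_by = {m: population.aggregate(m) for m in ("sex", "dwelling")}
    cases_by = {m: cases.aggregate(m) for m in ("sex", "dwelling")}
    rows = {}
    for margin in ("sex", "dwelling"):
        for level in pop_by[margin].index:
            p, c = pop_by[margin][level], cases_by[margin][level]
            if p <= 0:
                logger.warning(
                    "suppressing incidence for %s=%s: zero population", margin, level
                )
                continue
            rows[(margin, level)] = 1e5 * c / p
    smoking_rates = smoking_specific_incidence(
        alloc_cases[list(SMOKING_CATEGORIES)].sum(),
        alloc_pop[list(SMOKING_CATEGORIES)].sum(),
    )
    for cat, rate in smoking_rates.items():
        rows[("smoking", cat)] = rate
    incidence = pd.Series(rows, name="per_100000").to_frame()
    incidence["rounded"] = round_half_away(incidence["per_100000"])
    return {"counts": counts, "incidence": incidence}


def allocate_smoking_margin(
    population: StratifiedTable,
    prevalence: pd.DataFrame,
    smoking_rr: SmokingRelativeRisks,
    weight_by: str = "population",
) -> pd.DataFrame:
    """Population split over smoking categories (by prevalence alone)."""
    keys = ["age_group", "sex", "dwelling"]
    merged = population.data.merge(
        prevalence[keys + list(SMOKING_CATEGORIES)], on=keys,
        how="left", validate="many_to_one",
    )
    out = merged[["region", "age_group", "sex", "dwelling", "value"]].copy()
    for cat in SMOKING_CATEGORIES:
        out[cat] = merged["value"] * merged[cat]
    return out


def render_attribution(result: AttributionResult) -> str:
    """Table-2-shaped text report: avoidable burden by demographic group."""
    dw = result.margin("dwelling")
    tot = result.totals()
    err = result.scenario.err_spec

    def row(label, values, totals):
        cells = [
            _n_pct(values[d], totals[d]) for d in ("flat", "house")
        ] + [_n_pct(sum(values[d] for d in ("flat", "house")),
                    sum(totals[d] for d in ("flat", "house")))]
        return f"{label:<28}" + "".join(f"{c:>16}" for c in cells)

    case_by_dw = dw["cases"]
    lines = [
        f"Avoidable radon-attributable burden (ERR = {err.err_per_100bq:g}%, "
        f"exposure set: {result.scenario.exposure_set}, floor = "
        f"{result.scenario.counterfactual_floor:g} Bq m-3)",
        f"{'':<28}{'Flats':>16}{'Houses':>16}{'Total':>16}",
        f"{'Overall cases':<28}"
        + "".join(f"{round_half_away(v):>16}" for v in
                  [case_by_dw['flat'], case_by_dw['house'], tot['cases']]),
        row("Radon-attributable", dw["attributable"], case_by_dw),
        row("Attributable at floor", dw["counterfactual"], case_by_dw),
        row("Avoidable", dw["avoidable"], case_by_dw),
    ]
    for margin in ("age_group", "sex"):
        m = result.margin([margin, "dwelling"])
        avoid = m["avoidable"].unstack("dwelling")
        avoid_dw = dw["avoidable"]
        lines.append(f" {margin.replace('_', ' ').capitalize()}")
        for level in avoid.index:
            lines.append(row(f"  {level}", avoid.loc[level], avoid_dw))
    try:
        smk = result.strata.groupby("dwelling")[
            [f"avoidable_{c}" for c in SMOKING_CATEGORIES]
        ].sum()
        lines.append(" Smoking")
        for cat in SMOKING_CATEGORIES:
            vals = smk[f"avoidable_{cat}"]
            lines.append(row(f"  {cat}", vals, dw["avoidable"]))
    except KeyError:
        pass
    lines += [
        f"PAF (avoidable / total cases): {tot['paf_avoidable']:.2f}",
        ROUNDING_FOOTNOTE,
    ]
    return "\n".join(lines)


def render_uncertainty(result: UncertaintyResult) -> str:
    """Table-4-shaped text report: mean (95% uncertainty interval)."""
    spec = result.spec
    lines = [
        f"Simulation {spec.sim_id} (ERR ~ N[{spec.err_mean:g}, {spec.err_sd:g}^2], "
        f"M = {spec.reps}, endpoint = {spec.endpoint}, seed = {spec.seed})",
        f"{'margin':<24}{'mean (95% UI)':>24}",
    ]
    for (margin, level), row in result.table.iterrows():
        cell = (
            f"{round_half_away(row['mean'])} "
            f"({round_half_away(row['lower'])}, {round_half_away(row['upper'])})"
        )
        lines.append(f"{margin + ': ' + level:<24}{cell:>24}")
    lines.append("Negative simulated estimates were truncated to zero.")
    return "\n".join(lines)


def render_results(result) -> str:
    """Dispatch on result type (attribution vs uncertainty)."""
    if isinstance(result, AttributionResult):
        return render_attribution(result)
    if isinstance(result, UncertaintyResult):
        return render_uncertainty(result)
    raise TypeError(f"cannot render {type(result).__name__}")
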