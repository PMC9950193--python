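"""Radon attribution engine: linear-ERR risk model, avoidable burden, PAF,
mitigation and the radon/smoking joint-effect decomposition.

The risk model is the linear excess-relative-risk form from pooled
residential case-control studies,

    RR(X) = 1 + beta * X / 100,

with beta the percent excess relative risk per 100 Bq m-3 (8.4% uncorrected,
16% corrected for measurement error, 31% for small cell carcinoma) and X the
radon activity concentration in Bq m-3. Within a stratum with L registered
cases at concentration X, the cases attributable to radon are

    L - L / RR(X) = L * AF(X),    AF(X) = (beta X/100) / (1 + beta X/100),

i.e. the total is deflated by the relative risk to get the non-attributable
baseline. Because outdoor and residual indoor radon cannot be removed, the
*avoidable* burden is measured against a universal counterfactual floor
(25 Bq m-3 by default, roughly the lowest decile of residential levels):

    avoidable = L * (AF(X) - AF(floor)).

All quantities are real-valued and strictly additive over strata; rounding
happens only at report rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .allocation import allocation_shares
from .data_model import (
    SMOKING_CATEGORIES,
    ERRSpec,
    ScenarioConfig,
    SmokingRelativeRisks,
    StratifiedTable,
    ValidationError,
)
from .exposure import ExposureSet, build_exposure_sets

__all__ = [
    "relative_risk",
    "attributable_fraction",
    "attributable_cases",
    "avoidable_cases",
    "paf",
    "capped_gm",
    "mitigate",
    "derive_group_err",
    "joint_effect",
    "run_scenario",
    "AttributionResult",
    "JointEffectResult",
]


def _beta(err: ERRSpec | float) -> float:
    return err.beta if isinstance(err, ERRSpec) else float(err) / 100.0


def relative_risk(x, err: ERRSpec | float):
    """RR(X) = 1 + beta * X/100 for concentration ``x`` in Bq m-3.

    ``err`` is an :class:`ERRSpec` or a bare percent-per-100-Bq value. For
    nonnegative ERR the result is >= 1. A pathologically negative ERR can
    drive RR <= 0; callers doing Monte Carlo handle that via truncation of
    the resulting negative avoidable counts.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValidationError("radon concentration must be nonnegative")
    out = 1.0 + _beta(err) * x / 100.0
    return float(out) if out.ndim == 0 else out


def attributable_fraction(x, err: ERRSpec | float):
    """AF(X) = 1 - 1/RR(X) = beta x' / (1 + beta x'), x' = X/100."""
    rr = np.asarray(relative_risk(x, err), dtype=float)
    denom = np.where(np.abs(rr) < 1e-12, 1e-12, rr)
    out = 1.0 - 1.0 / denom
    return float(out) if out.ndim == 0 else out


def attributable_cases(L, x, err: ERRSpec | float):
    """Cases attributable to radon at concentration ``x``: L - L/RR(x)."""
    L = np.asarray(L, dtype=float)
    if (L < 0).any():
        raise ValidationError("case counts must be nonnegative")
    out = L * attributable_fraction(x, err)
    return float(out) if out.ndim == 0 else out


def avoidable_cases(L, x_observed, floor: float, err: ERRSpec | float):
    """Attributable cases in excess of the counterfactual floor.

    May be negative when observed concentrations lie below the floor; the
    sign is preserved here, truncation being a reporting/uncertainty
    policy, not part of the identity avoidable = attributable -
    counterfactual.
    """
    if floor < 0:
        raise ValidationError("counterfactual floor must be >= 0")
    out = np.asarray(attributable_cases(L, x_observed, err)) - np.asarray(
        attributable_cases(L, floor, err)
    )
    return float(out) if out.ndim == 0 else out


def paf(attributable: float, total: float) -> float:
    """Population attributable fraction: attributable / total cases."""
    if total <= 0:
        raise ValidationError("total case count must be positive")
    return float(attributable) / float(total)


def capped_gm(gm: float, gsd: float, cap: float) -> float:
    """GM of a lognormal(GM, GSD) after capping values at ``cap``.

    With log X ~ N(m, s2), m = log GM, s = log GSD and a = log cap,
    E[min(log X, a)] = m Phi(z) - s phi(z) + a (1 - Phi(z)) with
    z = (a - m)/s; the capped GM is its exponential. Used to translate a
    mitigation action level into stratum GMs when only GM/GSD summaries
    (not raw measurements) are available.
    """
    if gm <= 0 or cap <= 0:
        raise ValidationError("gm and cap must be positive")
    if gsd < 1:
        raise ValidationError("geometric SD must be >= 1")
    if gsd == 1.0:
        return min(gm, cap)
    m, s, a = np.log(gm), np.log(gsd), np.log(cap)
    z = (a - m) / s
    mean_log = m * norm.cdf(z) - s * norm.pdf(z) + a * (1.0 - norm.cdf(z))
    return float(np.exp(mean_log))


def mitigate(
    source: pd.DataFrame | ExposureSet,
    action_level: float,
    gsd: float | Mapping[str, float] | None = None,
) -> ExposureSet:
    """Exposure sets after mitigating concentrations above an action level.

    With raw measurements (columns region, dwelling, survey_id,
    concentration) every measurement above ``action_level`` is capped at it
    and per-cell GMs are recomputed — capping changes the whole upper tail,
    not just the mean. With GM-only input a lognormal model with the given
    ``gsd`` (scalar or per-dwelling mapping) reconstructs the capped GM
    analytically; omitting ``gsd`` in that case is a configuration error.
    """
    if action_level <= 0:
        raise ValidationError("action level must be positive")
    if isinstance(source, pd.DataFrame) and "concentration" in source.columns:
        capped = source.copy()
        capped["concentration"] = capped["concentration"].clip(upper=action_level)
        return build_exposure_sets(capped)
    exposure = source if isinstance(source, ExposureSet) else ExposureSet(source)
    if gsd is None:
        raise ValidationError(
            "mitigation of GM-only exposure needs a distributional model: "
            "supply raw measurements or a lognormal gsd (scalar or per dwelling)"
        )
    gms = exposure.data.loc[exposure.data["survey_id"] != "average"].copy()
    gsd_of = (lambda d: gsd[d]) if isinstance(gsd, Mapping) else (lambda d: gsd)
    gms["gm_concentration"] = [
        capped_gm(g, gsd_of(d), action_level)
        for g, d in zip(gms["gm_concentration"], gms["dwelling"])
    ]
    return build_exposure_sets(gms)


def derive_group_err(
    err_avg: float, miner_ratio: float, weight_smokers: float
) -> tuple[float, float]:
    """Split an average ERR into smoker and non-smoker ERRs.

    Solves e_s = ratio * e_n and w * e_s + (1 - w) * e_n = err_avg, where
    ``miner_ratio`` is the smoker-to-non-smoker ERR ratio taken from pooled
    miner studies and ``weight_smokers`` the smokers' weight in the
    average. Returns (err_smokers, err_nonsmokers) on the percent scale.
    """
    if miner_ratio <= 0:
        raise ValidationError("ERR ratio must be positive")
    if not 0.0 <= weight_smokers <= 1.0:
        raise ValidationError("weight must lie in [0, 1]")
    denom = weight_smokers * miner_ratio + (1.0 - weight_smokers)
    e_n = err_avg / denom
    e_s = miner_ratio * e_n
    if err_avg > 0 and (e_n <= 0 or e_s <= 0):
        raise ValidationError("infeasible group ERR split (nonpositive solution)")
    return e_s, e_n


@dataclass
class AttributionResult:
    """Per-stratum attribution with margins, totals and a summary table.

    ``strata`` carries, per (region, age_group, sex, dwelling): cases, the
    GM concentration used, attributable, counterfactual (attributable at
    the floor) and avoidable counts, plus per-smoking-category case and
    avoidable columns when a smoking prevalence table was supplied.
    """

    strata: pd.DataFrame
    scenario: ScenarioConfig
    smoking_rr: SmokingRelativeRisks = field(default_factory=SmokingRelativeRisks)

    _COUNT_COLS = ("cases", "attributable", "counterfactual", "avoidable")

    def totals(self) -> pd.Series:
        t = self.strata[list(self._COUNT_COLS)].sum()
        t["paf_avoidable"] = paf(t["avoidable"], t["cases"])
        t["paf_attributable"] = paf(t["attributable"], t["cases"])
        return t

    def margin(self, by: str | Sequence[str]) -> pd.DataFrame:
        """Sums of the count columns over a stratum margin, with PAFs."""
        cols = [by] if isinstance(by, str) else list(by)
        out = self.strata.groupby(cols, sort=True)[list(self._COUNT_COLS)].sum()
        out["paf_avoidable"] = out["avoidable"] / out["cases"]
        return out

    def smoking_margin(self) -> pd.DataFrame:
        """Avoidable and case counts by smoking category (if allocated)."""
        cats = [c for c in SMOKING_CATEGORIES if f"avoidable_{c}" in self.strata]
        if not cats:
            raise ValidationError(
                "no smoking allocation in this result (no prevalence table supplied)"
            )
        rows = {
            cat: {
                "cases": self.strata[f"cases_{cat}"].sum(),
                "avoidable": self.strata[f"avoidable_{cat}"].sum(),
            }
            for cat in cats
        }
        return pd.DataFrame(rows).T.rename_axis("smoking")

    def summary(self) -> str:
        err = self.scenario.err_spec
        t = self.totals()
        lines = [
            "Radon-attributable lung cancer burden",
            "=" * 53,
            f"Endpoint:            {err.endpoint}",
            f"ERR per 100 Bq m-3:  {err.err_per_100bq:g}%",
            f"Exposure set:        {self.scenario.exposure_set}",
            f"Counterfactual:      {self.scenario.counterfactual_floor:g} Bq m-3",
            "-" * 53,
            f"Total cases:                {t['cases']:10.1f}",
            f"Radon-attributable:         {t['attributable']:10.1f}",
            f"Attributable at floor:      {t['counterfactual']:10.1f}",
            f"Avoidable (above floor):    {t['avoidable']:10.1f}",
            f"PAF (avoidable/total):      {t['paf_avoidable']:10.3f}",
            "-" * 53,
        ]
        dw = self.margin("dwelling")["avoidable"]
        for d, v in dw.items():
            lines.append(f"Avoidable, {d:<6}             {v:10.1f}")
        return "\n".join(lines)


def run_scenario(
    population: StratifiedTable,
    cases: StratifiedTable,
    exposure: ExposureSet,
    smoking_prevalence: pd.DataFrame | None,
    scenario: ScenarioConfig,
    smoking_rr: SmokingRelativeRisks = SmokingRelativeRisks(),
    group_err: tuple[ERRSpec | float, ERRSpec | float] | None = None,
    gm_override: pd.Series | None = None,
) -> AttributionResult:
    """Full attribution scenario over every stratum.

    Attribution uses each (region, dwelling) cell's GM from the scenario's
    exposure set (``gm_override``, a Series indexed by (region, dwelling),
    substitutes e.g. a bimodally sampled draw). When a smoking prevalence
    frame is given, cases are allocated to smoking categories within each
    stratum before attribution, yielding per-category case and avoidable
    columns; ``group_err`` = (err for current+former smokers, err for never
    smokers) switches on the smoker-specific-ERR analysis, in which the two
    groups carry different risk coefficients.
    """
    pop = population.align_like(cases)
    df = cases.data.rename(columns={"value": "cases"}).copy()
    df["population"] = pop["value"].to_numpy()
    gm = gm_override if gm_override is not None else exposure.lookup(scenario.exposure_set)
    df = df.join(gm.rename("gm"), on=["region", "dwelling"])
    if df["gm"].isna().any():
        bad = df.loc[df["gm"].isna()].iloc[0]
        raise ValidationError(
            f"no exposure GM for cell (region={bad['region']}, dwelling={bad['dwelling']})"
        )

    err = scenario.err_spec
    floor = scenario.counterfactual_floor
    shares = None
    if smoking_prevalence is not None:
        keys = ["age_group", "sex", "dwelling"]
        prev = df[keys].merge(
            smoking_prevalence[keys + list(SMOKING_CATEGORIES)],
            on=keys, how="left", validate="many_to_one",
        )
        if prev[list(SMOKING_CATEGORIES)].isna().any().any():
            bad = prev.loc[prev["current"].isna(), keys].iloc[0]
            raise ValidationError(
                f"no smoking prevalence for ({bad['age_group']}, {bad['sex']}, "
                f"{bad['dwelling']})"
            )
        shares = allocation_shares(prev, smoking_rr)
        for cat in SMOKING_CATEGORIES:
            df[f"cases_{cat}"] = df["cases"] * shares[cat].to_numpy()

    if group_err is not None:
        if shares is None:
            raise ValidationError("group-specific ERR analysis requires a prevalence table")
        err_s, err_n = group_err
        # current + former smokers form a single group with their own ERR
        groups = {"current": err_s, "former": err_s, "never": err_n}
        df["attributable"] = 0.0
        df["counterfactual"] = 0.0
        for cat, e in groups.items():
            att = attributable_cases(df[f"cases_{cat}"], df["gm"], e)
            cf = attributable_cases(df[f"cases_{cat}"], floor, e)
            df[f"attributable_{cat}"] = att
            df[f"counterfactual_{cat}"] = cf
            df[f"avoidable_{cat}"] = att - cf
            df["attributable"] += att
            df["counterfactual"] += cf
        df["avoidable"] = df["attributable"] - df["counterfactual"]
    else:
        df["attributable"] = attributable_cases(df["cases"], df["gm"], err)
        df["counterfactual"] = attributable_cases(df["cases"], floor, err)
        df["avoidable"] = df["attributable"] - df["counterfactual"]
        if shares is not None:
            # the same AF applies within the stratum, so each category's
            # avoidable share equals its allocation share
            for cat in SMOKING_CATEGORIES:
                df[f"avoidable_{cat}"] = df["avoidable"] * shares[cat].to_numpy()

    return AttributionResult(strata=df, scenario=scenario, smoking_rr=smoking_rr)


@dataclass
class JointEffectResult:
    """Decomposition of avoidable burden into radon-alone and joint parts.

    For each smoking group the avoidable radon-attributable cases split as
    radon_alone + joint_with_smoking, where radon_alone is the burden the
    group would carry if its background (non-radon) incidence equalled the
    never smokers' — the remainder exists only because smoking multiplies
    the radon-induced excess and vanishes if either exposure is removed.
    """

    strata: pd.DataFrame
    scenario: ScenarioConfig

    def by_group(self) -> pd.DataFrame:
        rows = {}
        for cat in SMOKING_CATEGORIES:
            rows[cat] = {
                "avoidable_total": self.strata[f"avoidable_{cat}"].sum(),
                "radon_alone": self.strata[f"radon_alone_{cat}"].sum(),
                "joint_with_smoking": self.strata[f"joint_{cat}"].sum(),
            }
        return pd.DataFrame(rows).T.rename_axis("smoking")


def joint_effect(
    population: StratifiedTable,
    cases: StratifiedTable,
    exposure: ExposureSet,
    smoking_prevalence: pd.DataFrame,
    scenario: ScenarioConfig,
    smoking_rr: SmokingRelativeRisks = SmokingRelativeRisks(),
) -> JointEffectResult:
    """Split avoidable cases into radon-alone and radon-smoking joint parts.

    Per stratum and smoking group g with allocated cases L_g and population
    N_g = N * p_g: radon_alone_g applies the avoidable-case formula to
    N_g * I_never, the cases g would record at the never smokers' incidence
    I_never = L_never / N_never; joint_g is the remainder of g's avoidable
    total. For never smokers the joint part is identically zero.
    """
    res = run_scenario(
        population, cases, exposure, smoking_prevalence, scenario, smoking_rr
    )
    df = res.strata
    keys = ["age_group", "sex", "dwelling"]
    prev = df[keys].merge(
        smoking_prevalence[keys + list(SMOKING_CATEGORIES)],
        on=keys, how="left", validate="many_to_one",
    )
    n_never = df["population"] * prev["never"].to_numpy()
    if (n_never <= 0).any():
        bad = df.loc[(n_never <= 0).to_numpy()].iloc[0]
        raise ValidationError(
            f"zero never-smoker population in stratum ({bad['region']}, "
            f"{bad['age_group']}, {bad['sex']}, {bad['dwelling']})"
        )
    inc_never = df["cases_never"].to_numpy() / n_never.to_numpy()
    err = scenario.err_spec
    floor = scenario.counterfactual_floor
    for cat in SMOKING_CATEGORIES:
        n_g = df["population"].to_numpy() * prev[cat].to_numpy()
        baseline_cases = n_g * inc_never
        alone = avoidable_cases(baseline_cases, df["gm"].to_numpy(), floor, err)
        df[f"radon_alone_{cat}"] = alone
        df[f"joint_{cat}"] = df[f"avoidable_{cat}"] - alone
    return JointEffectResult(strata=df, scenario=scenario)
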