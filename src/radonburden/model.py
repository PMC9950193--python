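"""Model-object front end tying the pipeline stages together.

:class:`RadonBurdenModel` is constructed from the four input tables
(population, cases, radon exposure, smoking prevalence series); its
``fit`` runs an attribution scenario and returns the
:class:`~radonburden.attribution.AttributionResult` with per-stratum
estimates, margins and a ``summary()``; ``simulate`` runs the Monte Carlo
uncertainty engine. The underlying functional modules remain usable on
their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import attribution, smoking as smoking_mod, uncertainty as unc_mod
from .data_model import (
    ERRSpec,
    ScenarioConfig,
    SmokingRelativeRisks,
    StratifiedTable,
    ValidationError,
    read_stratified_table,
)
from .exposure import ExposureSet, build_exposure_sets


@dataclass
class RadonBurdenModel:
    """Stratified radon-attribution model for one reference year.

    Parameters
    ----------
    population, cases
        Stratified person and case counts on matching strata.
    exposure
        Per-(region, dwelling) survey GMs; the "average" set is derived if
        absent.
    smoking_series
        Annual prevalence tables (year, age_group, sex, dwelling,
        current, former, never); optional — without it no smoking margins
        are produced.
    measurements
        Raw radon measurements, enabling measurement-level mitigation.
    """

    population: StratifiedTable
    cases: StratifiedTable
    exposure: ExposureSet
    smoking_series: pd.DataFrame | None = None
    measurements: pd.DataFrame | None = None
    smoking_rr: SmokingRelativeRisks = field(default_factory=SmokingRelativeRisks)
    gsd: Mapping[str, float] | float | None = None

    def __post_init__(self) -> None:
        if "average" not in set(self.exposure.data["survey_id"]):
            self.exposure = build_exposure_sets(self.exposure)
        self._flat_share = smoking_mod.flat_shares_from_population(self.population)

    @classmethod
    def from_directory(cls, path, endpoint: str = "all_lung", **kwargs) -> "RadonBurdenModel":
        """Load population.csv, cases.csv, radon.csv and smoking.csv."""
        path = Path(path)
        population = read_stratified_table(
            path / "population.csv", "population", "persons"
        )
        cases = read_stratified_table(path / "cases.csv", "cases", "cases",
                                      endpoint=endpoint)
        exposure = ExposureSet.from_csv(path / "radon.csv")
        smoking_path = path / "smoking.csv"
        series = pd.read_csv(smoking_path) if smoking_path.exists() else None
        meas_path = path / "radon_measurements.csv"
        measurements = pd.read_csv(meas_path) if meas_path.exists() else None
        return cls(population, cases, exposure, smoking_series=series,
                   measurements=measurements, **kwargs)

    # ------------------------------------------------------------------
    def prevalence_for(self, scenario: ScenarioConfig) -> pd.DataFrame | None:
        """Lagged, imputed, dwelling-filled prevalence for the scenario."""
        if self.smoking_series is None:
            return None
        return smoking_mod.assemble_prevalence(
            self.smoking_series,
            reference_year=scenario.reference_year,
            lag=scenario.smoking_lag_years,
            flat_share=self._flat_share,
        )

    def fit(
        self,
        scenario: ScenarioConfig | None = None,
        group_err: tuple[ERRSpec | float, ERRSpec | float] | None = None,
    ) -> attribution.AttributionResult:
        """Run one attribution scenario (mitigating first if configured)."""
        scenario = scenario or ScenarioConfig()
        exposure = self.exposure
        if scenario.action_level is not None:
            exposure = self.mitigated_exposure(scenario.action_level)
        return attribution.run_scenario(
            self.population, self.cases, exposure,
            self.prevalence_for(scenario), scenario,
            smoking_rr=self.smoking_rr, group_err=group_err,
        )

    def mitigated_exposure(self, action_level: float) -> ExposureSet:
        source = self.measurements if self.measurements is not None else self.exposure
        return attribution.mitigate(source, action_level, gsd=self.gsd)

    def mitigation_curve(
        self,
        action_levels: Sequence[float] = (100.0, 200.0, 300.0),
        scenario: ScenarioConfig | None = None,
    ) -> pd.DataFrame:
        """Avoidable and prevented cases per mitigation action level.

        The unmitigated baseline is rebuilt from the same source as the
        mitigated sets (raw measurements when available), so an action
        level above every measured concentration prevents exactly zero
        cases.
        """
        scenario = scenario or ScenarioConfig()
        scenario = replace(scenario, action_level=None)
        if self.measurements is not None:
            base_exposure = build_exposure_sets(self.measurements)
        else:
            base_exposure = self.exposure
        prevalence = self.prevalence_for(scenario)
        base = attribution.run_scenario(
            self.population, self.cases, base_exposure, prevalence, scenario,
            smoking_rr=self.smoking_rr,
        )
        base_avoid = base.totals()["avoidable"]
        rows = []
        for level in action_levels:
            res = attribution.run_scenario(
                self.population, self.cases,
                self.mitigated_exposure(float(level)), prevalence, scenario,
                smoking_rr=self.smoking_rr,
            )
            avoid = res.totals()["avoidable"]
            rows.append({"action_level": float(level), "avoidable": avoid,
                         "prevented": base_avoid - avoid})
        return pd.DataFrame(rows).set_index("action_level")

    def joint_effect(self, scenario: ScenarioConfig | None = None) -> attribution.JointEffectResult:
        scenario = scenario or ScenarioConfig()
        prevalence = self.prevalence_for(scenario)
        if prevalence is None:
            raise ValidationError("joint-effect analysis requires a smoking series")
        return attribution.joint_effect(
            self.population, self.cases, self.exposure, prevalence, scenario,
            smoking_rr=self.smoking_rr,
        )

    def simulate(
        self, spec: unc_mod.SimulationSpec, floor: float = 25.0, **kwargs
    ) -> unc_mod.UncertaintyResult:
        return unc_mod.run_simulation(
            spec, self.population, self.cases, self.exposure,
            smoking_series=self.smoking_series, floor=floor,
            smoking_rr=self.smoking_rr, flat_share=self._flat_share, **kwargs
        )
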