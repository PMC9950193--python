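# radonburden

Estimation of the lung-cancer burden attributable to residential radon in a
stratified national population, for radiation-protection analysts and
environmental epidemiologists.

Residential radon (²²²Rn and its progeny) is the second most important
cause of lung cancer after smoking. This package implements a
population-attributable-fraction pipeline over (region × age group × sex ×
dwelling type) strata:

1. **Case allocation by smoking status.** Cancer registries do not record
   smoking, so each stratum's registered cases *L<sub>s</sub>* are split
   over current/former/never smokers by relative-risk-weighted prevalence,
   *L<sub>i</sub> = P<sub>ω(i)</sub> L<sub>s</sub> / Σ<sub>i</sub>
   P<sub>ω(i)</sub>* with *P<sub>ω(i)</sub> = p<sub>i</sub> RR<sub>i</sub>*
   (defaults RR = 15 for current, 4 for former smokers).
2. **Linear-ERR radon attribution.** Lung-cancer relative risk follows the
   linear excess-relative-risk model from pooled residential case-control
   studies, RR(X) = 1 + βX with β the ERR per 100 Bq m⁻³ (8.4% uncorrected,
   16% corrected for measurement error, 31% for small cell carcinoma) and X
   the stratum's geometric-mean radon concentration. Attributable cases are
   *L − L/RR(X)*; **avoidable** cases are measured against a universal
   counterfactual floor of 25 Bq m⁻³, the practical minimum of indoor
   exposure.
3. **Scenario analyses.** Mitigation of concentrations above action levels
   (100/200/300 Bq m⁻³), decomposition of the avoidable burden into
   radon-alone and radon×smoking joint components, and a smoker-specific
   ERR variant (smokers 10%, non-smokers 17%, derived from a weighted
   average of 16%).
4. **Monte Carlo uncertainty.** Each run draws the ERR from its normal
   uncertainty distribution, a smoking-prevalence year uniformly from
   2000–2015, and per-cell survey GMs from the strictly bimodal two-survey
   distribution; negative avoidable aggregates are truncated to zero and
   the mean with 2.5%/97.5% quantiles reported.

Inputs are four delimited-text tables (population, cases, radon survey GMs
or raw measurements, smoking prevalence series). A built-in synthetic-data
generator reproduces the structure of the Finnish setting (20 regions,
5.28 M people, 63% in houses, house/flat GM contrast ≈ 2, smoking more
prevalent in flats), so the full pipeline is testable without access to
the original registry and survey data, and parameter recovery can be
demonstrated against the generator's closed-form expectations.

## Worked example

```python
from radonburden import (SyntheticConfig, generate_dataset,
                         RadonBurdenModel, ScenarioConfig, ERRSpec)
from radonburden.uncertainty import simulation_spec
from radonburden.report import render_results

ds = generate_dataset(SyntheticConfig(seed=1))
model = RadonBurdenModel(ds.population, ds.cases, ds.exposure,
                         smoking_series=ds.smoking_series,
                         measurements=ds.measurements)

result = model.fit(ScenarioConfig(err_spec=ERRSpec(16.0)))
print(result.summary())
```

```
Radon-attributable lung cancer burden
=====================================================
Endpoint:            all_lung
ERR per 100 Bq m-3:  16%
Exposure set:        average
Counterfactual:      25 Bq m-3
-----------------------------------------------------
Total cases:                    2832.0
Radon-attributable:              316.6
Attributable at floor:           108.9
Avoidable (above floor):         207.7
PAF (avoidable/total):           0.073
-----------------------------------------------------
Avoidable, flat                     43.7
Avoidable, house                   164.0
```

Of 2832 simulated registered cases, 316.6 are attributable to radon at the
observed concentrations; 108.9 of those would persist even at a universal
25 Bq m⁻³, leaving 207.7 avoidable (PAF 0.073). Houses carry most of the
avoidable burden because their radon levels are roughly twice those of
flats.

```python
print(model.mitigation_curve().round(1))
#               avoidable  prevented
# action_level
# 100.0             123.8       82.6
# 200.0             170.6       35.7
# 300.0             186.8       19.6

print(render_results(model.simulate(simulation_spec("B", reps=10_000, seed=1))))
# Simulation B (ERR ~ N[16, 6.6^2], M = 10000, endpoint = all_lung, seed = 1)
# margin                             mean (95% UI)
# overall: total                     201 (47, 323)
# dwelling: house                    159 (38, 253)
# ...
```

Mitigating every dwelling above 100 Bq m⁻³ would prevent 82.6 of the 207.7
avoidable cases; the Monte Carlo mean (201) sits slightly below the point
estimate because the attributable fraction is concave in the ERR draw and
negative draws are truncated.

The same pipeline is scriptable from the shell:

```bash
radonburden synth --seed 1 --out data/
radonburden run --data data/ --err 16 --floor 25 --exposure-set average --out out/
radonburden uncertainty --data data/ --sim B --reps 10000 --seed 1 --out out/
```

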