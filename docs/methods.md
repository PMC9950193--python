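# Methods

## Model

All computation is stratified by region, age group (0–34, 35–44, 45–54,
55–64, 65–74, 75–84, 85+; the two youngest bands may be supplied collapsed
as 0–44), sex, and dwelling type (flat vs house). The stratum is the
atomic unit; every national figure is an exact sum of per-stratum
real-valued quantities, and rounding to integers happens only at report
rendering (so sums of rounded entries need not match rounded sums, which
reports footnote).

**Radon risk.** Lung-cancer relative risk is linear in radon activity
concentration, RR(X) = 1 + βX/100 with β the percent excess relative risk
per 100 Bq m⁻³. The coefficient is a configuration input with three
conventional values: 8.4 (pooled residential estimate for observed radon),
16 (corrected for measurement error), and 31 for small cell carcinoma
(30 selectable). The same β applies to all ages, sexes and smoking groups,
which makes the radon × smoking interaction multiplicative.

**Attribution.** With L registered cases in a stratum at concentration X,
cases not attributable to radon are L/RR(X), so attributable cases are
L·AF(X) with AF(X) = (βX/100)/(1 + βX/100). Avoidable cases are
attributable cases in excess of a universal counterfactual floor
(default 25 Bq m⁻³, roughly the lowest decile of residential levels):
L·(AF(X) − AF(floor)). AF is increasing and concave in X and in β.
Negative avoidable values (cells below the floor) are preserved
internally; truncation to zero is a reporting policy applied only in the
Monte Carlo engine.

**Exposure.** Every resident of a (region, dwelling) cell is assigned the
cell's geometric-mean concentration; exposure is conditional on region and
dwelling type but independent of age, sex and smoking within the cell.
Three exposure sets are supported: each of the two national surveys and
their arithmetic average, averaged on the per-cell GMs (not on pooled raw
measurements) — consistent with publishing regional maps as averages of
the survey GMs. Whether the original averaging weighted surveys by sample
size is unstated; unweighted is implemented. Seasonal correction of
single-period measurements is a configurable multiplicative factor table
defaulting to identity; the published coefficient sets are treated as
external configuration, not re-derived.

**Smoking.** Prevalence tables vary by year, age, sex and dwelling (not
region) and are lagged 10 years behind the reference year (2007 for a 2017
analysis). Two imputation steps mirror survey coverage gaps. (a) The 85+
band is extrapolated per sex and smoking category from a linear trend of
prevalence against age-band midpoint (dwellings pooled; six fits in
total); the exact functional form of the original six regression models is
unpublished, so linearity was chosen for transparency and the fit function
is pluggable. Extrapolations are clamped to [0, 1] and renormalised.
(b) Dwelling contrast for seniors (65+) is carried over from the 55–64
band and for adolescents from the 45–54 band as a flat/house *ratio*
applied to the recipient band's own overall level: solving p_flat = r·p_house
and w·p_flat + (1−w)·p_house = overall (w the recipient's flat population
share) preserves the overall prevalence exactly. The transfer is applied
to the current and former categories; never smokers take the complement,
which preserves that category's overall as well and keeps each row a
proper distribution.

**Case allocation.** Within each stratum, registered cases split over
smoking categories proportionally to prevalence × relative risk
(RR 15/4/1 for current/former/never, identical for men and women).
Allocation is exact-conserving per stratum and performed before any
aggregation; aggregating stratum-wise allocations differs from allocating
national totals with national prevalence whenever prevalence varies across
strata — that difference (higher radon, lower smoking in houses) is the
reason for dwelling-type stratification.

**Joint effect.** For smoking group g with allocated cases L_g and
population N_g, the radon-alone component applies the avoidable-case
formula to N_g·I_never (the cases g would record at the never smokers'
incidence I_never = L_never/N_never in that stratum); the joint component
is the remainder of g's avoidable total. For never smokers the joint part
is identically zero. The smoker-specific-ERR variant solves
e_s = ratio·e_n, w·e_s + (1−w)·e_n = ē for a given smoker/non-smoker ERR
ratio (10/17 from miner studies) and weight; with ē = 16 and w = 1/7 this
yields (10, 17). The weighting behind the published pair is unstated, so
the weight is an explicit parameter rather than a hard-coded constant.
In that analysis current and former smokers form a single group.

**Mitigation.** An action level caps the exposure distribution, not just
its mean: with raw measurements each value above the level is capped and
cell GMs recomputed; with GM-only input a lognormal model with configured
GSD gives the capped GM analytically (E[min(log X, log c)] under
log X ~ N(log GM, log² GSD)), a labelled approximation. Whether the
original analysis capped measurements or shifted GMs is unstated; capping
is primary here. Prevented cases are the difference in avoidable cases
between the unmitigated and mitigated exposure sets, both built from the
same source, so an action level above every measurement prevents exactly
zero.

**Uncertainty.** Per Monte Carlo run: one ERR draw from a normal prior
(applied identically across strata — the ERR is a single epidemiological
parameter), one smoking year drawn uniformly from 2000–2015 (globally per
run), and one survey pick per (region, dwelling) cell with probability ½
each (a global per-run pick is available behind a switch; independent
per-cell draws are the less correlated default). Five named simulations
A–E carry the conventional priors N(8.4, 3.3²), N(16, 6.6²), N(9.5, 2.3²),
N(17, 6.1²) and N(27, 13.7²) (E for small cell carcinoma); a
`methods_text` preset exposes the variant readings (mean 8, sd 2.43/6.18)
that circulate for the same distributions, neither silently preferred.
Negative aggregates are truncated to zero at the reported margin
(stratum-level truncation is available behind a flag and documented as
changing sums); the mean and the 2.5%/97.5% empirical quantiles
(linear-interpolation definition) are reported. Default 10,000 reps run in
about a second (fully vectorised with a single seeded generator; draws are
reproducible for a given seed and rep count).

## Synthetic data generator

The generator emulates the structure of the Finnish study setting; its
defaults are the study conditions, not tuning knobs:

- 20 regions with uneven population weights; 5,281,077 people; ~63% in
  houses, with age structure decreasing beyond middle age and flats
  relatively more common among the young and the very old.
- Radon lognormal per (region, dwelling) cell: national
  average-of-surveys GMs 50 (flats) / 90 (houses) Bq m⁻³; per-survey
  levels split in the ratio of the published national survey GMs
  (flats 62:37, houses 109:78, so the second survey is lower); regional
  GMs follow a smooth log-gradient spanning the observed regional extremes
  (flats ~32–86, houses ~44–194), recentred population-weighted to the
  national value. GSDs 2.1 (flats) and 2.7 (houses) make houses the more
  variable type. ~3,000 detector measurements per survey, allocated to
  cells by population share.
- Smoking: current prevalence 0.14 (flats) vs 0.10 (houses) at the 2007
  reference, with an age profile peaking in middle age, men declining and
  women rising mildly over 2000–2015, and a former/current ratio growing
  with age. The 85+ band is deliberately absent from the emitted series so
  the imputation path is exercised; the complete "truth" table (including
  85+) is retained for case generation. The inverse smoking–radon
  correlation is induced only through dwelling type.
- Cases: expected cases per stratum × smoking class are
  N · p_smoking · I_never · RR_smoking · (1 + βX/100) with age and sex
  incidence multipliers on the never-smoker baseline; counts are Poisson
  and summed over smoking classes (the registry does not record smoking).
  True β defaults to 16 (31 for the small-cell endpoint, generated with
  baseline fraction 0.14). The never-smoker baseline incidence
  (6.65 per 100,000 person-years) is the one generator constant not
  printed anywhere; it was set analytically so the national expected case
  count equals 2694 under the other fixed conditions.
- Seeding: one root seed; child streams per table via `SeedSequence`, so
  identical configurations give identical datasets.

Because the generator and the attribution engine share the linear-ERR
model, the expected avoidable count has a closed form
(Σ E[L_s]·(AF(X_s) − AF(floor)), variance Σ E[L_s]·(ΔAF)²), which the test
suite uses for parameter recovery: across 20 seeds the pipeline's national
avoidable estimate must fall within 3 Monte Carlo SE of this expectation.

What the generator does **not** emulate: within-region dwelling-count
geography (the regional allocation is a free, documented choice),
measurement-error ("usual radon") processes beyond lognormal sampling,
building-level covariates, regional smoking variation, or cohort effects
in smoking beyond smooth trends. Passing tests therefore demonstrate
correctness of the estimator under the model's own assumptions, not the
realism of any particular national estimate.

## Numerical choices

- Geometric means are exp(mean(log x)); non-positive measurements are
  rejected.
- The AF denominator 1 + βX/100 is floored at 1e-12 in vectorised Monte
  Carlo code so pathologically negative ERR draws produce large negative
  avoidable values (later truncated) instead of dividing by zero.
- Quantiles use numpy's linear interpolation; for draws 1..M the
  p-quantile is 1 + p(M − 1).
- Rounding in reports is half-away-from-zero.
- Equality of strata across tables is enforced by validated one-to-one
  merges; missing cells fail with the offending stratum named.

## Problem sizes

Tests run the full 20-region (560-stratum) configuration for acceptance
checks and a 6-region configuration for unit fixtures; Monte Carlo tests
use 1,000–10,000 reps (10,000 reps ≈ 1 s wall-clock). These sizes were
chosen to exercise every code path at the study's own scale while keeping
the suite fast.

## Known limitations

- Attribution uses each cell's GM as the exposure of every resident; an
  optional measurement-level mode exists for sensitivity analysis but the
  GM mode is primary.
- The linear no-threshold ERR model is assumed throughout; no
  exposure-age or time-since-exposure weighting (miner-study models are
  out of scope).
- Endpoints are all lung cancers and small cell carcinoma only.
- The uncertainty engine propagates ERR, smoking-year and survey-choice
  uncertainty; sampling variability of the case counts themselves is not
  propagated (the observed registry count is treated as fixed, as in the
  allocation-based design).
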