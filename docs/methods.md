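# Methods

This note documents the models, conventions and design choices behind
`haiforest`, in the spirit of a statistical software vignette. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The Healthy Aging Index

Five indicators are scored 0 (least healthy) / 1 / 2 (healthiest):

| Indicator | Units | 0 | 1 | 2 |
|---|---|---|---|---|
| Systolic blood pressure | mmHg | ≥ 143 | 126–143 | < 126 |
| Random glucose | mmol/L | ≥ 11.1 | 5.6–11.1 | < 5.6 |
| Creatinine (men) | mmol/L | ≥ 114.9 | 97.2–114.9 | < 97.2 |
| Creatinine (women) | mmol/L | ≥ 88.4 | 70.7–88.4 | < 70.7 |
| FVC (men) | L | < 3.2 | 3.2–3.8 | ≥ 3.8 |
| FVC (women) | L | < 2.1 | 2.1–2.6 | ≥ 2.6 |
| Cognition | z | < p10 | p10–0 | > 0 |

**Boundary policy.** The printed bands overlap at shared endpoints
(e.g. "≥ 143" vs "126–143"). We resolve them deterministically: the
least-healthy comparator applies first, then the healthiest strict
inequality, and the middle band is the remainder. For risk-increasing
indicators the bands are `[hi, ∞) / [lo, hi) / (−∞, lo)`; mirrored for the
protective FVC; for cognition the healthiest band is the strict `> 0` as
printed, so an exact 0 is intermediate. Exact-endpoint membership is a
documented package convention, not something the published table decides.

**Cognition threshold.** The 10th percentile is the empirical
linear-interpolation quantile of the analysis population's cognition
z-scores, computed at scoring time (≥ 10 finite values required); an
external threshold can be injected instead. Whether the original cohort
computed it per wave, per age or overall is unknown — population-at-scoring
is our choice, consistent with a within-cohort decline score.

**Age adjustment.** Integer completed years define the age groups; each
participant's total minus their group mean gives the age-adjusted HAI,
which is exactly mean-zero within every group. No pooling of sparse ages by
default (`min_bin_size=1`); optional pooling merges an under-filled bin
with its nearest age neighbour.

Cut-offs ship as an editable structure (`DEFAULT_CUTOFFS`, YAML-overridable
via `load_cutoffs`) with units recorded, so the index generalizes beyond
the default bands. Creatinine units follow the published table's printed
mmol/L label.

## 2. Longitudinal summaries

For a participant's observed waves `w ∈ {1..5}` with values `x_w`:

* `AUE = mean(x_w)` over observed waves (shift- and scale-equivariant;
  equals the wave-3 value for an exactly linear series).
* `TOE` = OLS slope of `x_w` on `w` (shift-invariant, scale-equivariant;
  per 5-year wave interval; equals difference/gap with two observations).
  We deliberately use the all-wave least-squares slope rather than
  last-minus-first over 4: it uses every observed wave and is robust to a
  single aberrant wave. The estimator is a pluggable choice should a
  different trend definition be preferred.
* `percent_of_time = 100 · #yes / #observed`; `transitioned_no_to_yes = 1`
  iff first observed = no and last observed = yes (a first-vs-last rule;
  "ever transitioned" is a defensible alternative the field description
  leaves open).

Summaries use observed waves only — an exposure measured in waves 2–4 is
averaged over exactly those three waves. The time axis is the wave index,
not calendar age, so TOE units are per wave interval. Ordinal exposures
(sleep-hour bands, educational level) are numeric-coded before
summarization; non-time-varying exposures enter as single baseline columns.
Participants missing an exposure entirely receive the feature's
cross-participant median — a simple documented single-value imputation
(multiple imputation is out of scope; the analysis is complete-case on the
outcome). The vectorized matrix builder is property-tested against the
scalar reference definitions.

## 3. Random forest, metrics, importance

* **Split**: seeded permutation; `ceil(0.8 n)` train (2252/563 at
  n = 2815).
* **Tuning**: exhaustive grid × 5-fold CV on the training set, scored by
  mean fold RMSE; deterministic lexicographic tie-break on
  (mtry, ntree, nodesize, maxnodes). The default grid is small —
  `mtry ∈ {p/3, √p, p/2}`, `ntree = 500`, `nodesize ∈ {5, 25}`,
  `maxnodes ∈ {∞, 64}` — because the original grid is unpublished. When
  tuning is skipped the defaults `mtry = p/3, ntree = 500, nodesize = 5`
  (the standard regression-forest heuristics) are used.
* **R² convention**: squared Pearson correlation between predictions and
  observations; a constant predictor (the null model, which predicts the
  training mean) gets R² = 0. This reproduces the way regression-training
  frameworks report a skill-free model as 0.00; the `1 − MSE/Var`
  convention is available behind `r2_convention="residual"`.
* **%IncMSE**: computed on held-out data (the test set), not out-of-bag:
  `100 · mean over repeats (MSE_permuted − MSE_baseline) / MSE_baseline`,
  default 3–5 repeats in pipeline runs. This matches the verbal definition
  of permutation importance while diverging from the R implementation's
  SD-normalized OOB variant; a test cross-checks the values against an
  independent permutation-importance implementation. Ranks break ties
  alphabetically.
* **PDP**: for each of 25 equally spaced grid points between a feature's
  5th and 95th percentiles, the feature column of the full background
  dataset is overwritten and predictions averaged — all other exposures
  keep their original values.

## 4. Top-x selection

The importance ranking is fixed once from the all-exposure model; for each
candidate x the forest is refitted on the top-x features under the same
seeded 5-fold CV, giving the selection curve. `choose_x` operationalizes
"the curve flattens" as the smallest x whose CV RMSE is within `tolerance`
(default 0.01 outcome units) of the curve minimum; the original choice was
made visually, so the full curve is always returned/printed for a human
override. The curve may be evaluated on an explicit x-grid instead of every
x — pipeline defaults use a coarse grid including the full feature count,
which preserves the chosen-x-vs-all-features comparison at a fraction of
the cost.

## 5. Generation-stratified analysis

Each generation is analysed independently (own split, fit, ranking, curve);
per-stratum seeds derive deterministically from the master seed and the
stratum label, so results do not depend on processing order. Age adjustment
is performed once on the pooled population before stratification —
adjusting within each generation instead is available via the library
(whether the original analysis re-derived the outcome per generation is not
stated). Strata under 100 participants are flagged and skipped. The
cross-generation table reports, per exposure ever selected, the number of
generations selecting it and the mean rank where selected, ordered by
(descending times-selected, ascending average rank, name).

## 6. Synthetic cohort generator

The generator emulates the study conditions: generations of 459 / 1155 /
872 / 329 participants (baseline ages uniform in 20–29 / 30–39 / 40–49 /
50–59), five exposure waves 5 years apart, outcome age = baseline + 25
years + 0–3 years of measurement-window jitter (outcome ages ≈ 45–87), sex
Bernoulli(0.533 female). 41 exposures across the four domains yield exactly
86 features (31 continuous/ordinal × AUE+TOE, 10 binary × two percent
summaries, 4 baseline columns).

**Exposure law.** Continuous:
`x_iw = m + g_gen + d(w−1) + u_i + e_iw` with random intercept
`u_i ~ N(0, ρs²)` and stationary AR(1) wave noise of variance `(1−ρ)s²`
and lag-1 correlation ρ (`within_person_correlation`, default 0.7). The
published cohort table reports only AUE/TOE means per generation, so the
wave-level covariance is a free modelling choice; exposures are mutually
independent given generation. Named exposures are calibrated so their
**AUE** means/SDs and TOE means match the published characteristics table
(BMI AUE 25.6 SD 3.5, TOE 0.6; DHD15 AUE 66.1 SD 11.8 measured in waves
2–4 only; pack-years AUE 8.8; NO₂ AUE 27.7 TOE −1.6; cholesterol
medication ~5% of the time, rising with generation age; …): baselines are
therefore `AUE − d·mean(w−1)` and generation shifts reproduce the
per-generation columns. Binary exposures use the same law on the
probability scale, clipped to [0, 1]; ordinals draw a persistent band with
occasional switches.

**Outcome law.** Indicator latent values are linear: a sex-specific
intercept, an age slope (so the crude HAI declines across generations and
age adjustment is meaningful), plus the planted effects
`Σ β · (realized summary − its cohort mean)` and Gaussian noise
(SDs: sbp 12 mmHg, glucose 1.0 mmol/L, creatinine 10 mmol/L, FVC 0.45 L,
cognition 0.9 z). Linearity is the simplest law under which
parameter-recovery tests have known truth. The default plants three
effects — AUE(BMI)→SBP +4.0 mmHg per kg/m², %time(cholesterol
medication)→glucose +0.08 mmol/L per percentage point,
AUE(DHD15)→cognition +0.06 z per index point. These are *net synthetic
effects*, not literature estimates: they are sized so the fitted model
lands in the modest-performance regime characteristic of exposome
prediction of aging (test R² in the high teens against 0 for the null, a
~9% RMSE reduction), which the test suite verifies by running the
pipeline.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: cross-exposure correlation (real anthropometric
and cholesterol measures are strongly collinear, which disperses importance
across proxies), selective attrition (healthier participants remaining),
measurement error in questionnaire exposures, non-linear or interactive
exposure effects, and item-level instruments (diet scores, activity
questionnaires, air-pollution dispersion models are generated directly as
derived values). Planted-predictor recovery here is therefore an easier
problem than the real analysis.

## 7. Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`, forest `random_state`); identical seeds give
byte-identical CSV outputs. The acceptance checks run the default cohort
(n = 2815, 86 features) at the production forest size (ntree = 500) over
10 seeds for predictor recovery, and evaluate the selection curve on one
seed over the coarse x-grid {1, 2, 3, 5, 10, 86}; unit and property tests
use smaller simulated problems (n = 100–400, 10–20 features, 30–100 trees)
chosen to keep the full suite fast while preserving each check's
discriminating power.
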