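# Methods

## Problem and model

`glimscreen` evaluates malnutrition instruments as *screening tools for
cancer cachexia*. The reference standard is the 2011 international consensus
definition of cancer cachexia, a binary diagnosis met when any of

1. weight loss > 5% over the past six months,
2. BMI < 18.5 kg/m² (the WHO Asian cutoff; the original consensus value of
   20 kg/m² is available via `bmi_cutoff`) together with weight loss > 2%,
3. appendicular skeletal muscle index (ASMI) consistent with sarcopenia
   (male < 7.0, female < 5.4 kg/m²) together with weight loss > 2%

holds. The candidate screens are:

* **One-step GLIM** — malnutrition diagnosed directly: ≥ 1 phenotypic
  criterion (weight loss, low BMI, reduced muscle) AND ≥ 1 etiologic
  criterion (reduced intake, inflammation/disease burden); severity is
  severe when any phenotypic criterion reaches its severe grade.
* **Two-step GLIM** — identical, but only for patients first screened at
  nutritional risk by NRS-2002 (total ≥ 3); screen negatives are labelled
  well nourished without assessment.
* **PG-SGA** — total score with triage bins 0–3 / 4–8 / ≥ 9; ≥ 4 is
  classified malnourished.

Because the two-step rule is the one-step rule conjoined with the NRS gate,
every two-step positive is a one-step positive (screen-filter containment).
And because consensus criteria 1 and 2 use the same (or stricter) thresholds
as the GLIM weight-loss and low-BMI phenotypes, any subject cachectic via
criterion 1 or 2 is one-step malnourished under the default etiologic
policy: the structural reason the one-step route is 100% sensitive when
criterion 3 contributes no additional cases.

## Thresholds and parameters

All GLIM thresholds are centralised in `GlimThresholds` (YAML-configurable);
comparisons are strict as written (`> 5%`, `< 18.5`, `≥ 3`):

| parameter | default | meaning |
|---|---|---|
| weight loss moderate / severe | > 5% / > 10% per 6 mo | phenotypic grading |
| low BMI moderate | < 18.5 (< 20 if age ≥ 70) kg/m² | Asian consensus values |
| low BMI severe | < 17.0 (< 17.8 if age ≥ 70) kg/m² | Asian consensus values |
| reduced muscle moderate / severe | < p15 / < p5 | within-sex cohort percentiles of MAMC, CC, HGS/W |
| NRS-2002 screen | total ≥ 3 | two-step gate |
| ASMI sarcopenia | male < 7.0, female < 5.4 kg/m² | consensus criterion 3 |

Muscle cutoffs are derived from the full analysis cohort within sex (not
from a healthy reference), with the type-7 linear-interpolation quantile
(`numpy.percentile(method="linear")`) recorded in the cutoffs' provenance;
at least 20 non-missing values per (sex, measure) are required. The
beyond-six-month weight-loss alternatives (> 10% / > 20%) are carried in the
configuration but inactive, since only the six-month interval is recorded.

Etiologic policies: the default, `malignancy-inflammation`, treats every
subject's active cancer as satisfying the inflammation/disease-burden
criterion and maps reduced intake to the anorexia flag. This is the only
operationalisation consistent with a cohort in which no cachectic patient is
one-step well-nourished while weight loss is the cachexia entry criterion.
`biomarker` (albumin < 35 g/L or NLR > 3) and `anorexia-only` are available
for sensitivity analyses.

## Evaluation statistics

* **Confusion metrics** dichotomise a k-level ordinal classifier against the
  binary reference; sensitivity = 100·TP/(TP+FN) etc. Raw values are kept at
  full precision; display rounding is half-up to one decimal (percents) and
  three decimals (AUC), via `decimal.Decimal` since Python's `round` is
  banker's.
* **Ordinal AUC** is the tie-corrected concordance: (concordant pairs + ½
  tied pairs) / (n_case · n_control), computed in exact integer arithmetic
  from the table counts. It equals the trapezoidal area under the empirical
  ROC through the k−1 operating points; `roc_points` (via
  `sklearn.metrics.roc_curve`) provides the per-subject route and the two are
  cross-checked to 1e-12 in tests. Three-level tools are ranked by category;
  this is deliberately the default because the bundled reference tables carry
  no finer information, and the published AUCs are reproduced exactly by the
  ordinal computation.
* **Decision curves**: net benefit NB(pt) = TP/N − (FP/N)·pt/(1−pt) for the
  fixed binary rule, against treat-all (crosses zero exactly at
  pt = prevalence) and treat-none (≡ 0). No smoothing; pt = 1 is rejected.
* **Subgroup evaluation** stratifies by TNM stage, sex, age group or tumour
  type; strata with fewer than 10 reference positives are flagged unstable,
  single-class strata are omitted with a warning, and exclusions for missing
  data are logged. Optional bootstrap confidence intervals are not
  implemented; point estimates mirror the reference analysis.

## Synthetic cohort generator

`generate_cohort` emulates a mixed Chinese solid-tumour inpatient cohort
with a latent cachexia state:

1. Tumour type from a configurable case mix; the five types with published
   per-type prevalence use those values (pancreatic 0.450, gastric 0.325,
   esophageal 0.285, ovarian 0.238, colorectal 0.217); the remaining types
   are free parameters chosen once as field-plausible values. The whole
   per-type prevalence vector is rescaled so the mixture equals the overall
   prevalence target (default 17%).
2. A single latent severity factor `s = 2.4·cachexia + z`, `z ~ N(0,1)`,
   drives all measures — the simplest structure that yields realistic
   correlation between instruments and the reference standard.
3. Class-conditional observables follow the reference cohort's baseline
   table: BMI 23.57 ± 3.06 (non-cachectic) vs 19.53 ± 3.39 (cachectic),
   MAMC 21.03 vs 19.88 cm, CC 33.72 vs 30.80 cm, albumin, MAC, TSF, KPS,
   anorexia rates 10.4% vs 24.8%, and TNM distributions per class. Weight
   loss averages 0.5% vs 9.0% with a 1.2 loading on `z`. Prior weight is
   generated jointly, `prior = current/(1 − WL/100)`, so the derived
   percentage is exact.
4. Instrument scores are noisy monotone functions of severity. The NRS-2002
   mapping (noise sd 0.2505, cut 1.1464) was solved analytically so at-risk
   rates are 13.3% (non-cachectic) and 88.8% (cachectic); the PG-SGA mapping
   (noise sd 1.574, bin cuts 0.39 / 2.20) solves the published joint bin
   rates, giving marginal bins ≈ 50.8 / 30.6 / 18.6%.
5. Configured per-field missingness (default 2–3% for anthropometry and
   biomarkers) is applied last. ASMI is generated only when enabled, so the
   reference standard's dependence on criterion 3 can be switched on and off.

All noise standard deviations scale with `noise_scale`; at 0 the cohort is a
deterministic function of the latent draws and the consensus classifier
recovers the latent state with > 99% accuracy (pipeline closure). The latent
state is emitted as a separate truth table and never enters the cohort CSV.

What the generator does *not* emulate: centre effects, survival, treatment,
recall error in the six-month prior weight, or the real cohort's full
correlation structure between instruments. Passing tests therefore
demonstrate the correctness and internal consistency of the rule engines and
evaluation machinery under realistic marginals — not clinical performance on
real data, for which the bundled reference tables are the ground truth.

## Numerical and design choices

* Missing data are excluded per classifier (never imputed), with per-reason
  exclusion counts logged; a record missing all three muscle measures grades
  reduced-muscle NONE with a warning.
* Supplied values always win over derivations; a disagreement beyond 0.5
  units logs a consistency warning. Derivation is idempotent.
* Weight gain is kept as a negative weight-loss percentage.
* Cross-tab level order is explicit; reversing it maps AUC → 1 − AUC
  (verified property).
* Printed summary tables can be expanded to per-subject labels
  (`crosstab_to_cohort`), so aggregate tables flow through the same
  per-subject engine as cohorts.
* The consensus qualifier "in the absence of simple starvation" has no
  recorded correlate and is not operationalised; cachexia staging
  (pre-cachexia / refractory) is out of scope.

## Problem sizes

The test suite uses cohorts of 5,000–20,000 synthetic subjects for
calibration and ordering properties, 10,000 per sex for percentile
calibration, and 1,000 random small tables for the AUC oracle comparison;
the full suite runs in well under a minute. `scripts/acceptance.py`
re-derives the headline metrics from the bundled counts (n = 8,478) and the
latent prevalence from a fresh 10,000-subject cohort.
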