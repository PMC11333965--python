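# Methods

## The problem and the model

Unilateral visuospatial neglect is inattention to one half of space after
brain injury, despite intact vision. `vrneglect` implements an
explainable, rule-based classifier of neglect from immersive-VR visual
search gameplay: a seated player searches for a target letter among
distractors placed on a 2 m sphere around their calibrated head position,
over eight game levels (two repetitions each of set sizes 2, 8, 16, 24;
the 2-element level is a tutorial and never analysed). Per trial the game
logs set size, target location, correctness and reaction time (RT); per
level it logs the mean lateral angle of the headset and gaze raycasts.
Lateral angles are signed: negative = left of the calibrated midline.

### The eight raw metrics

Orientation (directional bias; positive = rightward, the pattern of
*left* neglect):

| metric | definition | units |
|---|---|---|
| `accuracy_subtract` | accuracy(right targets) − accuracy(left targets), pooled over set sizes 8/16/24 | pp |
| `rt_subtract` | mean RT(left) − mean RT(right), correct trials, outlier-filtered pooled | s |
| `headset_mean`, `gaze_mean` | mean lateral raycast angle, per set size | ° |
| `headset_slope`, `gaze_slope` | OLS slope of those means against set size | °/item |

Challenge (search inefficiency):

| metric | definition | units |
|---|---|---|
| `accuracy_slope` | OLS slope of per-set-size accuracy | %/item |
| `rt_slope` | OLS slope of per-set-size mean correct RT | s/item |

RT outliers are removed per player with Tukey fences
(Q1 − 1.5·IQR, Q3 + 1.5·IQR) on correct-trial RTs — pooled across all
analysis trials for the subtraction contrast, within each set size for
the per-set-size means. Quartiles use linear interpolation between order
statistics everywhere in the package; this convention is not dictated by
the original description of the method, but every fence (and hence every
downstream label) depends on it, so it is fixed and documented here.
Values exactly on a fence are kept.

### Normative thresholding

A metric value is *atypical* iff it lies strictly outside the Tukey
fences of the control cohort **and** of the patient cohort (computed per
metric; per set size for the two mean metrics). This conjunction demands
behaviour unusual relative to both healthy players and the clinical
population, and can only reduce the false-positive rate relative to a
single-cohort rule (verified by simulation in the acceptance suite).

Flags: the six orientation metrics flag sign(value) ∈ {−1, 0, +1} when
atypical; the mean metrics flag when atypical at ≥ 1 set size, direction
from the set size with the largest fence exceedance (exact opposite-sign
ties flag 0 with a warning). The two challenge flags are one-sided —
accuracy falling or RT rising with set size; a player who *speeds up*
with set size is not "challenged", even if statistically atypical.
Missing metrics flag 0 with a warning: absence of data is never treated
as pathology.

### Classification

Summary scores: atypicality = count of non-zero flags (0–8); orientation
= algebraic sum of the six orientation flags (−6..+6, opposite effects
cancelling); challenge = sum of the two challenge flags (0–2); severity =
proportion of detection errors in the worse hemispace (0–1, descriptive
only — the error-proportion reading is the one consistent with typical
players scoring ≈ 0).

Label rule: **neglect** iff |orientation| > 1 or (|orientation| > 0 and
challenge > 0); **minor atypicality** iff some flag is set but the rule
is not met; **non-neglect** iff no flag is set. The rule uses
|orientation| so right-neglect (negative orientation) is handled
symmetrically. Neglect therefore always implies atypicality ≥ 2.

Category coding for neglect cases: side letter (L/R from the orientation
sign), plus 'O' when |orientation| ≥ the median |orientation| of the
neglect cohort, plus 'C' when challenge ≥ its median (medians pooled over
both sides). "At or above the median" (≥, not >) is the reading that
reproduces the observed cut-offs when many players sit exactly at the
median; explicit cut-offs can be passed to score new players against a
frozen cohort.

## Validation statistics

The binary reference test (pen-and-paper screening) is cross-tabulated
against the three VR classes two ways: Model 1 keeps all three classes
(the predictor's minor-atypicality row exists with zero counts); Model 2
pools non-neglect and minor atypicality into one not-neglect class.
Per-class metrics follow the standard one-vs-rest formulas (sensitivity,
specificity, balanced accuracy, PPV/NPV via the prevalence forms, F1 with
β = 1, prevalence, detection rate, detection prevalence). Overall
accuracy carries an exact Clopper–Pearson 95% CI, and is tested against
the no-information rate with a one-sided exact binomial tail — the
standard no-information-rate test; both choices reproduce the benchmark
intervals and P-values for 35/51 and 43/51 agreement at the precision
those benchmarks are stated to, which the acceptance suite checks. Agreement beyond chance is
Cohen's κ = (P_o − P_c)/(1 − P_c), computed from the matrix marginals
(cross-checked against scikit-learn in tests). Zero-denominator metrics
propagate as NaN, never as 0.

Risk modelling is univariable Poisson regression (log link, ML via
statsmodels GLM) of the atypicality count on one covariate at a time;
effects are incidence rate ratios with Wald 95% CIs. Categorical
predictors are dummy-coded against the least frequent level by default
(a combined reference can be given). For a binary predictor the IRR
equals the ratio of group mean counts exactly — used as a closed-form
oracle in tests. Patients with atypicality 0 are retained in the fit;
excluding them would discard most of a typical cohort.

## The synthetic cohort generator

No patient data ship with the package; a seeded simulator provides the
study conditions. Per trial, correctness is Bernoulli with
p = base + slope·set_size − deficit(hemispace), corrupted by a lapse
process; RT is log-normal (positive, right-skewed; the generative family
is a package choice fixed for reproducibility) around
base + slope·set_size + penalty(hemispace). Orientation summaries are
normal around bias_mean + bias_slope·set_size with SD `angle_noise_sd`;
when per-frame raycasts are requested the summary is the empirical frame
mean, keeping the two surfaces consistent. Defaults: 40 trials per level
(20 per hemispace, balancing hemispace proportions), accuracy base 0.95,
accuracy slope −0.2 pp/item, RT base 1.0 s, RT slope 0.04 s/item, angle
noise 1.5°, RT log-SD 0.22, lapse 0.01 — values a practitioner would
call typical for healthy visual search at these set sizes.

Presets encode the observed neglect categories: LOC (left accuracy
deficit 0.40, left RT penalty 0.8 s, +25° bias, steep accuracy slope),
LO (+25° bias with +0.5°/item slope), LC (left RT penalty + steep RT
slope), L (+25° bias only), RO/RC mirrored to the right, and `minor`
(a lone left RT penalty → exactly one flag). The default patient mix
fixes per-cohort counts (largest remainder, shuffled order) of
32 control-like, 5 minor, 3 LOC, 2 LO, 2 LC, 2 L, 2 RO, 3 RC per 51
patients, giving simulated label prevalences of ≈ 28% neglect / 11%
minor / 61% non-neglect.

What the simulator does **not** emulate — and hence what passing tests
do not show about real data:

* minor atypicality in real cohorts arises from *diverse* single-feature
  outliers; one fixed minor profile concentrates them on one metric, so
  its prevalence must stay low (~10%): if any one metric is atypical in
  more than ~25% of patients, the patient-cohort quartiles move into the
  atypical cluster and the conjunction rule stops flagging it — a
  property of the rule itself, visible in the simulator;
* headset and gaze biases are identical in expectation (no dissociation
  between head and eye orientation, which real patients show);
* no drift-diffusion-style cognitive process, no fatigue or learning
  across levels, no correlation between deficit severity and age or
  lesion covariates.

## Numerical choices and degenerate inputs

* Quartiles: linear interpolation; fences refused below 4 finite values.
* Boundary values (exactly on a fence) are typical (strict inequalities).
* On-sphere validation tolerance: 1e−6·r; lateral angle in (−180, 180],
  vertical in [−90, 90]; midline targets (lateral angle exactly 0) enter
  neither hemispace contrast.
* Per-player simulation streams derive from `SeedSequence([master, index])`,
  so cohorts are reproducible independent of iteration order.
* Constant heatmap columns normalize to 0.5 with a warning; positions
  with no surviving correct trials carry NaN RT in position maps.

## Problem sizes

The test and acceptance runs use 30 controls + 51 patients per cohort;
parameter recovery aggregates 100 seeded cohorts, conjunction
suppression 10 null cohorts, and Poisson CI coverage 200 simulated
two-group cohorts (n = 51) — sizes chosen to make the empirical rates
stable at the asserted thresholds.

## Known limitations

* Cohort-scale results from real patient cohorts (label prevalences,
  clinical risk-factor IRRs) depend on patient data the package does not
  ship; the package instead verifies the machinery by oracle
  equivalence, recovery and coverage properties.
* No canonical normative cut-off values ship with the package; fences
  are always derived from the cohort at hand (and can be frozen/reloaded
  as JSON).
* The per-set-size reading of the mean-metric fences is adopted; a
  pooled reading would differ when repetitions are unbalanced.
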