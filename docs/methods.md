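# Methods

This note documents the modeling choices behind `copreserve`: what each
stage computes, why its defaults are set the way they are, what the
synthetic-data generator does and does not emulate, and where the design was
genuinely open.

## Signal model and preprocessing

A trial is six synchronized COP displacement channels (left/right foot and
overall center, X = mediolateral, Y = anteroposterior), nominally 100 Hz for
20 s (T = 2000 samples). Cleaning runs per channel in a fixed order:

1. **Outlier replacement.** Points with `|x − μ| > 3·SD` are replaced by μ.
   μ and SD are computed once over the raw series, before any replacement
   (single flag-then-replace pass, strict inequality). SD is the population
   SD throughout the package — the convention is not forced by the method,
   but using one convention everywhere keeps the Z-score guard and template
   statistics mutually consistent. A constant channel is returned unchanged.
   Runs of ≥ 5 contiguous replacements are logged as a diagnostic (isolated
   spikes are the expected artifact; long runs suggest the 3-SD rule is
   eating signal), but no contiguity-specific handling is applied.
2. **Origin translation.** The first sample of each channel is subtracted,
   so every trajectory starts at (0, 0). Translation-by-first-sample (rather
   than mean-centering) is chosen because the step exists to remove initial
   foot-placement differences while leaving relative displacement intact.
3. **Z-score.** `(x − mean)/SD` with population SD; constant channels map to
   zeros.

Both the *translated* (mm) and *standardized* (unitless) variants are kept.
Template construction, DTW and the LSTM embeddings consume the standardized
variant; the statistical descriptors default to the translated variant
because `CV = σ/μ` is a 0/0 on Z-scored data (μ ≈ 0). If a translated
channel still has `|μ| < 1e−8`, the CV is regularized to `σ/(|μ| + 1e−8)`
and a warning is logged. A config switch (`stats_on="standardized"`)
reproduces the literal all-standardized reading for sensitivity analysis.

## Healthy templates

Per posture and channel, the template is the pointwise median of the control
subjects' standardized series (one series per subject — the mean of that
subject's trials by default; per-trial aggregation is configurable since
protocols differ on this point). Even-count medians average the two middle
values. Before the median, each timepoint's cross-control vector is screened
with a two-sided Grubbs test (α = 0.05, critical value from the Student-t
quantile formula). The test is *diagnostic*: flags are counted and logged,
values are not removed, matching a screening step meant to confirm that
upstream cleaning left no extreme stragglers. `exclude_outliers=True`
switches to exclusion for sensitivity analysis. Patients never enter
template construction.

**Template scope.** The default builds one template per posture from all
controls, outside the cross-validation loop — the single-pass protocol.
This has a measurable consequence: each control contributes (with weight
roughly 1/n_controls) to the very curve it is later compared against, so
control DTW distances are biased slightly low and a *null* cohort can
classify marginally above chance when n_controls is small. At 40 controls
the effect is small (pipeline null ROC-AUC ≈ 0.55–0.6 at short series
lengths in our tests); at 12–15 controls it is not. The package therefore
also provides `template_scope="per_fold"`, which rebuilds the template from
training-fold controls only and re-extracts features per fold, removing the
self-reference entirely at ~5× feature-extraction cost.

## DTW deviation features

Pointwise cost `|a − b|^γ`, cumulative cost by the standard three-move
recurrence with `D(0,0) = 0` (the first matched pair pays its own cost),
restricted to a Sakoe–Chiba band: for sample index i, template indices j are
limited to `[i − w, i + w]` with `w = max(1, ⌈band_fraction · max(m,n)⌉)`
and `band_fraction = 0.1`. The ceiling-and-floor rule preserves the 10%
geometry at full length (w = 200 at T = 2000) while keeping short test
sequences feasible; if `|n − m| > w` the endpoint is unreachable and the
call fails with the band geometry in the message. The γ grid is
{0.5, 1.0, 1.5, 2.0} with default 1.5 — sub-quadratic so single large benign
excursions are not over-penalized, super-linear so sustained misalignment
still dominates; `gamma_sweep` reruns the pipeline across the grid and
reports mean F1/ROC-AUC per γ. The banded DP is verified in the test suite
against an independent full-matrix textbook implementation (exact agreement
with the band disabled; agreement whenever the unconstrained optimal path
lies inside the band).

## Fixed-weight LSTM embeddings

A single-layer, 2-unit LSTM (gates input/forget/output with logistic
activation, tanh candidate, `c_t = f⊙c_{t−1} + i⊙g`, `h_t = o⊙tanh(c_t)`,
`h_0 = c_0 = 0`) is run over each standardized channel; the final hidden
state is the 2-D embedding, 12-D across channels. Weights are drawn once
from uniform(−0.5, 0.5) with a fixed seed (42) and zero biases, and the same
weight set is shared by all six channels. The cell is never trained — it is
a deterministic nonlinear sequence summary, a deliberately lightweight
choice for small cohorts where fitting a recurrent model would overfit.
The initializer distribution and the zero biases are this package's
convention (the architecture, unit count, fixedness and seed are the
method's; the initializer family is not pinned anywhere authoritative);
zero biases make the all-zero-input fixed point exact (`h_T = 0`), which the
tests assert. Embedding components always lie in (−1, 1).

## Statistical descriptors

Per channel: `CV = σ/μ` (population σ, guard above), OLS trend slope against
`t = 1…T` via the closed form `Σ(t−t̄)(x−x̄)/Σ(t−t̄)²`, and `IQR = Q3 − Q1`
with linear-interpolation quantiles (documented so values are
bit-reproducible). Feature names: `DTW-<ch>`, `LSTM-<ch>-1/2`, `cv_<ch>`,
`slope_<ch>`, `iqr_<ch>` — 36 in a fixed order. Per-subject vectors are the
mean of the three trial-level vectors (per-trial rows available).

## Feature selection

`S(i) = f(i)/max(f) + p(i)/max(p)` with f the one-way ANOVA F statistic and
p the mean-decrease-in-impurity importance of a 500-tree seeded random
forest fit on all features. Constant features get F = 0. Greedy traversal in
descending S drops any candidate with `|Spearman ρ| ≥ 0.7` against an
already-kept feature and stops at 7 kept features; if fewer than 4 survive
the full traversal the survivors are returned with a warning. Ties in S
break on higher F, then feature name — an arbitrary but fixed rule, needed
for reproducibility. With N = 82 and at most 7 features, N/p ≥ 11.7, above
the 10-samples-per-feature floor the 4–7 window is designed around.

**Selection scope.** The default re-runs selection inside every training
fold (`per_fold`), so held-out subjects never influence the feature set —
the leakage-safe protocol. `global` mode selects once on all rows
(single-pass, optimistically biased); both are logged, and the globally
selected set is always reported for interpretation.

## Cross-validation and SMOTE

5-fold stratified CV, optionally repeated over shuffle seeds
(`repeat_seeds`, default 5 repetitions to stabilize the per-subject
probability estimates). Within each training fold only: per-fold selection,
then SMOTE upsampling of the minority class to parity — synthetic point
`x + λ(x_nn − x)`, λ ~ U(0,1), x_nn among the `k = min(3, minority − 1)`
nearest minority neighbors (the cap of 3 follows the protocol; the −1
corrects the off-by-one when the minority is tiny, since a point cannot be
its own neighbor) — then grid search maximizing mean F1. `strict` mode tunes
on an inner 3-fold split of the balanced training data (nested); `paper`
mode tunes on the outer folds themselves (non-nested, the simpler protocol);
neither is asserted as the original analysis's choice, which is not pinned.
Hyperparameter grids are small published-default repository grids (KNN
neighbors {3,5,7,9}; RF/ET trees {200,500} × depth {∞,5,10}; SVM-RBF
C {0.1,1,10}; LR C {0.1,1,10}; DT depth {∞,3,5}; Gaussian NB defaults).
KNN/SVM/LR see train-fold-standardized features; tree models and NB see raw
features. Metrics: accuracy, precision (0 when nothing is predicted
positive), recall, F1, rank-based ROC-AUC and step-integrated AUPR;
single-class test folds report AUC/AUPR as missing rather than 0. Reports
give mean ± SD across folds per classifier and mean ± SD across classifiers
pooled.

## Interpretation and the reserve report

Attribution is pluggable; the default backend is permutation importance
(mean F1 drop over 20 permutations) computed per classifier on the
selected-feature table. Only the ranking is consumed: per model the top-5
features by |importance| (ties by name), then counts of each feature family
(DTW / LSTM / Statistical) across models. Clinical correlations are
exploratory Spearman ρ with pairwise deletion of missing values, the n used
reported, and no multiplicity correction by default (a Benjamini–Hochberg
column is available by flag).

The reserve report restricts to sarcopenia subjects, averages each subject's
out-of-fold `P(Y=1)` over classifiers and repeats, and reports range,
mean ± population SD, and `CV% = 100·SD/mean`. Averaging over classifiers
(rather than reporting per-classifier distributions) is the default because
the reserve construct is a property of the subject, not of a model; the
per-classifier breakdown remains in the evaluation report. The report
annotates subjects beyond the cohort-derived cutoffs (> 0.7 depleted,
< 0.5 high reserve) and labels these as unvalidated.

## Synthetic cohort generator

The generator exists so the pipeline is testable without clinical data. It
emulates exactly the signatures the features target:

* **Controls**: stationary AR(2) sway — poles at radius 0.98 and resonance
  0.5 Hz (inside the 0.3–1 Hz quiet-stance band), innovation variance set in
  closed form so the stationary SD is `sway_sd_mm` (default 2 mm). AR(2) was
  chosen over richer models because it is the simplest stationary process
  with a tunable low-frequency resonance and an analytic variance.
* **Patients**: the same process degraded by three terms, each scaled by
  severity `1 − reserve`: a linear drift (`drift_per_sample`, default
  0.003 mm/sample — 6 mm over a 20 s trial at full severity, a few times the
  sway SD), a delayed read of the sway process (`delay_samples`, default 20
  ≙ 200 ms corrective lag), and a dispersion multiplier
  (`sway_scale`, default 1.5). Reserve enters multiplicatively so that
  `reserve = 1` is an *exact* null: the patient generator consumes the
  random stream identically to a control and produces bit-identical output
  for the same seed — this is what makes the null-AUC acceptance test sharp.
* **Postures** differ in baseline sway (FT 1.0, FA 0.8, ST 1.3 — narrower
  base, more sway) and in pathology gain (FT 0.5, FA 0.7, ST 1.0):
  easy stances let patients compensate, semi-tandem expresses the full
  deficit. This mirrors the clinical rationale for testing in semi-tandem.
* **Subjects** get a baseline sway amplitude jitter of ±20% (inter-individual
  variability), and clinical indicators drawn around published healthy
  means, moving monotonically toward sarcopenic means with severity —
  decreasing for ASMI/grip/6MW speed, increasing for chair-stand time — so
  correlation tests have a known sign. The true reserve is recorded in the
  metadata (`reserve_true`) for validation.

What it does **not** emulate: inverted-pendulum biomechanics, interleaved
M/L–A/P coordination structure, nonstationary anxiety or fatigue effects,
comorbidity confounds, or realistic cross-channel correlation (channels are
independent AR processes). Passing tests therefore demonstrate that the
pipeline recovers the *statistical* signatures it claims to measure — drift,
misalignment, dispersion, and their graded mixture — not that it would reach
any particular accuracy on clinical recordings.

## Numerical and engineering choices

* DTW and the LSTM recursion are numba-compiled; the banded DP touches at
  most `2w + 1` cells per row.
* Data CSVs are written at 17 significant digits and read back with
  round-trip float parsing, so write→read is bit-exact; report JSONs round
  to 12 significant digits.
* Every stochastic step takes an explicit seed (simulation, forest, SMOTE,
  fold shuffling, permutation importance); identical seeds give bit-identical
  outputs, which the suite asserts at pipeline level (byte-identical JSON
  reports across reruns).
* Degenerate inputs are either guarded (constant series in Z-score/CV/Grubbs)
  or hard errors naming the offending record (missing channels, ragged
  lengths, non-contiguous sample indices, infeasible DTW bands, single-class
  labels, minority class of one).

## Problem sizes used by the test suite and acceptance script

Simulation-backed checks run at reduced geometry chosen to keep the full
suite in a few minutes on one CPU while leaving the tested effects
identifiable: the null/strong-effect classification checks use the full
82-subject split at T = 400 with one trial per subject and a three-model
classifier subset (LR, KNN, NB) with fixed hyperparameters; slope-recovery
checks use T = 1500; micro-example and oracle checks are instantaneous. The
acceptance script runs the full recording geometry (82 subjects × 3 trials
× 6 channels × 2000 samples, semi-tandem) through extraction and selection.
Slope-recovery tolerances use the empirical Monte-Carlo standard error of
the fitted slopes (SD/√n over replicate channels) rather than the OLS
formula SE, which is anti-conservative under autocorrelated AR(2) noise.

## Known limitations

* The attribution backend is permutation importance, not Shapley values;
  only rank/frequency summaries should be compared across models.
* The global-template default carries the small control self-reference bias
  described above; use `template_scope="per_fold"` for unbiased evaluation
  on small cohorts.
* `paper`-mode tuning is non-nested and optimistically biased by design;
  use `strict` mode when reporting performance.
* The simulator's channels are mutually independent, so cross-channel
  coordination features (not currently extracted) cannot be validated
  against it.
* Reserve stratification cutoffs (0.5 / 0.7 on `P(Y=1)`) are cohort-derived
  annotations, not validated clinical thresholds.
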