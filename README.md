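# copreserve

Multidimensional temporal analysis of center-of-pressure (COP) signals for
sarcopenia screening and **compensatory-reserve** profiling.

## The problem

Sarcopenia — age-related loss of skeletal muscle mass and function — often
escapes standing-balance screening because patients compensate: neuromuscular
adjustments mask deficits in easy stances. A force platform records the COP
trajectory during quiet standing (six channels: left foot, right foot and
overall center, each in the mediolateral *X* and anteroposterior *Y*
directions, 100 Hz, 20 s, three trials per posture, in feet-together FT,
feet-apart FA and semi-tandem ST stances). Conventional kinematic summaries
(sway amplitude, velocity) collapse these trajectories to scalars and lose
the temporal structure where compensation shows.

`copreserve` implements a template-referenced temporal pipeline for this
setting, aimed at movement-analysis researchers working with posturographic
cohorts. Because clinical COP recordings are rarely shareable, the package
includes a first-class synthetic cohort generator that reproduces the
statistical signatures the features target, so every stage is testable end
to end.

## The method

Per subject and posture, a 36-dimensional feature vector is extracted from
the preprocessed six-channel recording (outlier replacement at ±3 SD,
translation to the origin, Z-score):

* **6 DTW deviations.** Banded dynamic time warping between each
  standardized channel and a *healthy template* — the pointwise median curve
  of all control subjects (Grubbs-screened at α = 0.05). The pointwise cost
  is `C_γ(a, b) = |a − b|^γ` with γ ∈ {0.5, 1.0, 1.5, 2.0} (default 1.5),
  accumulated by the standard DTW recurrence
  `D(i,j) = C_γ + min(D(i−1,j), D(i,j−1), D(i−1,j−1))`, `D(0,0) = 0`, under a
  Sakoe–Chiba band `|i − j| ≤ 0.1·max(m,n)`.
* **12 LSTM embedding values.** The final hidden state `h_T` of an untrained
  2-unit LSTM with weights drawn once from a seeded uniform(−0.5, 0.5)
  initializer (seed 42, zero biases) and shared across channels — a
  deterministic sequential-pattern transformer, not a trained model.
* **18 statistical descriptors.** Per channel: coefficient of variation
  `CV = σ/μ`, OLS linear trend slope `α` against `t = 1…T` (directional
  drift), and interquartile range `IQR = Q3 − Q1` (sudden instability).

Features are then ranked by the composite score
`S(i) = f(i)/max(f) + p(i)/max(p)` (ANOVA-F plus random-forest importance,
equal weights) and pruned greedily: a candidate is dropped if
`|Spearman ρ| ≥ 0.7` with any higher-ranked kept feature, stopping at 7 kept
features (4–7 keeps subjects-per-feature ≥ 10 at N ≈ 82). Classification
uses 5-fold stratified cross-validation with SMOTE balancing of each
training fold (`k = min(3, minority − 1)` neighbors) and seven classifier
families (KNN, RF, ET, SVM, DT, NB, LR) tuned by grid search for mean F1.

The out-of-fold predicted probability `P(Y=1)` (Y = 1: sarcopenia) is the
reserve readout: low values mean COP dynamics near the healthy template
(effective compensation, high reserve), high values mean marked deviation
(depleted reserve). Per posture the package reports the intra-patient
`P(Y=1)` distribution — range, mean ± SD and CV% — plus attribution
frequencies per feature family and Spearman correlations between selected
features and clinical indicators (ASMI, grip strength, 5-time chair-stand,
6-minute-walk speed).

## Worked example

```python
from copreserve import PipelineConfig, SimProfile, run_pipeline, simulate_cohort
from copreserve.classify import CvConfig
from copreserve.select import SelectionConfig

cohort = simulate_cohort(SimProfile(
    n_controls=20, n_patients=20, postures=("ST",), trials_per_posture=3,
    T=500, reserve="uniform", seed=7,
))
config = PipelineConfig(
    cv=CvConfig(classifiers=("KNN", "RF", "SVM", "LR"), repeat_seeds=(0,),
                grids={"KNN": [{"n_neighbors": 5}], "RF": [{"n_estimators": 200}],
                       "SVM": [{"C": 1.0}], "LR": [{"C": 1.0}]}),
    selection=SelectionConfig(rf_trees=200),
)
result = run_pipeline(cohort, config)
pr = result.per_posture["ST"]
```

prints (via the report objects):

```
selected: ['iqr_COP-LX', 'iqr_COP-RX', 'iqr_COP-RY', 'iqr_COP-CX', 'iqr_COP-CY', 'DTW-COP-RX', 'cv_COP-CY']
KNN: acc 0.75+/-0.16  AUC 0.81+/-0.11
RF:  acc 0.78+/-0.12  AUC 0.88+/-0.10
SVM: acc 0.75+/-0.14  AUC 0.89+/-0.09
LR:  acc 0.82+/-0.10  AUC 0.88+/-0.11
pooled: acc 0.77+/-0.03  AUC 0.86+/-0.03
reserve: range (0.10, 0.98)  mean 0.68 +/- 0.27  CV 39.1%
type freq: {'DTW': 3, 'LSTM': 0, 'Statistical': 12}
```

Reading this: the hybrid filter kept 7 of 36 features (dispersion features
dominate because this synthetic cohort's patients were generated with
inflated sway and drift); the four classifiers separate patients from
controls at pooled ROC-AUC 0.86; and the patients — simulated with reserve
drawn uniformly in [0, 1] — show a wide out-of-fold `P(Y=1)` spread
(CV 39%), which is exactly the intra-group reserve gradient the method is
built to expose. Mean ± SD per classifier is across CV folds; the pooled row
is mean ± SD across classifiers.

A shell workflow is available too:

```bash
copreserve simulate --controls 40 --patients 42 --seed 0 --out data/
copreserve run --simulate --seed 0 --out run/
copreserve gamma-sweep --data data/cop_data.csv --meta data/meta.json --out sweep.csv
```

## Layout

| module | role |
| --- | --- |
| `copreserve.core` | domain types (`CopTrial`, `Cohort`), long-CSV + JSON I/O |
| `copreserve.simulate` | synthetic cohorts: AR(2) sway, severity-graded drift/delay/dispersion |
| `copreserve.preprocess` | ±3 SD outlier replacement, origin translation, Z-score |
| `copreserve.template` | Grubbs-screened pointwise-median healthy templates |
| `copreserve.features` | banded DTW, fixed-weight LSTM embeddings, CV/slope/IQR |
| `copreserve.select` | composite ANOVA-F + forest-importance scoring, Spearman pruning |
| `copreserve.classify` | SMOTE, stratified CV, seven classifiers, metrics |
| `copreserve.interpret` | attribution frequencies, clinical correlations, reserve report |
| `copreserve.pipeline` / `cli` | orchestration, manifests, `copreserve` command |

See `docs/methods.md` for modeling assumptions, parameter choices and known
limitations.
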