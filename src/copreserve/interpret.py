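"""Model interpretation and the compensatory-reserve variability report.

Three post-hoc analyses:

* attribution aggregation — per classifier, rank features by importance and
  count how often each feature family (DTW / LSTM / Statistical) appears in
  the top-5 lists across models.  The backend is pluggable; the default is
  permutation importance, which is model-agnostic and rank-based, matching
  the analysis's focus on rankings rather than absolute attribution values;
* clinical correlations — exploratory Spearman rho between each feature and
  each clinical indicator (ASMI, grip, 5TCS, 6MW, ...), pairwise-deleting
  missing values, with optional Benjamini-Hochberg correction;
* reserve report — the distribution of out-of-fold P(Y=1) over sarcopenia
  subjects (range, mean +/- SD, CV%).  Lower P(Y=1) means COP dynamics closer
  to the healthy template, i.e. greater compensatory reserve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.inspection import permutation_importance

from .classify import EvalReport, _make_estimator, smote_balance
from .core import Cohort
from .features import feature_type

logger = logging.getLogger(__name__)

#: Cohort-derived stratification cutoffs on P(Y=1); flagged, not validated.
RESERVE_DEPLETED_CUTOFF = 0.7
RESERVE_HIGH_CUTOFF = 0.5


@dataclass
class AttributionSummary:
    per_model_top5: Dict[str, List[str]]
    type_frequency: Dict[str, int]  # {"DTW": n, "LSTM": n, "Statistical": n}


def top5_type_frequency(attributions: Mapping[str, pd.Series], top_k: int = 5) -> AttributionSummary:
    """Count feature-family appearances in each model's top-k importance list.

    ``attributions`` maps classifier name to a per-feature importance vector
    (any scale; only the within-model ranking matters).  Ties break on
    feature name so the output is run-to-run stable.
    """
    per_model: Dict[str, List[str]] = {}
    freq = {"DTW": 0, "LSTM": 0, "Statistical": 0}
    for model, imp in attributions.items():
        if len(imp) < top_k:
            logger.warning("model %s has only %d features; using all of them", model, len(imp))
        ranked = sorted(imp.index, key=lambda name: (-abs(imp[name]), name))
        top = ranked[: min(top_k, len(ranked))]
        per_model[model] = top
        for name in top:
            freq[feature_type(name)] += 1
    return AttributionSummary(per_model_top5=per_model, type_frequency=freq)


def compute_attributions(
    features: pd.DataFrame,
    labels: Sequence[int],
    classifiers: Sequence[str],
    seed: int = 0,
    n_repeats: int = 20,
    smote_k_cap: int = 3,
) -> Dict[str, pd.Series]:
    """Permutation-importance vectors, one per classifier.

    Each model is fit on the full (SMOTE-balanced) selected-feature table with
    its default hyperparameters; importance is the mean F1 drop when a column
    is permuted.  This is the interpretation stage, not the evaluation stage,
    so fitting on all rows is deliberate.
    """
    y = np.asarray(labels, dtype=int)
    X = features.to_numpy(dtype=float)
    Xb, yb = smote_balance(X, y, seed=seed, k_cap=smote_k_cap)
    out: Dict[str, pd.Series] = {}
    for i, name in enumerate(classifiers):
        est = _make_estimator(name, {}, seed=seed + i)
        est.fit(Xb, yb)
        res = permutation_importance(
            est, X, y, scoring="f1", n_repeats=n_repeats, random_state=seed + i
        )
        out[name] = pd.Series(res.importances_mean, index=features.columns)
    return out


def clinical_correlations(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    *,
    bh_correct: bool = False,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Spearman rho between every feature and every clinical indicator.

    Rows of ``features`` and ``clinical`` align on subject id; missing
    clinical values are dropped pairwise and the n actually used is reported.
    Returns a frame with columns (feature, indicator, rho, p, n).
    """
    common = features.index.intersection(clinical.index)
    rows = []
    for feat in features.columns:
        for ind in clinical.columns:
            x = features.loc[common, feat].astype(float)
            z = pd.to_numeric(clinical.loc[common, ind], errors="coerce")
            ok = x.notna() & z.notna()
            n = int(ok.sum())
            if n < min_pairs:
                logger.info("skipping %s vs %s: only %d complete pair(s)", feat, ind, n)
                continue
            rho, p = spearmanr(x[ok], z[ok])
            rows.append(dict(feature=feat, indicator=ind, rho=float(rho), p=float(p), n=n))
    df = pd.DataFrame(rows, columns=["feature", "indicator", "rho", "p", "n"])
    if bh_correct and len(df):
        df["p_adj"] = _benjamini_hochberg(df["p"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj


@dataclass
class ReserveReport:
    """Intra-group P(Y=1) variability among sarcopenia subjects, one posture."""

    posture: str
    probabilities: Dict[str, float]  # subject -> mean out-of-fold P(Y=1)
    range: Tuple[float, float]
    mean: float
    sd: float
    cv_percent: float
    annotations: Dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "posture": self.posture,
            "range": list(self.range),
            "mean": self.mean,
            "sd": self.sd,
            "cv_percent": self.cv_percent,
            "probabilities": self.probabilities,
            "annotations": self.annotations,
        }


def reserve_report(
    eval_report: EvalReport,
    cohort: Cohort,
    posture: str,
    *,
    include_controls: bool = False,
) -> ReserveReport:
    """Summarize the out-of-fold P(Y=1) distribution over sarcopenia subjects.

    Each subject's probability is averaged over classifiers and CV repeats;
    SD is the population SD and CV% = 100 * SD / mean.  ``include_controls``
    switches to the all-subject distribution.
    """
    ids = cohort.patient_ids() if not include_controls else [s.subject_id for s in cohort.subjects]
    if not ids:
        raise ValueError("no sarcopenia subjects in cohort")
    probs = {sid: eval_report.mean_oof_probability(sid) for sid in sorted(ids)}
    vals = np.array(list(probs.values()))
    mean = float(vals.mean())
    sd = float(vals.std())  # population SD
    cv = 100.0 * sd / mean if mean > 0 else 0.0
    annotations = {
        "depleted_reserve": (
            f"P(Y=1) > {RESERVE_DEPLETED_CUTOFF}: "
            + ", ".join(s for s, p in probs.items() if p > RESERVE_DEPLETED_CUTOFF)
        ),
        "high_reserve": (
            f"P(Y=1) < {RESERVE_HIGH_CUTOFF}: "
            + ", ".join(s for s, p in probs.items() if p < RESERVE_HIGH_CUTOFF)
        ),
        "note": "cutoffs are cohort-derived, not clinically validated",
    }
    return ReserveReport(
        posture=posture,
        probabilities=probs,
        range=(float(vals.min()), float(vals.max())),
        mean=mean,
        sd=sd,
        cv_percent=float(cv),
        annotations=annotations,
    )
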