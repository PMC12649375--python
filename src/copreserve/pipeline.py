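"""End-to-end orchestration: preprocess -> template -> features -> select ->
classify -> interpret, posture by posture, with a reproducibility manifest.

Postures are processed independently end to end (templates and metrics are
posture-specific); there is no cross-posture feature pooling.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .classify import EvalReport, run_cv
from .config import PipelineConfig
from .core import Cohort, fmt12
from .features import GAMMA_GRID, DtwParams, extract_cohort_features
from .interpret import (
    clinical_correlations,
    compute_attributions,
    reserve_report,
    top5_type_frequency,
)
from .preprocess import preprocess_cohort
from .select import select_features
from .template import build_template

logger = logging.getLogger(__name__)

#: Models the attribution stage inspects (the high-performing families).
ATTRIBUTION_MODELS = ("KNN", "RF", "ET", "SVM")


@dataclass
class PostureResult:
    posture: str
    features: pd.DataFrame
    selection: Any
    eval_report: EvalReport
    attribution: Any
    correlations: pd.DataFrame
    reserve: Any
    template_flags: int


@dataclass
class PipelineResult:
    per_posture: Dict[str, PostureResult]
    manifest: Dict[str, Any]


def _round_floats(obj):
    if isinstance(obj, float):
        return fmt12(obj)
    if isinstance(obj, (np.floating,)):
        return fmt12(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def _write_json(path: Path, obj) -> str:
    path.write_text(json.dumps(_round_floats(obj), indent=1, sort_keys=True))
    return hashlib.md5(path.read_bytes()).hexdigest()


def _fold_feature_builder(cohort, posture, preprocessed, config):
    """Feature tables against templates built only from training-fold controls."""
    cache: Dict[frozenset, pd.DataFrame] = {}

    def build(train_subjects: List[str]) -> pd.DataFrame:
        key = frozenset(train_subjects)
        if key not in cache:
            template = build_template(
                cohort, posture, preprocessed=preprocessed,
                trial_aggregation=config.trial_aggregation,
                control_subset=train_subjects,
            )
            feats = extract_cohort_features(
                cohort, posture, template, preprocessed=preprocessed,
                dtw_params=config.dtw, lstm_spec=config.lstm, stats_on=config.stats_on,
            )
            cache[key] = feats.drop(columns=["label"])
        return cache[key]

    return build


def run_pipeline(
    cohort: Cohort,
    config: PipelineConfig = PipelineConfig(),
    out_dir: Optional[Path] = None,
    attribution_seed: int = 0,
) -> PipelineResult:
    """Run every stage on every posture present in the cohort.

    Returns in-memory results; if ``out_dir`` is given, also writes
    ``features_<posture>.csv``, ``report.json``, ``interpret.json`` and
    ``manifest.json`` (floats at 12 significant digits).
    """
    preprocessed = preprocess_cohort(cohort)
    clinical = pd.DataFrame(
        {s.subject_id: s.clinical for s in cohort.subjects}
    ).T.apply(pd.to_numeric, errors="coerce")

    per_posture: Dict[str, PostureResult] = {}
    for posture in cohort.postures:
        logger.info("pipeline: posture %s", posture)
        template = build_template(
            cohort, posture, preprocessed=preprocessed,
            trial_aggregation=config.trial_aggregation,
        )
        feats = extract_cohort_features(
            cohort, posture, template,
            preprocessed=preprocessed,
            dtw_params=config.dtw,
            lstm_spec=config.lstm,
            stats_on=config.stats_on,
            trial_aggregation="mean",  # classification operates on subject rows
        )
        X = feats.drop(columns=["label"])
        y = feats["label"].to_numpy(dtype=int)
        sel = select_features(X, y, config.selection)
        feature_builder = None
        if config.template_scope == "per_fold":
            feature_builder = _fold_feature_builder(cohort, posture, preprocessed, config)
        report = run_cv(X, y, config.cv, selection=config.selection,
                        selection_scope=config.selection_scope,
                        feature_builder=feature_builder)
        attr_models = [c for c in ATTRIBUTION_MODELS if c in config.cv.classifiers] or list(
            config.cv.classifiers
        )
        attributions = compute_attributions(
            X[sel.selected], y, attr_models, seed=attribution_seed,
            smote_k_cap=config.cv.smote_k_cap,
        )
        summary = top5_type_frequency(attributions)
        corr = clinical_correlations(X[sel.selected], clinical)
        reserve = reserve_report(report, cohort, posture)
        per_posture[posture] = PostureResult(
            posture=posture,
            features=feats,
            selection=sel,
            eval_report=report,
            attribution=summary,
            correlations=corr,
            reserve=reserve,
            template_flags=template.grubbs_flags,
        )

    manifest: Dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "attribution_seed": attribution_seed,
        "postures": list(per_posture),
        "n_subjects": len(cohort.subjects),
        "checksums": {},
    }
    result = PipelineResult(per_posture=per_posture, manifest=manifest)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    checks = result.manifest["checksums"]
    report_obj: Dict[str, Any] = {}
    interp_obj: Dict[str, Any] = {}
    for posture, pr in result.per_posture.items():
        fpath = out_dir / f"features_{posture}.csv"
        pr.features.to_csv(fpath, float_format="%.12g")
        checks[fpath.name] = hashlib.md5(fpath.read_bytes()).hexdigest()
        report_obj[posture] = {
            "per_classifier": pr.eval_report.per_classifier,
            "pooled": pr.eval_report.pooled,
            "selected_global": pr.selection.selected,
            "template_grubbs_flags": pr.template_flags,
        }
        interp_obj[posture] = {
            "attribution_top5": pr.attribution.per_model_top5,
            "type_frequency": pr.attribution.type_frequency,
            "clinical_correlations": pr.correlations.to_dict(orient="records"),
            "reserve": pr.reserve.as_dict(),
        }
    checks["report.json"] = _write_json(out_dir / "report.json", report_obj)
    checks["interpret.json"] = _write_json(out_dir / "interpret.json", interp_obj)
    _write_json(out_dir / "manifest.json", result.manifest)


def gamma_sweep(
    cohort: Cohort,
    config: PipelineConfig = PipelineConfig(),
    gammas=GAMMA_GRID,
) -> pd.DataFrame:
    """Mean F1 / ROC-AUC (pooled over classifiers and postures) per DTW gamma.

    Returns a frame indexed by gamma with a ``best`` marker on the row
    maximizing mean F1 (ties broken by ROC-AUC).
    """
    preprocessed = preprocess_cohort(cohort)
    rows = []
    for gamma in gammas:
        dtw = DtwParams(gamma=gamma, band_fraction=config.dtw.band_fraction)
        f1s, aucs = [], []
        for posture in cohort.postures:
            template = build_template(cohort, posture, preprocessed=preprocessed,
                                      trial_aggregation=config.trial_aggregation)
            feats = extract_cohort_features(
                cohort, posture, template, preprocessed=preprocessed,
                dtw_params=dtw, lstm_spec=config.lstm, stats_on=config.stats_on,
            )
            X = feats.drop(columns=["label"])
            y = feats["label"].to_numpy(dtype=int)
            report = run_cv(X, y, config.cv, selection=config.selection,
                            selection_scope=config.selection_scope)
            f1s.append(report.pooled["f1"][0])
            aucs.append(report.pooled["roc_auc"][0])
        rows.append(dict(gamma=gamma, mean_f1=float(np.mean(f1s)), mean_roc_auc=float(np.mean(aucs))))
    df = pd.DataFrame(rows).set_index("gamma")
    best = df.sort_values(["mean_f1", "mean_roc_auc"], ascending=False).index[0]
    df["best"] = df.index == best
    return df
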