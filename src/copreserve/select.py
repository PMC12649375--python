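"""Hybrid filter feature selection.

Each feature i gets a composite score

    S(i) = f(i)/max(f) + p(i)/max(p)

where f is the one-way ANOVA F statistic against the binary label and p the
mean-decrease-in-impurity importance from a seeded random forest fit on all
features (equal 1:1 weighting, S in [0, 2]).  Candidates are then traversed
in descending S and dropped whenever |Spearman rho| >= 0.7 with any
already-kept feature, stopping at 7 kept features; 4-7 survivors keep the
samples-per-feature ratio N/p >= 10 for cohorts around N = 82.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    rho_threshold: float = 0.7
    min_keep: int = 4
    max_keep: int = 7
    np_ratio: float = 10.0
    rf_trees: int = 500
    rf_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rho_threshold <= 1:
            raise ValueError("rho_threshold must be in (0, 1]")
        if self.min_keep > self.max_keep:
            raise ValueError("min_keep must be <= max_keep")


@dataclass
class SelectionResult:
    scores: pd.DataFrame          # columns f, p, S indexed by feature
    ranked: List[str]             # all features in descending S
    selected: List[str]           # surviving features, in rank order
    pruned: Dict[str, str]        # removed feature -> blocking higher-ranked feature


def combine_scores(f: np.ndarray, p: np.ndarray) -> np.ndarray:
    """S = f/max(f) + p/max(p), the equal-weight composite of the two ranks."""
    f = np.asarray(f, dtype=float)
    p = np.asarray(p, dtype=float)
    fmax = f.max() if f.max() > 0 else 1.0
    pmax = p.max() if p.max() > 0 else 1.0
    return f / fmax + p / pmax


def composite_scores(
    features: pd.DataFrame,
    labels: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
) -> pd.DataFrame:
    """ANOVA-F, forest importance and composite score per feature.

    ``features`` is a subjects x p numeric frame; ``labels`` a binary vector.
    """
    y = np.asarray(labels)
    if features.shape[1] < 1:
        raise ValueError("at least one feature required")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to score features")
    X = features.to_numpy(dtype=float)
    f_stat, _ = f_classif(X, y)
    f_stat = np.nan_to_num(f_stat, nan=0.0)  # constant features get F = 0
    forest = RandomForestClassifier(
        n_estimators=config.rf_trees, random_state=config.rf_seed, n_jobs=1
    ).fit(X, y)
    imp = forest.feature_importances_
    return pd.DataFrame(
        {"f": f_stat, "p": imp, "S": combine_scores(f_stat, imp)}, index=features.columns
    )


def correlation_prune(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    config: SelectionConfig = SelectionConfig(),
    n_samples: Optional[int] = None,
) -> SelectionResult:
    """Greedy redundancy pruning in descending composite-score order.

    Ties in S break on higher F then lexicographic name, so the ranking is
    deterministic given the forest seed.
    """
    if features.shape[1] == 0:
        raise ValueError("empty feature set")
    order = sorted(
        scores.index,
        key=lambda name: (-scores.at[name, "S"], -scores.at[name, "f"], name),
    )
    selected: List[str] = []
    pruned: Dict[str, str] = {}
    for name in order:
        if len(selected) >= config.max_keep:
            break
        blocker = None
        for kept in selected:
            rho = spearmanr(features[name], features[kept]).statistic
            if np.isnan(rho):
                rho = 0.0
            if abs(rho) >= config.rho_threshold:
                blocker = kept
                break
        if blocker is None:
            selected.append(name)
        else:
            pruned[name] = blocker
    if len(selected) < config.min_keep:
        logger.warning(
            "only %d feature(s) survived correlation pruning (minimum target %d)",
            len(selected), config.min_keep,
        )
    n = n_samples if n_samples is not None else features.shape[0]
    if selected and n / len(selected) < config.np_ratio:
        logger.warning(
            "samples-per-feature ratio %.1f below the %.0f floor (N=%d, p=%d)",
            n / len(selected), config.np_ratio, n, len(selected),
        )
    return SelectionResult(scores=scores, ranked=order, selected=selected, pruned=pruned)


def select_features(
    features: pd.DataFrame,
    labels: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
) -> SelectionResult:
    """Convenience wrapper: composite scoring followed by correlation pruning."""
    scores = composite_scores(features, labels, config)
    return correlation_prune(features, scores, config, n_samples=features.shape[0])
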