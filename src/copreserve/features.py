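"""The 36-dimensional multidimensional temporal feature vector.

Per subject x posture the vector concatenates, over the six COP channels:

* 6 DTW deviations — banded dynamic-time-warping distance between the
  standardized channel and the healthy template, pointwise cost
  ``|a - b| ** gamma`` (gamma grid {0.5, 1.0, 1.5, 2.0}, default 1.5) under a
  Sakoe-Chiba band of half-width 10% of the longer sequence;
* 12 LSTM embedding values — the final hidden state of an untrained 2-unit
  LSTM with weights drawn once from a seeded uniform(-0.5, 0.5) initializer
  (seed 42, zero biases) and shared across channels, applied to the
  standardized series;
* 18 statistical descriptors — coefficient of variation sigma/mu, OLS linear
  trend slope against t = 1..T, and interquartile range, computed on the
  translated (pre-Z-score) series by default because sigma/mu degenerates on
  standardized data.

Everything here is deterministic given the LSTM seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .core import CHANNELS, Cohort
from .preprocess import PreprocessedTrial, preprocess_cohort
from .template import HealthyTemplate

logger = logging.getLogger(__name__)

#: Cost-exponent grid explored by the gamma sweep.
GAMMA_GRID = (0.5, 1.0, 1.5, 2.0)


@dataclass(frozen=True)
class DtwParams:
    """Banded DTW parameters: cost exponent and band width fraction."""

    gamma: float = 1.5
    band_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if not 0 < self.band_fraction <= 1:
            raise ValueError("band_fraction must be in (0, 1]")

    def band_halfwidth(self, n: int, m: int) -> int:
        """w = max(1, ceil(band_fraction * max(m, n))): 10% geometry at full
        length while keeping short test sequences feasible."""
        return max(1, math.ceil(self.band_fraction * max(m, n)))


@dataclass(frozen=True)
class LstmSpec:
    """Fixed-weight LSTM embedding specification (2 units, global seed 42)."""

    units: int = 2
    seed: int = 42

    def __post_init__(self) -> None:
        if self.units < 1:
            raise ValueError("units must be >= 1")


def dtw_distance(sample: np.ndarray, template: np.ndarray, params: DtwParams = DtwParams()) -> float:
    """Banded DTW distance: cumulative |a-b|**gamma cost of the optimal path."""
    s1 = np.ascontiguousarray(sample, dtype=float)
    s2 = np.ascontiguousarray(template, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("DTW requires non-empty series")
    if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))):
        raise ValueError("DTW requires finite series")
    n, m = s1.size, s2.size
    w = params.band_halfwidth(n, m)
    if abs(n - m) > w:
        raise ValueError(
            f"band half-width {w} cannot connect endpoints: |n - m| = {abs(n - m)} "
            f"(n={n}, m={m}, band_fraction={params.band_fraction})"
        )
    d = float(_kernels.dtw_banded(s1, s2, float(params.gamma), int(w)))
    if not np.isfinite(d):
        raise RuntimeError("banded DTW produced no feasible path")  # unreachable for |n-m| <= w
    return d


@lru_cache(maxsize=8)
def lstm_weights(spec: LstmSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Input and recurrent weight stacks, drawn once per (units, seed).

    Gate order (input, forget, candidate, output); uniform(-0.5, 0.5); the
    same weights are shared by all six channels.
    """
    rng = np.random.default_rng(spec.seed)
    wx = rng.uniform(-0.5, 0.5, size=(4, spec.units))
    wh = rng.uniform(-0.5, 0.5, size=(4, spec.units, spec.units))
    wx.setflags(write=False)
    wh.setflags(write=False)
    return wx, wh


def lstm_embedding(series: np.ndarray, spec: LstmSpec = LstmSpec()) -> np.ndarray:
    """Final hidden state h_T of the fixed-weight LSTM run over the series."""
    x = np.ascontiguousarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("LSTM embedding requires a non-empty series")
    wx, wh = lstm_weights(spec)
    return np.asarray(_kernels.lstm_forward(x, wx, wh))


def statistical_features(series: np.ndarray) -> Tuple[float, float, float]:
    """(cv, slope, iqr) of one channel.

    cv = sigma/mu with population sigma; if |mu| < 1e-8 the ratio is
    regularized to sigma/(|mu| + 1e-8) with a warning.  slope is the OLS
    trend against t = 1..T; iqr uses linear-interpolation quantiles.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("statistical features require length >= 2")
    mu = x.mean()
    sigma = x.std()
    if abs(mu) < 1e-8:
        if sigma > 0:
            logger.warning("near-zero mean (%g): coefficient of variation regularized", mu)
        cv = sigma / (abs(mu) + 1e-8)
    else:
        cv = sigma / mu
    t = np.arange(1, x.size + 1, dtype=float)
    tc = t - t.mean()
    slope = float(tc @ (x - mu) / (tc @ tc))
    q1, q3 = np.percentile(x, [25.0, 75.0])
    return float(cv), slope, float(q3 - q1)


def feature_names() -> List[str]:
    """The 36 canonical feature names, in fixed order."""
    names = [f"DTW-{ch}" for ch in CHANNELS]
    for ch in CHANNELS:
        names += [f"LSTM-{ch}-1", f"LSTM-{ch}-2"]
    names += [f"cv_{ch}" for ch in CHANNELS]
    names += [f"slope_{ch}" for ch in CHANNELS]
    names += [f"iqr_{ch}" for ch in CHANNELS]
    return names


def feature_type(name: str) -> str:
    """Map a feature name to its family: DTW, LSTM or Statistical."""
    if name.startswith("DTW-"):
        return "DTW"
    if name.startswith("LSTM-"):
        return "LSTM"
    return "Statistical"


@dataclass
class FeatureVector:
    """Named 36-dimensional feature vector for one subject x posture."""

    subject_id: str
    posture: str
    values: Dict[str, float]

    def __post_init__(self) -> None:
        expected = feature_names()
        if list(self.values.keys()) != expected:
            raise ValueError("feature vector must contain exactly the 36 canonical features in order")
        arr = np.array(list(self.values.values()))
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature vector contains non-finite entries")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()))


def extract_features(
    trial: PreprocessedTrial,
    template: HealthyTemplate,
    *,
    dtw_params: DtwParams = DtwParams(),
    lstm_spec: LstmSpec = LstmSpec(),
    stats_on: str = "translated",
) -> FeatureVector:
    """36 named features for a single preprocessed trial."""
    if trial.posture != template.posture:
        raise ValueError(
            f"posture mismatch: trial is {trial.posture}, template is {template.posture}"
        )
    if trial.n_samples != template.n_samples:
        raise ValueError(
            f"length mismatch: trial has {trial.n_samples} samples, template {template.n_samples}"
        )
    if stats_on not in ("translated", "standardized"):
        raise ValueError(f"stats_on must be 'translated' or 'standardized', got {stats_on!r}")
    values: Dict[str, float] = {}
    for ch in CHANNELS:
        values[f"DTW-{ch}"] = dtw_distance(trial.standardized[ch], template.curves[ch], dtw_params)
    for ch in CHANNELS:
        emb = lstm_embedding(trial.standardized[ch], lstm_spec)
        for k in range(lstm_spec.units):
            values[f"LSTM-{ch}-{k + 1}"] = float(emb[k])
    stats_series = trial.translated if stats_on == "translated" else trial.standardized
    cvs, slopes, iqrs = {}, {}, {}
    for ch in CHANNELS:
        cvs[ch], slopes[ch], iqrs[ch] = statistical_features(stats_series[ch])
    for ch in CHANNELS:
        values[f"cv_{ch}"] = cvs[ch]
    for ch in CHANNELS:
        values[f"slope_{ch}"] = slopes[ch]
    for ch in CHANNELS:
        values[f"iqr_{ch}"] = iqrs[ch]
    return FeatureVector(subject_id=trial.subject_id, posture=trial.posture, values=values)


def extract_cohort_features(
    cohort: Cohort,
    posture: str,
    template: HealthyTemplate,
    *,
    preprocessed: Optional[Mapping[Tuple[str, str, int], PreprocessedTrial]] = None,
    dtw_params: DtwParams = DtwParams(),
    lstm_spec: LstmSpec = LstmSpec(),
    stats_on: str = "translated",
    trial_aggregation: str = "mean",
) -> pd.DataFrame:
    """Feature table for one posture: subjects x 36 named columns + ``label``.

    With ``trial_aggregation='mean'`` (the default, one row per subject) the
    per-trial feature vectors are averaged; ``'per_trial'`` keeps one row per
    trial with a ``trial_index`` column.
    """
    if preprocessed is None:
        preprocessed = preprocess_cohort(cohort)
    labels = cohort.labels()
    names = feature_names()
    rows, index = [], []
    for s in sorted(cohort.subjects, key=lambda s: s.subject_id):
        trials = cohort.trials_for(s.subject_id, posture)
        if not trials:
            raise ValueError(f"subject {s.subject_id!r} has no trials for posture {posture}")
        vecs = [
            extract_features(
                preprocessed[(t.subject_id, t.posture, t.trial_index)],
                template,
                dtw_params=dtw_params,
                lstm_spec=lstm_spec,
                stats_on=stats_on,
            )
            for t in trials
        ]
        if trial_aggregation == "mean":
            mean = np.mean([v.as_array() for v in vecs], axis=0)
            rows.append(dict(zip(names, mean), label=labels[s.subject_id]))
            index.append(s.subject_id)
        elif trial_aggregation == "per_trial":
            for t, v in zip(trials, vecs):
                rows.append(dict(v.values, label=labels[s.subject_id], trial_index=t.trial_index))
                index.append(s.subject_id)
        else:
            raise ValueError(f"unknown trial_aggregation {trial_aggregation!r}")
    df = pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))
    return df
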