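"""Per-channel COP cleaning: outlier replacement, origin translation, Z-score.

The three steps run in a fixed order on every channel independently:

1. points farther than 3 population SD from the channel mean (both computed
   once over the raw series) are replaced by the mean;
2. the channel is translated so its first sample sits at the origin, removing
   initial foot-placement offsets while preserving relative displacement;
3. the translated series is Z-scored (population SD).

Both the translated (mm) and standardized (unitless) variants are kept:
template construction, DTW and LSTM embeddings consume the standardized
series, while the statistical descriptors default to the translated series
because the coefficient of variation sigma/mu is degenerate on Z-scored data.
The module is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .core import CHANNELS, Cohort, CopTrial

logger = logging.getLogger(__name__)


def clean_outliers(series: np.ndarray) -> Tuple[np.ndarray, int]:
    """Replace points with |x - mu| > 3*SD by mu; return (cleaned, count).

    mu and SD (population) are computed once over the full input, before any
    replacement.  A constant series (SD = 0) is returned unchanged.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    mu = x.mean()
    sd = x.std()  # population
    if sd == 0.0:
        return x.copy(), 0
    mask = np.abs(x - mu) > 3.0 * sd
    out = np.where(mask, mu, x)
    count = int(mask.sum())
    # contiguous runs of >= 5 replacements are unexpected in quiet-stance data
    if count >= 5:
        run, longest = 0, 0
        for m in mask:
            run = run + 1 if m else 0
            longest = max(longest, run)
        if longest >= 5:
            logger.warning("replaced a contiguous run of %d outliers (>= 5)", longest)
    return out, count


def translate_to_origin(channels: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
    """Subtract each channel's first sample so trajectories start at (0, 0)."""
    return {ch: np.asarray(v, dtype=float) - float(v[0]) for ch, v in channels.items()}


def zscore(series: np.ndarray) -> np.ndarray:
    """(x - mean) / population SD; a constant series maps to all zeros."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    sd = x.std()
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


@dataclass
class PreprocessedTrial:
    """Cleaned trial holding both the translated and the standardized variant."""

    subject_id: str
    posture: str
    trial_index: int
    sampling_rate_hz: float
    translated: Dict[str, np.ndarray]
    standardized: Dict[str, np.ndarray]
    outlier_count: Dict[str, int] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.translated.values())))


def preprocess_trial(trial: CopTrial) -> PreprocessedTrial:
    """Run clean -> translate -> zscore on all six channels of one trial."""
    cleaned: Dict[str, np.ndarray] = {}
    counts: Dict[str, int] = {}
    for ch in CHANNELS:
        cleaned[ch], counts[ch] = clean_outliers(trial.channels[ch])
    translated = translate_to_origin(cleaned)
    standardized = {ch: zscore(v) for ch, v in translated.items()}
    return PreprocessedTrial(
        subject_id=trial.subject_id,
        posture=trial.posture,
        trial_index=trial.trial_index,
        sampling_rate_hz=trial.sampling_rate_hz,
        translated=translated,
        standardized=standardized,
        outlier_count=counts,
    )


def preprocess_cohort(cohort: Cohort) -> Dict[Tuple[str, str, int], PreprocessedTrial]:
    """Preprocess every trial; keyed by (subject_id, posture, trial_index)."""
    return {
        (t.subject_id, t.posture, t.trial_index): preprocess_trial(t)
        for t in cohort.trials
    }
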