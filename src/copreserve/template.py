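"""Posture-specific healthy template construction.

The reference curve for each channel is the pointwise median of the
standardized COP series of all non-sarcopenia subjects (one series per
subject, averaged over that subject's trials by default).  Before taking the
median, each timepoint's cross-subject value vector is screened with a
two-sided Grubbs test (alpha = 0.05); the test is diagnostic — flags are
counted and logged, values are not removed unless ``exclude_outliers`` is
set.  Patient data never enter template construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import CHANNELS, Cohort
from .preprocess import PreprocessedTrial, preprocess_cohort

logger = logging.getLogger(__name__)


@dataclass
class GrubbsResult:
    applicable: bool
    is_outlier: bool
    G: float
    critical: float
    outlier_index: int = -1


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile formula."""
    t2 = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_test(values: np.ndarray, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-outlier Grubbs test.

    G = max|x - mean| / s with sample SD (ddof=1).  Returns a not-applicable
    result for n < 3 or a constant vector.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        return GrubbsResult(False, False, np.nan, np.nan)
    s = x.std(ddof=1)
    if s == 0.0:
        return GrubbsResult(False, False, np.nan, np.nan)
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    G = dev[idx] / s
    crit = grubbs_critical(n, alpha)
    return GrubbsResult(True, bool(G > crit), float(G), float(crit), idx)


@dataclass
class HealthyTemplate:
    """Per-posture normative reference: one median curve per channel."""

    posture: str
    curves: Dict[str, np.ndarray]
    n_controls: int
    grubbs_alpha: float = 0.05
    grubbs_flags: int = 0

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.curves.values())))


def _subject_series(
    cohort: Cohort,
    preprocessed: Mapping[Tuple[str, str, int], PreprocessedTrial],
    subject_id: str,
    posture: str,
    trial_aggregation: str,
) -> Dict[str, np.ndarray]:
    """One standardized series per channel for a subject (trial mean by default)."""
    trials = cohort.trials_for(subject_id, posture)
    if not trials:
        raise ValueError(f"subject {subject_id!r} has no trials for posture {posture}")
    keys = [(t.subject_id, t.posture, t.trial_index) for t in trials]
    if trial_aggregation == "mean":
        return {
            ch: np.mean([preprocessed[k].standardized[ch] for k in keys], axis=0)
            for ch in CHANNELS
        }
    raise ValueError(f"unknown trial_aggregation {trial_aggregation!r}")


def build_template(
    cohort: Cohort,
    posture: str,
    *,
    preprocessed: Optional[Mapping[Tuple[str, str, int], PreprocessedTrial]] = None,
    trial_aggregation: str = "mean",
    grubbs_alpha: float = 0.05,
    exclude_outliers: bool = False,
    control_subset: Optional[Sequence[str]] = None,
) -> HealthyTemplate:
    """Median control curve per channel, with Grubbs screening per timepoint.

    ``control_subset`` restricts template construction to the named controls
    (used by the per-fold template mode so held-out controls never shape the
    reference they are later compared against).
    """
    controls = cohort.control_ids()
    if control_subset is not None:
        subset = set(control_subset)
        unknown_patients = subset - set(controls) - set(cohort.patient_ids())
        if unknown_patients:
            raise ValueError(f"unknown subject(s) in control_subset: {sorted(unknown_patients)}")
        controls = [c for c in controls if c in subset]
    if not controls:
        raise ValueError("cannot build a healthy template: cohort has no control subjects")
    if preprocessed is None:
        control_trials = [t for t in cohort.trials if t.subject_id in set(controls) and t.posture == posture]
        sub = Cohort(
            subjects=[s for s in cohort.subjects if s.label == 0],
            trials=control_trials,
        )
        preprocessed = preprocess_cohort(sub)
        cohort_for_series = sub
    else:
        cohort_for_series = cohort

    per_subject = {
        sid: _subject_series(cohort_for_series, preprocessed, sid, posture, trial_aggregation)
        for sid in controls
    }
    lengths = {len(v[CHANNELS[0]]) for v in per_subject.values()}
    if len(lengths) != 1:
        raise ValueError(f"control series lengths differ: {sorted(lengths)}")

    n = len(controls)
    flags = 0
    curves: Dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        # subjects x T matrix of standardized values
        mat = np.stack([per_subject[sid][ch] for sid in sorted(controls)])
        if n >= 3:
            mean = mat.mean(axis=0)
            s = mat.std(axis=0, ddof=1)
            dev = np.abs(mat - mean)
            gmax = np.where(s > 0, dev.max(axis=0) / np.where(s > 0, s, 1.0), 0.0)
            crit = grubbs_critical(n, grubbs_alpha)
            flagged = gmax > crit
            flags += int(flagged.sum())
            if exclude_outliers and flagged.any():
                masked = mat.copy()
                cols = np.where(flagged)[0]
                masked[np.argmax(dev[:, cols], axis=0), cols] = np.nan
                curves[ch] = np.where(flagged, np.nanmedian(masked, axis=0), np.median(mat, axis=0))
                continue
        curves[ch] = np.median(mat, axis=0)
    if flags:
        logger.info("Grubbs flagged %d timepoint(s) across channels for posture %s (diagnostic only)", flags, posture)
    return HealthyTemplate(
        posture=posture,
        curves=curves,
        n_controls=n,
        grubbs_alpha=grubbs_alpha,
        grubbs_flags=flags,
    )
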