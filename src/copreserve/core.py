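"""Domain types and file I/O for center-of-pressure (COP) cohorts.

A recording session yields, per subject, per standing posture, three 20 s
trials of six synchronized COP displacement channels (left foot X/Y, right
foot X/Y, overall center X/Y) sampled at 100 Hz.  The interchange format is
long-format CSV (one row per sample) plus a JSON metadata file mapping
subject ids to the binary sarcopenia label and optional clinical indicators
(ASMI, grip strength, five-time chair-stand time, six-minute-walk speed, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: The six COP displacement channels, in canonical order.
CHANNELS: tuple = ("COP-LX", "COP-LY", "COP-RX", "COP-RY", "COP-CX", "COP-CY")

#: Standing postures: feet-together, feet-apart, semi-tandem.
POSTURES: tuple = ("FT", "FA", "ST")

#: Clinical indicator keys recognised in metadata (all optional).
CLINICAL_KEYS: tuple = ("ASMI", "grip", "TCS5", "MW6", "age", "height", "weight", "sex")

# CSV column schema for the long-format data file.
DATA_COLUMNS = ("subject_id", "posture", "trial_index", "sample_index", "channel", "value")


class CohortError(ValueError):
    """Raised when cohort data violate the format contract."""


@dataclass
class CopTrial:
    """One subject x posture x trial recording: six equal-length channels."""

    subject_id: str
    posture: str
    trial_index: int
    channels: Dict[str, np.ndarray]
    sampling_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self.validate()

    def validate(self) -> None:
        where = f"subject={self.subject_id} posture={self.posture} trial={self.trial_index}"
        if self.posture not in POSTURES:
            raise CohortError(f"unknown posture code {self.posture!r} ({where})")
        if self.trial_index < 1:
            raise CohortError(f"trial_index must be >= 1 ({where})")
        if self.sampling_rate_hz <= 0:
            raise CohortError(f"sampling_rate_hz must be positive ({where})")
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise CohortError(f"missing channel(s) {missing} ({where})")
        extra = [c for c in self.channels if c not in CHANNELS]
        if extra:
            raise CohortError(f"unknown channel(s) {extra} ({where})")
        lengths = {c: len(v) for c, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise CohortError(f"ragged channel lengths {lengths} ({where})")
        if self.n_samples < 2:
            raise CohortError(f"trial length must be >= 2, got {self.n_samples} ({where})")
        for c, v in self.channels.items():
            if not np.all(np.isfinite(v)):
                raise CohortError(f"non-finite values in channel {c} ({where})")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class SubjectRecord:
    """Subject metadata: binary sarcopenia label (1 = sarcopenia) + clinical indicators."""

    subject_id: str
    label: int
    clinical: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise CohortError(f"label must be 0 or 1, got {self.label!r} (subject={self.subject_id})")
        for k, v in self.clinical.items():
            if k == "sex":
                continue
            if v is not None and (not np.isfinite(v) or v <= 0):
                raise CohortError(
                    f"clinical indicator {k}={v!r} must be a positive real (subject={self.subject_id})"
                )


@dataclass
class Cohort:
    """A labeled collection of subjects and their COP trials."""

    subjects: List[SubjectRecord]
    trials: List[CopTrial]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = {s.subject_id for s in self.subjects}
        if len(ids) != len(self.subjects):
            raise CohortError("duplicate subject_id in metadata")
        for t in self.trials:
            if t.subject_id not in ids:
                raise CohortError(
                    f"trial subject {t.subject_id!r} (posture={t.posture}, trial={t.trial_index}) "
                    "absent from metadata"
                )
        # every subject with data must cover every posture present in the cohort
        postures = {t.posture for t in self.trials}
        by_subject: Dict[str, set] = {}
        for t in self.trials:
            by_subject.setdefault(t.subject_id, set()).add(t.posture)
        for sid, have in by_subject.items():
            if have != postures:
                raise CohortError(
                    f"subject {sid!r} has trials for {sorted(have)} but cohort covers {sorted(postures)}"
                )

    @property
    def postures(self) -> List[str]:
        return [p for p in POSTURES if any(t.posture == p for t in self.trials)]

    def labels(self) -> Dict[str, int]:
        return {s.subject_id: s.label for s in self.subjects}

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def trials_for(self, subject_id: str, posture: str) -> List[CopTrial]:
        out = [t for t in self.trials if t.subject_id == subject_id and t.posture == posture]
        return sorted(out, key=lambda t: t.trial_index)

    def control_ids(self) -> List[str]:
        return [s.subject_id for s in self.subjects if s.label == 0]

    def patient_ids(self) -> List[str]:
        return [s.subject_id for s in self.subjects if s.label == 1]


def write_cohort(cohort: Cohort, data_path, meta_path) -> None:
    """Write a cohort as long-format CSV + JSON metadata.

    Rows are ordered (subject, posture, trial, channel, sample) so output is
    deterministic.  Floats are printed at 17 significant digits, which makes
    ``read_cohort(write_cohort(c))`` value-exact.
    """
    data_path, meta_path = Path(data_path), Path(meta_path)
    with open(data_path, "w") as fh:
        fh.write(",".join(DATA_COLUMNS) + "\n")
        for t in sorted(cohort.trials, key=lambda t: (t.subject_id, t.posture, t.trial_index)):
            for ch in CHANNELS:
                v = t.channels[ch]
                prefix = f"{t.subject_id},{t.posture},{t.trial_index},"
                fh.writelines(
                    f"{prefix}{i},{ch},{x:.17g}\n" for i, x in enumerate(v)
                )
    meta = {}
    for s in sorted(cohort.subjects, key=lambda s: s.subject_id):
        entry: dict = {"label": int(s.label)}
        entry.update({k: s.clinical[k] for k in sorted(s.clinical)})
        meta[s.subject_id] = entry
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_cohort(data_path, meta_path) -> Cohort:
    """Read a cohort from long-format CSV + JSON metadata.

    Validates channel completeness, per-channel sample-index contiguity and
    that every subject appearing in the data file has metadata.
    """
    data_path, meta_path = Path(data_path), Path(meta_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    subjects = []
    for sid, entry in sorted(meta.items()):
        clinical = {k: v for k, v in entry.items() if k != "label"}
        subjects.append(SubjectRecord(subject_id=sid, label=int(entry["label"]), clinical=clinical))

    df = pd.read_csv(
        data_path,
        dtype={"subject_id": str, "posture": str, "trial_index": int, "sample_index": int, "channel": str},
        float_precision="round_trip",  # bit-exact read-back of %.17g output
    )
    missing_cols = set(DATA_COLUMNS) - set(df.columns)
    if missing_cols:
        raise CohortError(f"data file missing columns {sorted(missing_cols)}")

    known = {s.subject_id for s in subjects}
    trials: List[CopTrial] = []
    for (sid, posture, tidx), grp in df.groupby(["subject_id", "posture", "trial_index"], sort=True):
        if sid not in known:
            raise CohortError(f"subject {sid!r} in data file absent from metadata")
        channels = {}
        for ch, cgrp in grp.groupby("channel", sort=True):
            cgrp = cgrp.sort_values("sample_index")
            idx = cgrp["sample_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise CohortError(
                    f"non-contiguous sample_index for subject={sid} posture={posture} "
                    f"trial={tidx} channel={ch}"
                )
            channels[ch] = cgrp["value"].to_numpy(dtype=float)
        missing = [c for c in CHANNELS if c not in channels]
        if missing:
            raise CohortError(
                f"missing channel(s) {missing} for subject={sid} posture={posture} trial={tidx}"
            )
        trials.append(CopTrial(subject_id=sid, posture=str(posture), trial_index=int(tidx), channels=channels))
    return Cohort(subjects=subjects, trials=trials)


def fmt12(x: float) -> float:
    """Round-trip a float through 12 significant digits (report serialization)."""
    return float(f"{float(x):.12g}")


def json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return fmt12(float(o))
    if isinstance(o, float):
        return fmt12(o)
    if isinstance(o, np.ndarray):
        return [json_default(v) for v in o.tolist()]
    raise TypeError(f"not JSON serializable: {type(o)}")
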