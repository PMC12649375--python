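"""Synthetic COP cohort generator.

Controls are generated as stationary second-order autoregressive (AR(2)) sway:
low-pass Gaussian noise with a resonance in the 0.3-1 Hz quiet-stance band,
zero drift, and a closed-form stationary variance so the target sway SD (mm)
is hit exactly in expectation.  Patients are the same process degraded by
three severity-graded pathology terms, each scaled by ``1 - reserve``:

* directional drift — a linear trend of ``drift_per_sample`` mm/sample,
* delayed corrective response — the sway process is read ``delay_samples``
  later, emulating sluggish neuromuscular corrections,
* inflated dispersion — sway amplitude multiplied by
  ``1 + (1-reserve)*(sway_scale-1)``.

``reserve`` in [0, 1] encodes compensatory reserve: at ``reserve=1`` every
pathology term vanishes and the patient generator path is bit-identical to a
control with the same seed (an exact null).  Postures differ in base sway
amplitude and in how strongly they express pathology (semi-tandem, the
narrow-base stance, has gain 1; the easier stances partially mask deficits),
mirroring the observation that narrow stances unmask compensated deficits.

Clinical indicators are drawn around published healthy-cohort means and move
monotonically toward sarcopenic means as ``1 - reserve`` grows, so feature vs.
indicator correlation tests have a known sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.signal import lfilter

from .core import CHANNELS, Cohort, CopTrial, SubjectRecord

#: Per-posture multiplier on baseline sway amplitude (narrow base sways more).
POSTURE_SWAY = {"FT": 1.0, "FA": 0.8, "ST": 1.3}

#: Per-posture gain on the pathology terms: easy stances let patients
#: compensate, semi-tandem expresses the full deficit.
POSTURE_SEVERITY_GAIN = {"FT": 0.5, "FA": 0.7, "ST": 1.0}

# Clinical anchors (mean, SD) for controls and definite-sarcopenia patients:
# grip strength (kg), five-time chair stand (s), six-minute-walk speed (m/s),
# appendicular skeletal muscle index (kg/m^2).
_CLINICAL_CONTROL = {"grip": (25.75, 3.20), "TCS5": (8.46, 1.05), "MW6": (1.17, 0.11), "ASMI": (6.49, 0.45)}
_CLINICAL_PATIENT = {"grip": (20.33, 2.50), "TCS5": (12.89, 1.25), "MW6": (0.85, 0.09), "ASMI": (6.08, 0.35)}


@dataclass
class SimProfile:
    """Generation parameters for a synthetic cohort."""

    n_controls: int = 40
    n_patients: int = 42
    postures: Tuple[str, ...] = ("FT", "FA", "ST")
    trials_per_posture: int = 3
    T: int = 2000
    fs: float = 100.0
    drift_per_sample: float = 0.003  # mm/sample at full severity (ST)
    delay_samples: int = 20          # corrective lag at full severity
    sway_scale: float = 1.5          # dispersion multiplier at full severity
    reserve: Union[str, float, Sequence[float]] = "uniform"
    seed: int = 0
    sway_sd_mm: float = 2.0          # control stationary sway SD
    ar_f0_hz: float = 0.5            # AR(2) resonance frequency
    ar_pole_radius: float = 0.98
    subject_amplitude_jitter: float = 0.2  # per-subject baseline sway +/- 20%

    def __post_init__(self) -> None:
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.delay_samples < 0:
            raise ValueError("delay_samples must be >= 0")
        if self.sway_scale < 1:
            raise ValueError("sway_scale must be >= 1")
        for p in self.postures:
            if p not in POSTURE_SWAY:
                raise ValueError(f"unknown posture {p!r}")

    def resolve_reserves(self, rng: np.random.Generator) -> np.ndarray:
        """Per-patient reserve values in [0, 1]."""
        if isinstance(self.reserve, str):
            if self.reserve != "uniform":
                raise ValueError(f"unknown reserve spec {self.reserve!r}")
            r = rng.uniform(0.0, 1.0, size=self.n_patients)
        elif np.isscalar(self.reserve):
            r = np.full(self.n_patients, float(self.reserve))
        else:
            r = np.asarray(self.reserve, dtype=float)
            if len(r) != self.n_patients:
                raise ValueError("reserve sequence length must equal n_patients")
        if np.any((r < 0) | (r > 1)):
            raise ValueError("reserve values must lie in [0, 1]")
        return r


def _ar2_coeffs(profile: SimProfile) -> Tuple[float, float, float]:
    """AR(2) coefficients and innovation SD hitting the target stationary SD.

    Poles at radius r and angle theta = 2*pi*f0/fs give a1 = 2r cos(theta),
    a2 = -r^2; the stationary variance of x_t = a1 x_{t-1} + a2 x_{t-2} + e_t
    is sigma_e^2 (1-a2) / ((1+a2) ((1-a2)^2 - a1^2)).
    """
    r = profile.ar_pole_radius
    theta = 2.0 * np.pi * profile.ar_f0_hz / profile.fs
    a1 = 2.0 * r * np.cos(theta)
    a2 = -r * r
    var_unit = (1.0 - a2) / ((1.0 + a2) * ((1.0 - a2) ** 2 - a1 ** 2))
    sigma_e = profile.sway_sd_mm / np.sqrt(var_unit)
    return a1, a2, sigma_e


def _ar2_series(rng: np.random.Generator, n: int, a1: float, a2: float, sigma_e: float) -> np.ndarray:
    burn = 500
    e = rng.normal(0.0, sigma_e, size=burn + n)
    # x_t = a1 x_{t-1} + a2 x_{t-2} + e_t as an IIR filter
    x = lfilter([1.0], [1.0, -a1, -a2], e)
    return x[burn:]


def simulate_trial(
    profile: SimProfile,
    subject_kind: str,
    reserve: float,
    seed: int,
    *,
    posture: str = "ST",
    amplitude_scale: float = 1.0,
    trial_index: int = 1,
    subject_id: str = "S",
) -> CopTrial:
    """Generate one six-channel trial.

    ``subject_kind`` is ``"control"`` or ``"patient"``.  A patient at
    ``reserve=1`` consumes the random stream exactly like a control, so with
    the same seed the two trials are identical.
    """
    if profile.T < 2:
        raise ValueError("T must be >= 2")
    if subject_kind not in ("control", "patient"):
        raise ValueError(f"subject_kind must be 'control' or 'patient', got {subject_kind!r}")
    severity = (1.0 - float(reserve)) if subject_kind == "patient" else 0.0
    gain = POSTURE_SEVERITY_GAIN[posture]
    lag = int(round(gain * severity * profile.delay_samples))
    disp = 1.0 + gain * severity * (profile.sway_scale - 1.0)
    drift = gain * severity * profile.drift_per_sample

    a1, a2, sigma_e = _ar2_coeffs(profile)
    rng = np.random.default_rng(seed)
    t = np.arange(1, profile.T + 1, dtype=float)
    amp = amplitude_scale * POSTURE_SWAY[posture]
    channels: Dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        base = _ar2_series(rng, profile.T + lag, a1, a2, sigma_e)
        sway = base[lag : lag + profile.T]  # delayed read of the sway process
        channels[ch] = amp * disp * sway + drift * t
    return CopTrial(
        subject_id=subject_id,
        posture=posture,
        trial_index=trial_index,
        channels=channels,
        sampling_rate_hz=profile.fs,
    )


def _clinical(rng: np.random.Generator, severity: float) -> Dict[str, float]:
    out: Dict[str, float] = {}
    for key in ("ASMI", "grip", "TCS5", "MW6"):
        m0, s0 = _CLINICAL_CONTROL[key]
        m1, s1 = _CLINICAL_PATIENT[key]
        mean = m0 + severity * (m1 - m0)
        sd = s0 + severity * (s1 - s0)
        out[key] = float(max(rng.normal(mean, sd), 0.05))
    out["age"] = float(np.clip(rng.normal(70.0, 6.0), 60.0, 95.0))
    return out


def simulate_cohort(profile: SimProfile) -> Cohort:
    """Generate a full labeled cohort (subjects, trials, clinical metadata)."""
    master = np.random.default_rng(np.random.SeedSequence(profile.seed))
    reserves = profile.resolve_reserves(master)
    n_total = profile.n_controls + profile.n_patients
    jit = profile.subject_amplitude_jitter
    amplitudes = 1.0 + master.uniform(-jit, jit, size=n_total)
    trial_seeds = master.integers(0, 2 ** 31, size=(n_total, len(profile.postures), profile.trials_per_posture))

    subjects: List[SubjectRecord] = []
    trials: List[CopTrial] = []
    for i in range(n_total):
        is_patient = i >= profile.n_controls
        if is_patient:
            sid = f"P{i - profile.n_controls + 1:03d}"
            reserve = float(reserves[i - profile.n_controls])
            kind, label = "patient", 1
            severity = 1.0 - reserve
        else:
            sid = f"C{i + 1:03d}"
            reserve, kind, label, severity = 1.0, "control", 0, 0.0
        clinical = _clinical(master, severity)
        clinical["reserve_true"] = max(float(reserve), 1e-6) if is_patient else 1.0
        subjects.append(SubjectRecord(subject_id=sid, label=label, clinical=clinical))
        for pj, posture in enumerate(profile.postures):
            for tk in range(profile.trials_per_posture):
                trials.append(
                    simulate_trial(
                        profile,
                        kind,
                        reserve,
                        int(trial_seeds[i, pj, tk]),
                        posture=posture,
                        amplitude_scale=float(amplitudes[i]),
                        trial_index=tk + 1,
                        subject_id=sid,
                    )
                )
    return Cohort(subjects=subjects, trials=trials)
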