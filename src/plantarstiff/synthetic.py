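"""Synthetic gait cohort generator.

No public dataset pairs regional stance-phase plantar pressure with
plantar soft-tissue stiffness, so every downstream stage of this package is
exercised on seeded synthetic cohorts that reproduce the *statistical
structure* the analysis assumes: 30 subjects x 5 trials x 2 feet = 300
samples, ten regional mean pressures with a walking-like load distribution
(heel and central forefoot dominant, toes light), and a stiffness target
distributed around 477 +/- 15 N/m whose ground-truth dependence on each
region carries a configurable sign and magnitude.

The ground-truth relationship is linear with an optional smooth
interaction:

    k_true(F) = intercept
                + sum_i sign_i * magnitude_i * (F_i - profile_i)
                + nonlinearity_scale * g(F)

where ``g`` is a heel x forefoot interaction (product of the relative
deviations of total heel load and total central-forefoot load from their
cohort means).  The observed stiffness adds Gaussian measurement noise and
is clipped to the stiffness meter's valid range [70, 1900] N/m (clipped
samples are flagged).

Default effect magnitudes are calibrated so that (a) the cohort stiffness
standard deviation lands near the reference 15.26 N/m and (b) on the linear
ground truth, mean-impact-value contribution rates are proportional to the
reference per-region contribution rates.  For a linear model the MIV of
region i is proportional to |coefficient_i| * mean_pressure_i, so the
calibration sets ``magnitude_i = EFFECT_SCALE * rate_i / profile_i``.

The generator is statistical, not physical: it emulates no gait dynamics,
foot anatomy or tissue mechanics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .measurement import OscillationTrace, StancePressureSeries
from .regions import (
    MYOTON_STIFFNESS_RANGE,
    N_REGIONS,
    REFERENCE_CONTRIBUTION_RATES,
    REFERENCE_EFFECT_SIGNS,
    REFERENCE_STIFFNESS_MEAN,
    REGION_LABELS,
)

__all__ = [
    "CohortConfig",
    "SyntheticSample",
    "generate_cohort",
    "cohort_to_frame",
    "save_cohort",
    "load_cohort",
    "generate_stance_series",
    "generate_oscillation",
    "DEFAULT_REGION_MEAN_PROFILE",
    "DEFAULT_EFFECT_MAGNITUDES",
]

#: Typical stance-phase mean regional load (N): heel and central forefoot
#: dominant, midfoot moderate, lesser toes light.
DEFAULT_REGION_MEAN_PROFILE = (45.0, 12.0, 60.0, 85.0, 90.0, 70.0, 40.0, 55.0, 95.0, 80.0)

#: Scale constant of the magnitude calibration described in the module
#: docstring ((N/m) per unit contribution rate).
EFFECT_SCALE = 3.9

DEFAULT_EFFECT_MAGNITUDES = tuple(
    EFFECT_SCALE * REFERENCE_CONTRIBUTION_RATES[label] / mean
    for label, mean in zip(REGION_LABELS, DEFAULT_REGION_MEAN_PROFILE)
)

DEFAULT_EFFECT_SIGNS = tuple(REFERENCE_EFFECT_SIGNS[label] for label in REGION_LABELS)

#: Between-subject and within-subject (trial) pressure variability as
#: fractions of the regional mean.
_SUBJECT_CV = 0.10
_TRIAL_CV = 0.05


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    Defaults reproduce the study design the package targets: 30 subjects,
    5 trials per subject, both feet (300 samples), stiffness around
    477 +/- 15 N/m with reference effect signs.
    """

    n_subjects: int = 30
    n_trials: int = 5
    feet: tuple[str, ...] = ("left", "right")
    region_mean_profile: tuple[float, ...] = DEFAULT_REGION_MEAN_PROFILE
    subject_sd: tuple[float, ...] = tuple(_SUBJECT_CV * m for m in DEFAULT_REGION_MEAN_PROFILE)
    trial_sd: tuple[float, ...] = tuple(_TRIAL_CV * m for m in DEFAULT_REGION_MEAN_PROFILE)
    effect_signs: tuple[int, ...] = DEFAULT_EFFECT_SIGNS
    effect_magnitudes: tuple[float, ...] = DEFAULT_EFFECT_MAGNITUDES
    stiffness_intercept: float = REFERENCE_STIFFNESS_MEAN
    noise_sd: float = 5.0
    nonlinearity_scale: float = 0.0
    pairing: str = "per_trial"  # or "repeat_mean": average of stiffness_repeats noise draws
    stiffness_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("n_subjects and n_trials must be >= 1")
        if not self.feet or not set(self.feet) <= {"left", "right"}:
            raise ValueError("feet must be a non-empty subset of {'left', 'right'}")
        for name in ("region_mean_profile", "subject_sd", "trial_sd",
                     "effect_signs", "effect_magnitudes"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (N_REGIONS,):
                raise ValueError(f"{name} must have exactly {N_REGIONS} entries")
        if np.any(np.asarray(self.region_mean_profile) < 0):
            raise ValueError("region_mean_profile must be non-negative")
        if np.any(np.asarray(self.subject_sd) < 0) or np.any(np.asarray(self.trial_sd) < 0):
            raise ValueError("standard deviations must be non-negative")
        if np.any(np.asarray(self.effect_magnitudes) < 0):
            raise ValueError("effect_magnitudes must be non-negative")
        if not set(np.asarray(self.effect_signs, dtype=int)) <= {-1, 1}:
            raise ValueError("effect_signs must be +1 or -1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.nonlinearity_scale < 0:
            raise ValueError("nonlinearity_scale must be non-negative")
        if self.pairing not in ("per_trial", "repeat_mean"):
            raise ValueError("pairing must be 'per_trial' or 'repeat_mean'")
        if self.stiffness_repeats < 1:
            raise ValueError("stiffness_repeats must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_subjects * self.n_trials * len(self.feet)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("feet", "region_mean_profile", "subject_sd", "trial_sd",
                    "effect_signs", "effect_magnitudes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticSample:
    """One walking trial of one foot: pressures, true and observed stiffness."""

    subject_id: int
    foot: str
    trial_index: int
    pressures: np.ndarray
    stiffness_true: float
    stiffness_observed: float
    clipped: bool = False


# heel = medial + lateral heel; central forefoot = metatarsals 2-4
_HEEL_IDX = np.array([8, 9])
_FOREFOOT_IDX = np.array([3, 4, 5])


def _interaction(pressures: np.ndarray, profile: np.ndarray) -> float:
    """Smooth heel x central-forefoot interaction term g(F)."""
    heel = pressures[_HEEL_IDX].sum() / profile[_HEEL_IDX].sum() - 1.0
    fore = pressures[_FOREFOOT_IDX].sum() / profile[_FOREFOOT_IDX].sum() - 1.0
    return float(heel * fore)


def true_stiffness(pressures: np.ndarray, config: CohortConfig) -> float:
    """Evaluate the ground-truth pressure-to-stiffness relationship (N/m)."""
    pressures = np.asarray(pressures, dtype=float)
    profile = np.asarray(config.region_mean_profile, dtype=float)
    signs = np.asarray(config.effect_signs, dtype=float)
    mags = np.asarray(config.effect_magnitudes, dtype=float)
    value = config.stiffness_intercept + float(
        np.sum(signs * mags * (pressures - profile))
    )
    if config.nonlinearity_scale:
        value += config.nonlinearity_scale * _interaction(pressures, profile)
    return value


def generate_cohort(config: CohortConfig) -> list[SyntheticSample]:
    """Draw a full synthetic cohort, deterministically for a given config.

    Each subject gets a between-subject regional offset shared by both feet
    and all trials; each trial/foot adds within-subject noise.  Negative
    pressure draws are truncated at zero (rare at the default variability).
    Observed stiffness is the ground truth plus Gaussian noise — one draw
    per trial (``pairing='per_trial'``) or the mean of
    ``stiffness_repeats`` draws (``pairing='repeat_mean'``) — clipped to
    the meter range with a flag.
    """
    rng = np.random.default_rng(config.seed)
    profile = np.asarray(config.region_mean_profile, dtype=float)
    subject_sd = np.asarray(config.subject_sd, dtype=float)
    trial_sd = np.asarray(config.trial_sd, dtype=float)
    lo, hi = MYOTON_STIFFNESS_RANGE

    samples: list[SyntheticSample] = []
    for subject in range(1, config.n_subjects + 1):
        subject_offset = rng.normal(0.0, subject_sd)
        for foot in config.feet:
            for trial in range(1, config.n_trials + 1):
                pressures = np.clip(
                    profile + subject_offset + rng.normal(0.0, trial_sd), 0.0, None
                )
                k_true = true_stiffness(pressures, config)
                if config.pairing == "per_trial":
                    noise = rng.normal(0.0, config.noise_sd)
                else:
                    noise = rng.normal(0.0, config.noise_sd, config.stiffness_repeats).mean()
                observed = k_true + noise
                clipped = not (lo <= observed <= hi)
                samples.append(
                    SyntheticSample(
                        subject_id=subject,
                        foot=foot,
                        trial_index=trial,
                        pressures=pressures,
                        stiffness_true=k_true,
                        stiffness_observed=float(np.clip(observed, lo, hi)),
                        clipped=clipped,
                    )
                )
    return samples


def cohort_to_frame(samples: list[SyntheticSample]) -> pd.DataFrame:
    """Tabulate a cohort: meta columns, region_1..region_10, stiffness."""
    rows = []
    for s in samples:
        row = {"subject_id": s.subject_id, "foot": s.foot, "trial": s.trial_index}
        row.update({f"region_{i + 1}": p for i, p in enumerate(s.pressures)})
        row["stiffness"] = s.stiffness_observed
        row["stiffness_true"] = s.stiffness_true
        row["clipped"] = s.clipped
        rows.append(row)
    return pd.DataFrame(rows)


def save_cohort(samples: list[SyntheticSample], csv_path, config: CohortConfig) -> None:
    """Write the cohort CSV plus a JSON sidecar with the generator config."""
    csv_path = Path(csv_path)
    cohort_to_frame(samples).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps({"generator": "plantarstiff.synthetic",
                                   "config": config.to_dict()}, indent=2))


def load_cohort(csv_path) -> pd.DataFrame:
    df = pd.read_csv(csv_path)
    required = [f"region_{i + 1}" for i in range(N_REGIONS)] + ["stiffness"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return df


def generate_stance_series(
    sample: SyntheticSample,
    fs: float = 120.0,
    duration: float = 0.75,
    seed: int = 0,
    noise_scale: float = 0.05,
) -> StancePressureSeries:
    """Expand a sample's mean pressures into a stance-phase time series.

    Each region gets a smooth positive loading template (a raised-cosine
    bump whose centre moves from heel strike to toe off with the region's
    anatomical position) plus seeded roughness, rescaled so the temporal
    mean of every region equals the sample's mean pressure exactly (to
    machine precision).  Frame count is ``round(fs * duration)``.
    """
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    n = int(round(fs * duration))
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n, endpoint=False)

    # Loading-peak timing per region over normalised stance (heel early,
    # forefoot mid/late, toes late).
    centers = np.array([0.80, 0.85, 0.65, 0.62, 0.60, 0.58, 0.55, 0.35, 0.12, 0.12])
    widths = np.array([0.25, 0.22, 0.30, 0.30, 0.30, 0.30, 0.30, 0.35, 0.25, 0.25])

    frames = np.empty((n, 10))
    for r in range(10):
        bump = 0.5 * (1.0 + np.cos(np.pi * np.clip((t - centers[r]) / widths[r], -1, 1)))
        base = 0.15 + bump + noise_scale * rng.standard_normal(n)
        base = np.clip(base, 1e-6, None)
        frames[:, r] = base * (sample.pressures[r] / base.mean())
    return StancePressureSeries(frames, sampling_rate=fs)


def generate_oscillation(
    stiffness: float,
    probe_mass: float = 0.018,
    seed: int = 0,
    damping_ratio: float = 0.05,
    impact_velocity: float = 0.15,
    fs: float = 3200.0,
    duration: float | None = None,
    noise_scale: float = 0.0,
) -> OscillationTrace:
    """Synthesize a probe-tap oscillation for a tissue of known stiffness.

    Uses the closed-form underdamped single-degree-of-freedom solution for
    a probe of mass ``m`` on tissue of stiffness ``k`` set moving with
    initial velocity ``v0``:

        x(t) = (v0 / wd) exp(-zeta*wn*t) sin(wd t),   wn = sqrt(k/m)

    with analytic velocity and acceleration.  At light damping the peak
    acceleration and first displacement peak satisfy
    ``m * a_max / delta_l ~= k`` to well within 1%.  ``noise_scale`` adds
    seeded Gaussian roughness (fraction of each channel's peak amplitude).
    """
    if stiffness <= 0 or probe_mass <= 0:
        raise ValueError("stiffness and probe_mass must be positive")
    if not 0 <= damping_ratio < 1:
        raise ValueError("damping_ratio must be in [0, 1)")
    wn = np.sqrt(stiffness / probe_mass)
    wd = wn * np.sqrt(1.0 - damping_ratio**2)
    if duration is None:
        duration = 3.0 * 2.0 * np.pi / wn  # three oscillation periods
    n = max(int(round(fs * duration)), 8)
    t = np.arange(n) / fs

    sigma = damping_ratio * wn
    env = np.exp(-sigma * t)
    c = impact_velocity / wd
    x = c * env * np.sin(wd * t)
    v = c * env * (wd * np.cos(wd * t) - sigma * np.sin(wd * t))
    a = c * env * ((sigma**2 - wd**2) * np.sin(wd * t) - 2 * sigma * wd * np.cos(wd * t))

    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        x = x + noise_scale * np.max(np.abs(x)) * rng.standard_normal(n)
        v = v + noise_scale * np.max(np.abs(v)) * rng.standard_normal(n)
        a = a + noise_scale * np.max(np.abs(a)) * rng.standard_normal(n)
    return OscillationTrace(time=t, displacement=x, velocity=v, acceleration=a)
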