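"""Measurement primitives: regional mean pressure and oscillation stiffness.

Two formulas turn raw recordings into the model's features and target:

* the regional mean pressure over the stance phase,
  ``F_mean = (sum_i F_i) / n`` per region, computed from the 120 Hz
  pressure-plate time series;
* the soft-tissue stiffness read off a probe's damped natural oscillation,
  ``S = a_max * m_probe / delta_l`` (N/m), where ``a_max`` is the peak
  acceleration, ``m_probe`` the probe mass and ``delta_l`` the tissue
  deformation.

The deformation convention: ``delta_l`` is the peak displacement excursion
of the first compression half-cycle (displacement from rest to the first
oscillation peak).  The trace source does not prescribe how the scalar is
read off the curve, so this package fixes that convention and documents it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import N_REGIONS, REGION_LABELS

__all__ = [
    "StancePressureSeries",
    "RegionalPressureVector",
    "OscillationMeasurement",
    "OscillationTrace",
    "mean_regional_pressure",
    "extract_oscillation_features",
    "compute_stiffness",
    "read_stance_series_csv",
    "read_oscillation_csv",
]


@dataclass
class StancePressureSeries:
    """Per-region pressure samples over one stance phase.

    ``frames`` has shape (n_frames, 10), one column per plantar region in
    the canonical order; all pressures are non-negative.
    """

    frames: np.ndarray
    sampling_rate: float
    region_labels: tuple[str, ...] = REGION_LABELS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[1] != N_REGIONS:
            raise ValueError(
                f"frames must be (n_frames, {N_REGIONS}), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("series must contain at least one frame")
        if len(self.region_labels) != N_REGIONS:
            raise ValueError("exactly 10 region labels required")
        if np.any(self.frames < 0):
            raise ValueError("pressures must be non-negative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class RegionalPressureVector:
    """Mean stance-phase pressure for the ten regions (one trial, one foot)."""

    values: np.ndarray
    region_labels: tuple[str, ...] = REGION_LABELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_REGIONS,):
            raise ValueError(f"expected {N_REGIONS} values, got {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("mean pressures must be non-negative")


@dataclass
class OscillationMeasurement:
    """Scalar features of one probe oscillation: a_max (m/s^2), probe mass (kg), delta_l (m)."""

    a_max: float
    probe_mass: float
    delta_l: float

    def __post_init__(self) -> None:
        if self.a_max <= 0:
            raise ValueError("a_max must be positive")
        if self.probe_mass <= 0:
            raise ValueError("probe_mass must be positive")
        if self.delta_l <= 0:
            raise ValueError("delta_l must be positive")


@dataclass
class OscillationTrace:
    """Sampled displacement / velocity / acceleration of a probe oscillation."""

    time: np.ndarray
    displacement: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray

    def __post_init__(self) -> None:
        arrays = [
            np.asarray(a, dtype=float)
            for a in (self.time, self.displacement, self.velocity, self.acceleration)
        ]
        self.time, self.displacement, self.velocity, self.acceleration = arrays
        n = self.time.size
        if any(a.size != n for a in arrays):
            raise ValueError("trace arrays must have equal lengths")
        if n < 2:
            raise ValueError("trace must contain at least two samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


def mean_regional_pressure(series: StancePressureSeries) -> RegionalPressureVector:
    """Average pressure of the ten plantar regions over the stance phase.

    Per region, returns ``(sum_i F_i) / n`` over all provided frames.  No
    heel-strike / toe-off windowing is applied: the caller supplies the
    stance window.
    """
    if series.n_frames == 0:
        raise ValueError("cannot average a series with zero frames")
    return RegionalPressureVector(
        series.frames.mean(axis=0), region_labels=series.region_labels
    )


def extract_oscillation_features(
    trace: OscillationTrace, probe_mass: float
) -> OscillationMeasurement:
    """Read (a_max, delta_l) off an oscillation trace.

    ``a_max`` is the maximum absolute acceleration over the whole trace.
    ``delta_l`` is the peak absolute displacement within the first
    compression half-cycle: from the start of the trace up to the first
    sign change of the displacement after its initial excursion.

    Raises
    ------
    ValueError
        If the trace is flat (no oscillation to measure).
    """
    a_max = float(np.max(np.abs(trace.acceleration)))
    s = trace.displacement
    if a_max == 0.0 or np.max(np.abs(s)) == 0.0:
        raise ValueError("flat trace: no oscillation to extract features from")

    # First half-cycle: samples before displacement first crosses back
    # through zero (sign opposite to the initial excursion).
    initial_sign = np.sign(s[np.argmax(np.abs(s) > 0)])
    crossing = np.nonzero(np.sign(s) == -initial_sign)[0]
    end = crossing[0] if crossing.size else s.size
    delta_l = float(np.max(np.abs(s[:end])))
    if delta_l == 0.0:
        raise ValueError("no displacement excursion in the first half-cycle")
    return OscillationMeasurement(a_max=a_max, probe_mass=probe_mass, delta_l=delta_l)


def compute_stiffness(m: OscillationMeasurement) -> float:
    """Soft-tissue stiffness ``S = a_max * m_probe / delta_l`` in N/m."""
    if m.delta_l == 0:
        raise ZeroDivisionError("delta_l must be nonzero")
    return m.a_max * m.probe_mass / m.delta_l


def read_stance_series_csv(path, sampling_rate: float = 120.0) -> StancePressureSeries:
    """Read a stance series from CSV (frame rows x 10 region columns)."""
    df = pd.read_csv(path)
    missing = [r for r in REGION_LABELS if r not in df.columns]
    if missing:
        raise ValueError(f"stance series CSV missing region columns: {missing}")
    return StancePressureSeries(
        df[list(REGION_LABELS)].to_numpy(dtype=float), sampling_rate=sampling_rate
    )


def read_oscillation_csv(path) -> OscillationTrace:
    """Read an oscillation trace from CSV with columns time, s, v, a."""
    df = pd.read_csv(path)
    for col in ("time", "s", "v", "a"):
        if col not in df.columns:
            raise ValueError(f"oscillation CSV missing column {col!r}")
    return OscillationTrace(
        time=df["time"].to_numpy(),
        displacement=df["s"].to_numpy(),
        velocity=df["v"].to_numpy(),
        acceleration=df["a"].to_numpy(),
    )
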