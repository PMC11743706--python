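"""Dataset assembly, min-max normalization and the 8:2 split.

Inputs and the stiffness target are min-max normalized to (0, 1),

    x_standard = (x - x_min) / (x_max - x_min),

before any optimization or training, and predictions are inverse-normalized
back to N/m afterwards.  By default the normalizer is fitted on the *full*
dataset before splitting, reproducing the processing order this pipeline
models; that order leaks the test rows' min/max into training, so a strict
``fit_on="train"`` option is provided.  Values outside the fitted range map
outside [0, 1] through the same affine map.

The split is 8:2 by a seeded uniform permutation of rows by default
(trial-random: rows are trials, so a subject can appear on both sides); a
subject-wise mode keeps all rows of a subject on one side.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import N_REGIONS, REGION_LABELS

__all__ = [
    "Dataset",
    "NormalizationParams",
    "SplitSpec",
    "dataset_from_frame",
    "fit_normalizer",
    "normalize",
    "denormalize",
    "split",
]


@dataclass
class Dataset:
    """Supervised dataset: features X (n x 10), target y (N/m), row metadata."""

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match X rows")
        if self.meta is not None and len(self.meta) != self.X.shape[0]:
            raise ValueError("meta rows must match X rows")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("dataset contains missing values")
        if self.n_samples < 2:
            raise ValueError("dataset needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def take(self, idx: np.ndarray) -> "Dataset":
        meta = self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None
        return Dataset(self.X[idx], self.y[idx], meta)


def dataset_from_frame(df: pd.DataFrame, target: str = "stiffness") -> Dataset:
    """Build a Dataset from the cohort CSV schema (region_1..region_10 + target)."""
    feature_cols = [f"region_{i + 1}" for i in range(N_REGIONS)]
    missing = [c for c in feature_cols + [target] if c not in df.columns]
    if missing:
        raise ValueError(f"frame missing columns: {missing}")
    meta_cols = [c for c in ("subject_id", "foot", "trial") if c in df.columns]
    meta = df[meta_cols].reset_index(drop=True) if meta_cols else None
    return Dataset(df[feature_cols].to_numpy(float), df[target].to_numpy(float), meta)


@dataclass
class NormalizationParams:
    """Per-feature and target min/max of the fitted data."""

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if self.x_min.shape != self.x_max.shape:
            raise ValueError("x_min / x_max shape mismatch")
        if np.any(self.x_max <= self.x_min):
            raise ValueError("x_max must exceed x_min element-wise")
        if self.y_max <= self.y_min:
            raise ValueError("y_max must exceed y_min")

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
            "y_min": self.y_min,
            "y_max": self.y_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(np.asarray(d["x_min"]), np.asarray(d["x_max"]),
                   float(d["y_min"]), float(d["y_max"]))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "NormalizationParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_normalizer(dataset: Dataset) -> NormalizationParams:
    """Column-wise min/max of features and target.

    A constant column makes the affine map undefined and is reported as an
    error naming the column rather than silently mapped.
    """
    x_min = dataset.X.min(axis=0)
    x_max = dataset.X.max(axis=0)
    constant = np.nonzero(x_max == x_min)[0]
    if constant.size:
        names = [REGION_LABELS[i] if i < N_REGIONS else f"col_{i}" for i in constant]
        raise ValueError(f"constant feature column(s): {names}; min-max map undefined")
    y_min, y_max = float(dataset.y.min()), float(dataset.y.max())
    if y_max == y_min:
        raise ValueError("constant target column; min-max map undefined")
    return NormalizationParams(x_min, x_max, y_min, y_max)


def normalize(values: np.ndarray, vmin, vmax) -> np.ndarray:
    """Affine map to the fitted (0, 1) range; out-of-range values pass through."""
    return (np.asarray(values, dtype=float) - vmin) / (np.asarray(vmax) - vmin)


def denormalize(standard: np.ndarray, vmin, vmax) -> np.ndarray:
    """Inverse of :func:`normalize`."""
    return np.asarray(standard, dtype=float) * (np.asarray(vmax) - vmin) + vmin


@dataclass
class SplitSpec:
    """8:2 train/test split specification."""

    train_fraction: float = 0.8
    seed: int = 0
    mode: str = "trial-random"  # or "subject-wise"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.mode not in ("trial-random", "subject-wise"):
            raise ValueError("mode must be 'trial-random' or 'subject-wise'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SplitSpec":
        return cls(**d)


def split(dataset: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Partition the dataset into disjoint, exhaustive train and test sets.

    trial-random: a seeded uniform permutation of the rows; the first
    ``round(train_fraction * n)`` go to training.  subject-wise: subjects
    are shuffled and assigned whole to the training side until it reaches
    the target size, so no subject straddles the split.
    """
    n = dataset.n_samples
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    n_train = int(round(spec.train_fraction * n))
    rng = np.random.default_rng(spec.seed)

    if spec.mode == "trial-random":
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    else:
        if dataset.meta is None or "subject_id" not in dataset.meta.columns:
            raise ValueError("subject-wise split requires subject_id metadata")
        subjects = dataset.meta["subject_id"].to_numpy()
        unique = np.unique(subjects)
        if unique.size < 2:
            raise ValueError("subject-wise split needs at least 2 subjects")
        order = rng.permutation(unique)
        train_mask = np.zeros(n, dtype=bool)
        count = 0
        for s in order:
            if count >= n_train:
                break
            mask = subjects == s
            train_mask |= mask
            count += int(mask.sum())
        if train_mask.all():  # keep the test side non-empty
            train_mask[subjects == order[-1]] = False
        train_idx = np.nonzero(train_mask)[0]
        test_idx = np.nonzero(~train_mask)[0]

    if len(test_idx) == 0 or len(train_idx) == 0:
        raise ValueError("split produced an empty side")
    return dataset.take(train_idx), dataset.take(test_idx)
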