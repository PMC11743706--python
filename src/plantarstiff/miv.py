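"""Mean Impact Value (MIV) feature attribution.

MIV asks how much the model's output moves when one input feature is
perturbed by +/-10% on its raw physical scale: for feature i,

    MIV_i = mean_m( P_i1[m] - P_i2[m] )

where P_i1 / P_i2 are the de-normalized predictions after multiplying the
raw feature column by 1.10 / 0.90, re-normalizing with the stored
normalization parameters, and running the trained network.  A positive MIV
means the feature pushes stiffness up; a negative MIV pushes it down.
Contribution rates normalize the magnitudes,

    Con_i = |MIV_i| / sum_j |MIV_j| * 100,

keeping each feature's sign as an annotation; ties in the contribution
ranking are broken by region index.

Because the perturbation acts on the raw scale and predictions are
compared after inverse normalization, MIVs carry physical units (N/m) and
are invariant to any constant shift of the model output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .regions import N_REGIONS, REGION_LABELS

__all__ = ["MIVResult", "perturb_and_predict", "miv_for_feature",
           "contribution_rates", "miv_report"]

#: Default perturbation factors (+10%, -10%).
FACTOR_UP = 1.10
FACTOR_DOWN = 0.90


@dataclass
class MIVResult:
    """Signed MIVs and normalized contribution rates, ranked."""

    table: pd.DataFrame  # columns: region, miv, sign, contribution, rank

    def __post_init__(self) -> None:
        total = self.table["contribution"].sum()
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"contributions must sum to 100, got {total}")
        if len(self.table) == 0:
            raise ValueError("empty MIV table")

    @property
    def signs(self) -> np.ndarray:
        """Signs in region order (+1/-1/0), index-aligned to the features."""
        ordered = self.table.sort_index()
        return np.sign(ordered["miv"].to_numpy())

    def top(self, k: int) -> pd.DataFrame:
        return self.table.sort_values("rank").head(k)


def perturb_and_predict(
    predict_raw: Callable[[np.ndarray], np.ndarray],
    X_raw: np.ndarray,
    feature_index: int,
    factor: float,
) -> np.ndarray:
    """Predictions (physical units) after scaling one raw feature column.

    ``predict_raw`` must map a raw-scale feature matrix to de-normalized
    predictions (it owns the stored normalization parameters).
    """
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    if not 0 <= feature_index < X_raw.shape[1]:
        raise IndexError(f"feature index {feature_index} out of range")
    X_pert = X_raw.copy()
    X_pert[:, feature_index] *= factor
    return np.asarray(predict_raw(X_pert), dtype=float)


def miv_for_feature(
    predict_raw: Callable[[np.ndarray], np.ndarray],
    X_raw: np.ndarray,
    feature_index: int,
    factor_up: float = FACTOR_UP,
    factor_down: float = FACTOR_DOWN,
) -> float:
    """Signed mean impact value of one feature (target units)."""
    p1 = perturb_and_predict(predict_raw, X_raw, feature_index, factor_up)
    p2 = perturb_and_predict(predict_raw, X_raw, feature_index, factor_down)
    return float(np.mean(p1 - p2))


def contribution_rates(mivs: Sequence[float],
                       labels: Sequence[str] | None = None) -> MIVResult:
    """Normalize |MIV|s to percentages and rank descending.

    Raises on all-zero MIVs (the contribution is undefined).
    """
    mivs = np.asarray(mivs, dtype=float)
    if mivs.size == 0 or not np.all(np.isfinite(mivs)):
        raise ValueError("MIVs must be a non-empty finite vector")
    total = np.abs(mivs).sum()
    if total == 0:
        raise ValueError("all MIVs are zero; contribution rates undefined")
    if labels is None:
        labels = (list(REGION_LABELS) if mivs.size == N_REGIONS
                  else [f"feature_{i + 1}" for i in range(mivs.size)])
    contrib = np.abs(mivs) / total * 100.0
    table = pd.DataFrame({
        "region": list(labels),
        "miv": mivs,
        "sign": np.where(mivs > 0, "+", np.where(mivs < 0, "-", "0")),
        "contribution": contrib,
    })
    # rank 1 = largest contribution; ties broken by feature index (stable)
    order = np.argsort(-contrib, kind="stable")
    ranks = np.empty(mivs.size, dtype=int)
    ranks[order] = np.arange(1, mivs.size + 1)
    table["rank"] = ranks
    return MIVResult(table=table)


def miv_report(
    predict_raw: Callable[[np.ndarray], np.ndarray],
    X_raw: np.ndarray,
    labels: Sequence[str] | None = None,
) -> MIVResult:
    """Full MIV table over all features of ``X_raw``, ranked by contribution."""
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    mivs = [miv_for_feature(predict_raw, X_raw, i) for i in range(X_raw.shape[1])]
    return contribution_rates(mivs, labels=labels)
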