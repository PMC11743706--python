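"""Evaluation metrics on the physical (N/m) scale.

Three error measures summarize a fitted model per data split, computed on
inverse-normalized predictions so that units are N/m:

* MBE  = (1/n) sum (y_m - y_hat_m)                      (signed bias)
* RMSE = sqrt((1/n) sum (y_m - y_hat_m)^2)
* REP  = |y_m - y_hat_m| / y_m * 100  per sample, summarized by its
  maximum and mean.

The relative error is taken as an absolute value per sample before the
max/mean summaries, so reported REPs are non-negative magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ErrorReport", "mbe", "rmse", "rep", "error_report", "reports_to_frame"]


def _check(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 1:
        raise ValueError("need at least one sample")
    return y, yhat


def mbe(y, yhat) -> float:
    """Mean bias error ``(1/n) sum (y - y_hat)``, signed, in target units."""
    y, yhat = _check(y, yhat)
    return float(np.mean(y - yhat))


def rmse(y, yhat) -> float:
    """Root mean square error in target units."""
    y, yhat = _check(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rep(y, yhat) -> tuple[np.ndarray, float, float]:
    """Per-sample relative error percentage plus (max, mean) summaries."""
    y, yhat = _check(y, yhat)
    if np.any(y == 0):
        raise ValueError("REP undefined: some true values are zero")
    values = np.abs(y - yhat) / np.abs(y) * 100.0
    return values, float(values.max()), float(values.mean())


@dataclass
class ErrorReport:
    """MBE / RMSE / REP summary for one data split."""

    set_label: str
    n: int
    mbe: float
    rmse: float
    rep_max: float
    rep_mean: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.rmse < 0 or self.rep_max < 0 or self.rep_mean < 0:
            raise ValueError("rmse and REP summaries must be non-negative")

    def to_dict(self) -> dict:
        return {"set": self.set_label, "n": self.n, "mbe": self.mbe,
                "rmse": self.rmse, "rep_max": self.rep_max,
                "rep_mean": self.rep_mean}


def error_report(y, yhat, set_label: str) -> ErrorReport:
    """Compute all three metrics for one split of de-normalized data."""
    _, r_max, r_mean = rep(y, yhat)
    return ErrorReport(set_label=set_label, n=int(np.asarray(y).size),
                       mbe=mbe(y, yhat), rmse=rmse(y, yhat),
                       rep_max=r_max, rep_mean=r_mean)


def reports_to_frame(reports) -> pd.DataFrame:
    """Stack reports into the standard table layout (one row per split)."""
    df = pd.DataFrame([r.to_dict() for r in reports])
    return df.rename(columns={
        "mbe": "MBE (N/m)", "rmse": "RMSE (N/m)",
        "rep_max": "Maximum REP (%)", "rep_mean": "Average REP (%)",
    })
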