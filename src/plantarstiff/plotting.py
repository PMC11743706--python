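"""Standard figures: convergence trace, prediction scatter, MIV bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_convergence", "plot_predictions", "plot_contributions"]


def _axes(ax):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    return ax


def plot_convergence(trace, ax=None):
    """Global-best fitness (training RMSE, normalized) per iteration."""
    ax = _axes(ax)
    trace = np.asarray(trace)
    ax.plot(np.arange(1, trace.size + 1), trace, marker="o", ms=3)
    ax.set_xlabel("PSO-GA iteration")
    ax.set_ylabel("Best fitness (train RMSE, normalized)")
    ax.set_title("Hybrid optimizer convergence")
    return ax


def plot_predictions(y_train, yhat_train, y_test, yhat_test, ax=None):
    """Predicted vs actual stiffness with the identity line."""
    ax = _axes(ax)
    ax.scatter(y_train, yhat_train, s=12, alpha=0.6, label="train")
    ax.scatter(y_test, yhat_test, s=12, alpha=0.8, label="test")
    lo = min(np.min(y_train), np.min(y_test))
    hi = max(np.max(y_train), np.max(y_test))
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlabel("Measured stiffness (N/m)")
    ax.set_ylabel("Predicted stiffness (N/m)")
    ax.legend()
    ax.set_title("Model prediction performance")
    return ax


def plot_contributions(miv_result, ax=None):
    """Bar chart of contribution rates, annotated with each MIV's sign."""
    ax = _axes(ax)
    table = miv_result.table
    colors = ["tab:blue" if s == "+" else "tab:red" for s in table["sign"]]
    ax.bar(range(len(table)), table["contribution"], color=colors)
    ax.set_xticks(range(len(table)))
    ax.set_xticklabels(
        [f"{r} ({s})" for r, s in zip(table["region"], table["sign"])],
        rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("Contribution rate (%)")
    ax.set_title("MIV contribution rates of regional pressures")
    return ax
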