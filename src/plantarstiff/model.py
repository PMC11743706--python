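"""Model / Results objects tying the pipeline together.

`PlantarStiffnessModel` holds a cohort (ten regional mean pressures per
trial/foot plus one stiffness target) and, on `fit()`, runs the full
estimation procedure: min-max normalize, split 8:2, PSO-GA search for the
initial genome, backpropagation training, and evaluation on both splits.
The returned `PlantarStiffnessResults` carries the fitted genome, the
optimizer convergence trace, the training loss history, per-split error
reports, and exposes prediction, MIV attribution, a text `summary()` and
plotting helpers — the usual Model -> Results idiom of statistical
modelling packages.

Example
-------
>>> from plantarstiff import synthetic, model
>>> cfg = synthetic.CohortConfig(seed=42)
>>> df = synthetic.cohort_to_frame(synthetic.generate_cohort(cfg))
>>> res = model.PlantarStiffnessModel.from_dataframe(df).fit(seed=42)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, miv as miv_mod, network, optimizer, preprocessing
from .regions import N_REGIONS, REGION_LABELS

__all__ = ["PlantarStiffnessModel", "PlantarStiffnessResults"]


class PlantarStiffnessModel:
    """Regression model of plantar soft-tissue stiffness on regional pressures.

    Parameters
    ----------
    X : array-like, shape (n, 10)
        Mean stance-phase pressure per plantar region (canonical order).
    y : array-like, shape (n,)
        Soft-tissue stiffness per trial/foot, N/m.
    meta : DataFrame, optional
        Per-row subject_id / foot / trial metadata (needed for the
        subject-wise split mode).
    """

    def __init__(self, X, y, meta: pd.DataFrame | None = None,
                 arch: network.NetworkArchitecture | None = None):
        self.dataset = preprocessing.Dataset(X, y, meta)
        if self.dataset.X.shape[1] != N_REGIONS:
            raise ValueError(f"expected {N_REGIONS} regional features")
        self.arch = arch or network.NetworkArchitecture()
        if self.arch.n_input != N_REGIONS or self.arch.n_output != 1:
            raise ValueError("architecture must map 10 regions to 1 output")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str = "stiffness",
                       arch: network.NetworkArchitecture | None = None
                       ) -> "PlantarStiffnessModel":
        """Build the model from the cohort CSV schema (region_1..10 + target)."""
        ds = preprocessing.dataset_from_frame(df, target=target)
        return cls(ds.X, ds.y, ds.meta, arch=arch)

    def fit(self,
            optimizer_config: optimizer.OptimizerConfig | None = None,
            train_config: network.TrainConfig | None = None,
            split_spec: preprocessing.SplitSpec | None = None,
            normalize_on: str = "all",
            seed: int | None = None) -> "PlantarStiffnessResults":
        """Run normalize -> split -> PSO-GA -> train -> evaluate.

        ``normalize_on='all'`` fits the min-max parameters on the full
        dataset before splitting (the default processing order this
        pipeline models; it leaks the test extrema — use ``'train'`` for a
        strict protocol).  ``seed``, when given, overrides the seeds in
        the optimizer config and split spec.
        """
        if seed is not None:
            ss = np.random.SeedSequence(seed)
            split_seed, opt_seed = (int(s.generate_state(1)[0] % (2**31))
                                    for s in ss.spawn(2))
        else:
            split_seed = opt_seed = None
        split_spec = split_spec or preprocessing.SplitSpec()
        optimizer_config = optimizer_config or optimizer.OptimizerConfig()
        train_config = train_config or network.TrainConfig()
        if split_seed is not None:
            split_spec = preprocessing.SplitSpec(
                split_spec.train_fraction, split_seed, split_spec.mode)
            d = optimizer_config.to_dict()
            d["seed"] = opt_seed
            optimizer_config = optimizer.OptimizerConfig.from_dict(d)

        if normalize_on not in ("all", "train"):
            raise ValueError("normalize_on must be 'all' or 'train'")

        if normalize_on == "all":
            norm = preprocessing.fit_normalizer(self.dataset)
            train_set, test_set = preprocessing.split(self.dataset, split_spec)
        else:
            train_set, test_set = preprocessing.split(self.dataset, split_spec)
            norm = preprocessing.fit_normalizer(train_set)

        Xtr = preprocessing.normalize(train_set.X, norm.x_min, norm.x_max)
        ytr = preprocessing.normalize(train_set.y, norm.y_min, norm.y_max)

        genome0, trace = optimizer.optimize_network(
            self.arch, Xtr, ytr, optimizer_config)
        genome, loss_history = network.train(
            genome0, self.arch, Xtr, ytr, train_config)

        results = PlantarStiffnessResults(
            model=self, genome=genome, initial_genome=genome0,
            normalizer=norm, split_spec=split_spec,
            optimizer_config=optimizer_config, train_config=train_config,
            train_set=train_set, test_set=test_set,
            convergence_trace=trace, loss_history=loss_history,
        )
        results._evaluate()
        return results


@dataclass
class PlantarStiffnessResults:
    """Fitted-model container returned by :meth:`PlantarStiffnessModel.fit`."""

    model: PlantarStiffnessModel
    genome: np.ndarray
    initial_genome: np.ndarray
    normalizer: preprocessing.NormalizationParams
    split_spec: preprocessing.SplitSpec
    optimizer_config: optimizer.OptimizerConfig
    train_config: network.TrainConfig
    train_set: preprocessing.Dataset
    test_set: preprocessing.Dataset
    convergence_trace: np.ndarray
    loss_history: np.ndarray
    report_train: metrics.ErrorReport | None = None
    report_test: metrics.ErrorReport | None = None

    # -- prediction ---------------------------------------------------
    def predict(self, X_raw) -> np.ndarray:
        """Predict stiffness (N/m) from raw-scale regional pressures."""
        norm = self.normalizer
        Xn = preprocessing.normalize(np.atleast_2d(X_raw), norm.x_min, norm.x_max)
        yn = network.forward(self.genome, self.model.arch, Xn)
        return preprocessing.denormalize(yn, norm.y_min, norm.y_max)

    def _evaluate(self) -> None:
        self.report_train = metrics.error_report(
            self.train_set.y, self.predict(self.train_set.X), "train")
        self.report_test = metrics.error_report(
            self.test_set.y, self.predict(self.test_set.X), "test")

    @property
    def optimal_fitness(self) -> float:
        """Final global-best fitness (normalized-scale training RMSE)."""
        return float(self.convergence_trace[-1])

    @property
    def final_train_mse(self) -> float:
        return float(self.loss_history[-1])

    def error_table(self) -> pd.DataFrame:
        return metrics.reports_to_frame([self.report_train, self.report_test])

    # -- attribution --------------------------------------------------
    def miv(self, on: str = "all") -> miv_mod.MIVResult:
        """Mean-impact-value report (``on`` = 'all' or 'train' rows)."""
        if on == "all":
            X = self.model.dataset.X
        elif on == "train":
            X = self.train_set.X
        else:
            raise ValueError("on must be 'all' or 'train'")
        return miv_mod.miv_report(self.predict, X, labels=REGION_LABELS)

    # -- reporting ----------------------------------------------------
    def summary(self) -> str:
        """Plain-text fit summary in the style of statistical model results."""
        lines = []
        a = self.model.arch
        lines.append("Plantar Soft-Tissue Stiffness Regression (PSO-GA-BP)")
        lines.append("=" * 60)
        lines.append(f"Samples: {self.model.dataset.n_samples} "
                     f"(train {self.train_set.n_samples} / test {self.test_set.n_samples}, "
                     f"{self.split_spec.mode})")
        lines.append(f"Network: {a.n_input}-{a.n_hidden}-{a.n_output} "
                     f"({a.hidden_activation}/{a.output_activation}), "
                     f"genome length {a.genome_length}")
        lines.append(f"Optimizer: PSO {self.optimizer_config.pso_iterations} it x "
                     f"{self.optimizer_config.pso_swarm_size} particles, "
                     f"GA {self.optimizer_config.ga_generations} gen; "
                     f"optimal fitness (train RMSE, normalized) = "
                     f"{self.optimal_fitness:.5f}")
        lines.append(f"Training: {len(self.loss_history) - 1} epochs, "
                     f"final MSE (normalized) = {self.final_train_mse:.3e}")
        lines.append("-" * 60)
        lines.append(self.error_table().to_string(index=False,
                                                  float_format=lambda v: f"{v:.2f}"))
        lines.append("-" * 60)
        lines.append("Top regions by MIV contribution:")
        top = self.miv().top(4)
        for _, row in top.iterrows():
            lines.append(f"  {row['region']:<14} {row['sign']} "
                         f"{row['contribution']:6.2f} %  (MIV {row['miv']:+.2f} N/m)")
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------
    def plot_convergence(self, ax=None):
        """Global-best fitness versus hybrid-optimizer iteration."""
        from . import plotting
        return plotting.plot_convergence(self.convergence_trace, ax=ax)

    def plot_predictions(self, ax=None):
        """Predicted versus actual stiffness for both splits."""
        from . import plotting
        return plotting.plot_predictions(
            self.train_set.y, self.predict(self.train_set.X),
            self.test_set.y, self.predict(self.test_set.X), ax=ax)

    def plot_contributions(self, ax=None):
        """Signed bar chart of MIV contribution rates per region."""
        from . import plotting
        return plotting.plot_contributions(self.miv(), ax=ax)

    # -- persistence --------------------------------------------------
    def save(self, path) -> None:
        """Serialize everything needed to reload and re-apply the model."""
        payload = {
            "architecture": self.model.arch.to_dict(),
            "genome": self.genome.tolist(),
            "initial_genome": self.initial_genome.tolist(),
            "normalizer": self.normalizer.to_dict(),
            "split_spec": self.split_spec.to_dict(),
            "optimizer_config": self.optimizer_config.to_dict(),
            "train_config": self.train_config.to_dict(),
            "convergence_trace": self.convergence_trace.tolist(),
            "loss_history": self.loss_history.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path, df: pd.DataFrame, target: str = "stiffness"
             ) -> "PlantarStiffnessResults":
        """Reload a saved fit and re-bind it to its cohort table.

        The stored split spec and seed reconstruct the same train/test
        partition, so evaluation and MIV reports are reproduced exactly.
        """
        d = json.loads(Path(path).read_text())
        arch = network.NetworkArchitecture.from_dict(d["architecture"])
        model = PlantarStiffnessModel.from_dataframe(df, target=target, arch=arch)
        split_spec = preprocessing.SplitSpec.from_dict(d["split_spec"])
        train_set, test_set = preprocessing.split(model.dataset, split_spec)
        results = cls(
            model=model,
            genome=np.asarray(d["genome"], dtype=float),
            initial_genome=np.asarray(d["initial_genome"], dtype=float),
            normalizer=preprocessing.NormalizationParams.from_dict(d["normalizer"]),
            split_spec=split_spec,
            optimizer_config=optimizer.OptimizerConfig.from_dict(d["optimizer_config"]),
            train_config=network.TrainConfig.from_dict(d["train_config"]),
            train_set=train_set, test_set=test_set,
            convergence_trace=np.asarray(d["convergence_trace"], dtype=float),
            loss_history=np.asarray(d["loss_history"], dtype=float),
        )
        results._evaluate()
        return results
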