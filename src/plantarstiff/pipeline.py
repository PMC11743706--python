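"""End-to-end run orchestration with a reproducibility manifest.

`run_pipeline` executes generate -> preprocess -> optimize -> train ->
evaluate -> MIV from a single YAML/dict configuration and writes every
artifact to a run directory:

    cohort.csv / cohort.json   synthetic cohort + generator config
    convergence.csv/.png       optimizer global-best fitness per iteration
    loss_history.csv           training MSE per epoch
    model.json                 genome, architecture, normalizer, split spec
    error_report.csv/.json     MBE / RMSE / max & mean REP per split
    miv.csv / miv.png          per-region MIV and contribution rates
    predictions.png            predicted vs actual scatter
    summary.txt                text summary of the fit
    manifest.json              config snapshot, seeds, version, checksums

A single global seed fans out to per-stage seeds (cohort, split,
optimizer) through `numpy.random.SeedSequence.spawn`, so each stage is
independently reproducible and a re-run of the manifest is bit-identical.
Floating-point artifacts are serialized at full precision; rounding only
happens in rendered tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import PlantarStiffnessModel, PlantarStiffnessResults
from .network import NetworkArchitecture, TrainConfig
from .optimizer import OptimizerConfig
from .preprocessing import SplitSpec
from .synthetic import CohortConfig, cohort_to_frame, generate_cohort, save_cohort

__all__ = ["stage_seeds", "run_pipeline", "ARTIFACTS"]

ARTIFACTS = ("cohort.csv", "convergence.csv", "model.json", "error_report.csv",
             "miv.csv", "loss_history.csv", "manifest.json")


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan a global seed out to per-stage seeds (< 2**31), deterministically."""
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("cohort", "split", "optimizer")
    return {name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(names, children)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _configs_from_dict(config: dict, seed: int):
    seeds = stage_seeds(seed)
    cohort_cfg = CohortConfig.from_dict(
        {**config.get("cohort", {}), "seed": seeds["cohort"]})
    split_cfg = SplitSpec.from_dict(
        {**config.get("split", {}), "seed": seeds["split"]})
    opt_cfg = OptimizerConfig.from_dict(
        {**config.get("optimizer", {}), "seed": seeds["optimizer"]})
    train_cfg = TrainConfig.from_dict(config.get("training", {}))
    arch = NetworkArchitecture.from_dict(config.get("network", {}))
    return cohort_cfg, split_cfg, opt_cfg, train_cfg, arch, seeds


def run_pipeline(config: dict | str | Path, seed: int, out_dir) -> Path:
    """Run the full pipeline and write all artifacts to ``out_dir``.

    ``config`` is a dict or a path to a YAML file with optional sections
    ``cohort``, ``split``, ``optimizer``, ``training``, ``network``; absent
    fields take the package defaults.  Returns the run directory.
    """
    if not isinstance(config, dict):
        import yaml
        config = yaml.safe_load(Path(config).read_text()) or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort_cfg, split_cfg, opt_cfg, train_cfg, arch, seeds = _configs_from_dict(
        config, seed)

    samples = generate_cohort(cohort_cfg)
    save_cohort(samples, out / "cohort.csv", cohort_cfg)
    df = cohort_to_frame(samples)

    model = PlantarStiffnessModel.from_dataframe(df, arch=arch)
    results = model.fit(optimizer_config=opt_cfg, train_config=train_cfg,
                        split_spec=split_cfg)

    pd.DataFrame({
        "iteration": np.arange(1, results.convergence_trace.size + 1),
        "best_fitness": results.convergence_trace,
    }).to_csv(out / "convergence.csv", index=False)
    pd.DataFrame({
        "epoch": np.arange(results.loss_history.size),
        "mse": results.loss_history,
    }).to_csv(out / "loss_history.csv", index=False)

    results.save(out / "model.json")

    results.error_table().to_csv(out / "error_report.csv", index=False)
    (out / "error_report.json").write_text(json.dumps(
        {r.set_label: r.to_dict() for r in
         (results.report_train, results.report_test)}, indent=2))

    miv_res = results.miv()
    miv_res.table.to_csv(out / "miv.csv", index=False)
    (out / "summary.txt").write_text(results.summary() + "\n")

    import matplotlib.pyplot as plt
    for name, plot in (("convergence.png", results.plot_convergence),
                       ("predictions.png", results.plot_predictions),
                       ("miv.png", results.plot_contributions)):
        ax = plot()
        ax.figure.savefig(out / name, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)

    manifest = {
        "package_version": __version__,
        "global_seed": seed,
        "stage_seeds": seeds,
        "config": {
            "cohort": cohort_cfg.to_dict(),
            "split": split_cfg.to_dict(),
            "optimizer": opt_cfg.to_dict(),
            "training": train_cfg.to_dict(),
            "network": arch.to_dict(),
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "checksums": {},
    }
    for name in ("cohort.csv", "convergence.csv", "loss_history.csv",
                 "model.json", "error_report.csv", "miv.csv"):
        manifest["checksums"][name] = _sha256(out / name)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
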