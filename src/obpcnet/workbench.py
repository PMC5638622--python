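"""Experiment orchestration: configs, pipelines, reports.

Ties the modules into the three experiments: the analytic coupling-space
sweep, its Monte Carlo validation, and the LIF verification/violation
runs.  Configurations are plain YAML; every stochastic stage carries an
explicit seed and a scale factor (grid step, realization counts) that is
recorded in the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lif_network import LIFNetworkSpec, run_named_test
from .sweep import (
    SweepGrid,
    drop_covariability_ids,
    mc_validate,
    per_constraint_profile,
    rates_only_ids,
    run_grid,
    subset_sweep,
    svd_structure,
)

log = logging.getLogger("obpcnet")

__all__ = ["RunConfig", "run_pipeline", "export_report"]

EXPERIMENTS = ("sweep", "mc_validate", "lif_baseline", "lif_tests", "smoke")


@dataclass
class RunConfig:
    """One experiment run: id, parameters, seeds, output directory."""

    experiment: str
    out_dir: str
    seed: int = 0
    # sweep parameters
    grid_step: float = 0.25
    mc_n_real: int = 500
    mc_max_tuples: int = 20
    # LIF parameters
    lif_n_real: int = 500
    lif_t_win: float = 1.0
    lif_tests: tuple = ("baseline", "test1", "test2", "test3")
    lif_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def _sweep_stage(cfg: RunConfig, out: Path):
    grid = SweepGrid.with_step(cfg.grid_step)
    result = run_grid(grid, checkpoint_path=out / "sweep_table.csv")
    summary = {
        "n_tuples": result.n_tuples,
        "admissible_fraction": result.admissible_fraction,
        "per_constraint": per_constraint_profile(result),
        "subset_fraction_8": subset_sweep(result, drop_covariability_ids()),
        "subset_fraction_4": subset_sweep(result, rates_only_ids()),
        "grid_step": cfg.grid_step,
    }
    if result.admissible_matrix().shape[0] >= 2:
        s = svd_structure(result)
        summary["svd"] = {
            "mean": s["mean"].tolist(),
            "singular_values": s["singular_values"].tolist(),
            "top2_variance_fraction": s["top2_variance_fraction"],
        }
    return result, summary


def run_pipeline(config: RunConfig) -> dict:
    """Execute one experiment end to end; write tables and a JSON summary.

    Re-running a completed config is a no-op (the summary file acts as the
    checkpoint); partial sweep tables are resumed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_path = out / f"{config.experiment}_summary.json"
    if summary_path.exists():
        log.info("experiment %s already complete in %s", config.experiment, out)
        with open(summary_path) as fh:
            return json.load(fh)

    config.to_yaml(out / "config.yaml")
    summary: dict = {"experiment": config.experiment, "seed": config.seed}

    if config.experiment in ("sweep", "smoke"):
        if config.experiment == "smoke":
            config.grid_step = max(config.grid_step, 1.0)
        _, s = _sweep_stage(config, out)
        summary.update(s)

    elif config.experiment == "mc_validate":
        result, s = _sweep_stage(config, out)
        validated = mc_validate(result, n_real=config.mc_n_real,
                                seed=config.seed,
                                max_tuples=config.mc_max_tuples)
        validated.save(out / "sweep_table_mc.csv")
        s["mc_validated_fraction"] = validated.mc_validated_fraction
        s["mc_n_real"] = config.mc_n_real
        summary.update(s)

    elif config.experiment in ("lif_baseline", "lif_tests"):
        tests = (("baseline",) if config.experiment == "lif_baseline"
                 else tuple(config.lif_tests))
        spec = LIFNetworkSpec().with_couplings(**config.lif_overrides)
        results = {}
        for tid in tests:
            r = run_named_test(tid, n_real=config.lif_n_real,
                               t_win=config.lif_t_win, seed=config.seed,
                               spec=spec)
            r["curves"].to_csv(out / f"lif_{tid}_curves.csv", index=False)
            results[tid] = {
                "violated": list(r["violated"]),
                "summaries": {f"{reg}_{st}": vars(s).copy()
                              for (reg, st), s in r["summaries"].items()},
                "rates_table": _rates_table(r["rasters"], spec),
            }
        summary["lif"] = results
        summary["lif_n_real"] = config.lif_n_real

    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _rates_table(rasters, spec: LIFNetworkSpec) -> dict:
    """Population mean +/- SD of per-cell firing rates, per region and state."""
    out = {}
    for state, raster in rasters.items():
        n_trials = max(len(raster.trials), 1)
        total = n_trials * raster.trial_length
        counts = raster.table.groupby("unit").size()
        for region, lo, hi in (("OB", 0, spec.ob.n),
                               ("PC", spec.ob.n, spec.ob.n + spec.pc.n)):
            rates = (counts.reindex(range(lo, hi), fill_value=0) / total)
            out[f"nu_{region}_{state}"] = {
                "mean_hz": float(rates.mean()), "sd_hz": float(rates.std())}
    return out


def export_report(results_dir, fmt: str = "csv", plots: bool = False) -> list:
    """Collect a completed run's outputs into tidy tables (and figures).

    Returns the list of files written.  Raises if the directory has no
    completed summary (no partial exports).
    """
    results_dir = Path(results_dir)
    summaries = sorted(results_dir.glob("*_summary.json"))
    if not summaries:
        raise FileNotFoundError(f"no completed experiment summary in {results_dir}")
    written = []
    for spath in summaries:
        with open(spath) as fh:
            summary = json.load(fh)
        rows = _flatten(summary)
        tidy = pd.DataFrame(rows, columns=["key", "value"])
        dest = spath.with_suffix(".report.csv")
        tidy.to_csv(dest, index=False)
        written.append(dest)
    table_path = results_dir / "sweep_table.csv"
    if plots and table_path.exists():
        written += _admissible_projections(table_path, results_dir)
    return written


def _flatten(d, prefix=""):
    rows = []
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            rows += _flatten(v, key + ".")
        elif isinstance(v, (list, tuple)):
            rows.append((key, json.dumps(v)))
        else:
            rows.append((key, v))
    return rows


def _admissible_projections(table_path, out_dir: Path) -> list:
    """2-D projections of the admissible set (pairs of coupling axes)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = pd.read_csv(table_path)
    adm = t[t["admissible"]]
    pairs = [("gIO", "gIP"), ("gEO", "gEP"), ("gIO", "gEP"), ("gIP", "gEO")]
    fig, axes = plt.subplots(2, 2, figsize=(8, 7))
    for ax, (xa, ya) in zip(axes.ravel(), pairs):
        ax.scatter(adm[xa], adm[ya], s=8, c="tab:blue")
        ax.set_xlabel(f"|{xa}|")
        ax.set_ylabel(f"|{ya}|")
        lim = max(t[xa].max(), t[ya].max())
        ax.set_xlim(0, lim * 1.05)
        ax.set_ylim(0, lim * 1.05)
        if {xa, ya} == {"gIO", "gIP"}:
            ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    fig.suptitle("Admissible coupling tuples (analytic classification)")
    fig.tight_layout()
    dest = out_dir / "admissible_projections.png"
    fig.savefig(dest, dpi=120)
    plt.close(fig)
    return [dest]
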