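"""MSE metrics, percent-change comparisons and benchmark report assembly.

Reporting conventions: per-environment MSEs are computed within each
outer fold and then averaged across folds (fold-then-mean, never pooled
records first); the "overall" cell pools each fold's test records across
environments before averaging the fold values; percent change between a
baseline and a method is 100 * (MSE_baseline - MSE_method) /
MSE_baseline, positive when the method improves on the baseline. Because
the change formula is not symmetric in its arguments, the raw MSEs are
always emitted alongside so either direction can be recomputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocols import ProtocolResult

__all__ = ["mse", "percent_mse_change", "BenchmarkReport", "build_report"]


def mse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Mean of squared differences."""
    obs = np.asarray(observed, float).ravel()
    pred = np.asarray(predicted, float).ravel()
    if len(obs) != len(pred):
        raise ValueError("observed and predicted lengths differ")
    if len(obs) == 0:
        raise ValueError("empty vectors")
    return float(np.mean((obs - pred) ** 2))


def percent_mse_change(mse_baseline: float, mse_method: float) -> float:
    """100 * (baseline - method) / baseline; positive = method better."""
    if mse_baseline <= 0 or mse_method <= 0:
        raise ValueError("MSEs must be positive for a percent comparison")
    return 100.0 * (mse_baseline - mse_method) / mse_baseline


@dataclass
class BenchmarkReport:
    """Fold-level MSE cells plus summaries for a set of protocol runs."""

    cells: pd.DataFrame        # method, environment, fold, mse
    summary: pd.DataFrame      # method, environment, mean_mse, se_mse, n_folds
    percent_change: pd.DataFrame  # baseline, method, overall percent change
    metadata: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "cells": self.cells.to_dict(orient="records"),
            "summary": self.summary.to_dict(orient="records"),
            "percent_change": self.percent_change.to_dict(orient="records"),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


def build_report(results: list[ProtocolResult], config: dict | None = None
                 ) -> BenchmarkReport:
    """Assemble the per-method, per-environment MSE grid.

    All results must come from the same split plan (same seed and fold
    count) so cells are comparable record-for-record.
    """
    if not results:
        raise ValueError("no results to report")
    seeds = {r.plan_seed for r in results}
    ks = {r.k for r in results}
    if len(seeds) > 1 or len(ks) > 1:
        raise ValueError("results come from different split plans")

    rows = []
    for res in results:
        for f in res.folds:
            rows.append((res.method, "overall", f.fold, f.mse))
            for env, v in f.per_env_mse.items():
                rows.append((res.method, env, f.fold, v))
    cells = pd.DataFrame(rows, columns=["method", "environment", "fold", "mse"])

    grouped = cells.groupby(["method", "environment"], sort=False)["mse"]
    summary = grouped.agg(
        mean_mse="mean",
        se_mse=lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v)))
        if len(v) > 1 else 0.0,
        n_folds="count",
    ).reset_index()

    overall = {
        res.method: float(np.mean([f.mse for f in res.folds]))
        for res in results
    }
    pc_rows = []
    for base, mb in overall.items():
        for meth, mm in overall.items():
            if base == meth:
                continue
            pc_rows.append((base, meth, mb, mm, percent_mse_change(mb, mm)))
    percent_change = pd.DataFrame(
        pc_rows,
        columns=["baseline", "method", "baseline_mse", "method_mse",
                 "pct_change"],
    )

    metadata = {"plan_seed": results[0].plan_seed, "k": results[0].k}
    if config:
        metadata["config"] = config
    return BenchmarkReport(cells=cells, summary=summary,
                           percent_change=percent_change, metadata=metadata)


def plot_report(report: BenchmarkReport, path) -> None:
    """Optional grouped bar chart of mean MSE per method and environment."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = report.summary
    envs = [e for e in summary["environment"].unique()]
    methods = list(summary["method"].unique())
    x = np.arange(len(envs))
    width = 0.8 / max(1, len(methods))
    fig, ax = plt.subplots(figsize=(1.8 * len(envs) + 2, 4))
    for i, m in enumerate(methods):
        sub = summary[summary["method"] == m].set_index("environment")
        vals = [sub.loc[e, "mean_mse"] if e in sub.index else np.nan
                for e in envs]
        errs = [sub.loc[e, "se_mse"] if e in sub.index else 0.0 for e in envs]
        ax.bar(x + i * width, vals, width, yerr=errs, capsize=3, label=m)
    ax.set_xticks(x + width * (len(methods) - 1) / 2)
    ax.set_xticklabels(envs)
    ax.set_ylabel("MSE")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
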