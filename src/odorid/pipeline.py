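"""End-to-end orchestration: simulate/load -> drift-correct -> validate ->
permutation-test, with CSV/JSON artifacts and figure analogues.

The pipeline reproduces the full analysis layout of an eNose identification
study on any table in the canonical schema: per-day within-day accuracies,
real-versus-null accuracy distributions, accumulated-day curves, and the
across-day holdout (train on all days but the last, test on the unseen day).
All acceptance-grade numbers are written as CSV/JSON; plots are convenience
artifacts only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import KNNConfig, LDAConfig, ModelConfig
from .datamodel import EndpointTable
from .io import read_endpoint_csv, write_endpoint_csv
from .preprocess import DriftCorrectionSpec, drift_correct, subset
from .simulate import CohortConfig, config_to_dict, simulate_cohort
from .stats import PermutationResult, permutation_test
from .validate import (
    FoldScheme,
    run_accumulated_days,
    run_across_day_holdout,
    run_loo,
    run_repeated_one_out_per_participant,
)

log = logging.getLogger("odorid")

#: Default model per region: fine KNN (k=2) for the ear, linear discriminant
#: for armpit and lower back — each region's best-performing classifier.
DEFAULT_MODELS: Mapping[str, ModelConfig] = {
    "ear": KNNConfig(k=2),
    "armpit": LDAConfig(),
    "back": LDAConfig(),
}

DRIFT_MODES = ("none", "fresh_control_division")


@dataclass
class PipelineConfig:
    """One reproducible run: data source, models, designs, iteration counts."""

    cohort: Optional[CohortConfig] = None
    csv_path: Optional[str] = None
    csv_dialect: str = "wide"
    models: Mapping[str, ModelConfig] = field(default_factory=lambda: dict(DEFAULT_MODELS))
    drift_modes: Sequence[str] = DRIFT_MODES
    n_iterations: int = 500
    n_null_iterations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.csv_path is None):
            raise ValueError("specify exactly one data source: cohort config or csv_path")


@dataclass
class PipelineResults:
    within_day: pd.DataFrame
    accumulated: pd.DataFrame
    holdout: pd.DataFrame
    permutation: pd.DataFrame
    distributions: dict  # (region, mode, stage) -> arrays, for plotting
    manifest: dict


def _model_name(config: ModelConfig) -> str:
    return "knn" if isinstance(config, KNNConfig) else "lda"


def _load_table(config: PipelineConfig) -> EndpointTable:
    if config.cohort is not None:
        table, _ = simulate_cohort(config.cohort)
        return table
    return read_endpoint_csv(config.csv_path, dialect=config.csv_dialect)


def run_pipeline(config: PipelineConfig, out_dir: Optional[str | Path] = None,
                 plots: bool = False) -> PipelineResults:
    """Run every stage; optionally write artifacts under *out_dir*."""
    table = _load_table(config)
    days = sorted(int(d) for d in table.frame["day"].unique())
    regions = [r for r in table.frame["region"].dropna().unique()]
    log.info("pipeline: %d rows, days=%s, regions=%s, seed=%d",
             len(table), days, regions, config.seed)

    within_rows, acc_rows, hold_rows, perm_rows = [], [], [], []
    distributions: dict = {}
    multi_day = len(days) >= 2
    if not multi_day:
        log.warning("single-day table: accumulated-day and holdout stages skipped")

    for mode in config.drift_modes:
        corrected = drift_correct(table, DriftCorrectionSpec(mode=mode))
        for region in regions:
            model = config.models.get(region, KNNConfig(k=2))
            regional = subset(corrected, regions=[region])
            # -- within-day stage (per-day LOO + repeated per-sample CV)
            for day in days:
                day_table = subset(regional, days=[day])
                loo = run_loo(day_table, model)
                per = run_repeated_one_out_per_participant(
                    day_table, model, n_iterations=config.n_iterations,
                    seed=_derive(config.seed, mode, region, day),
                )
                within_rows.append(
                    dict(region=region, drift=mode, day=day, model=_model_name(model),
                         loo_accuracy=loo.accuracies[0], cv_mean=per.mean,
                         cv_median=per.median, cv_sd=per.sd)
                )
                distributions[(region, mode, f"within_day_{day}")] = per.accuracies
            # -- permutation stage on best and worst day (by CV mean)
            if within_rows:
                sub = [r for r in within_rows
                       if r["region"] == region and r["drift"] == mode]
                for tag, pick in (("best", max), ("worst", min)):
                    day = pick(sub, key=lambda r: r["cv_mean"])["day"]
                    day_table = subset(regional, days=[day])
                    scheme = FoldScheme(kind="one_sample_per_participant_out",
                                        n_iterations=config.n_iterations,
                                        seed=_derive(config.seed, mode, region, day, tag))
                    res = permutation_test(day_table, model, scheme,
                                           n_iterations=config.n_null_iterations,
                                           seed=_derive(config.seed, mode, region, day, tag, "null"))
                    perm_rows.append(_perm_row(region, mode, f"within_day_{tag}", day, res))
                    distributions[(region, mode, f"null_{tag}")] = res.null_accuracies
            # -- accumulated-day and holdout stages
            if multi_day:
                acc = run_accumulated_days(
                    regional, model, n_iterations=config.n_iterations,
                    seed=_derive(config.seed, mode, region, "accumulate"),
                )
                for window, dist in acc.items():
                    acc_rows.append(
                        dict(region=region, drift=mode, days="-".join(map(str, window)),
                             n_days=len(window), model=_model_name(model),
                             cv_mean=dist.mean, cv_median=dist.median, cv_sd=dist.sd)
                    )
                    distributions[(region, mode, f"accumulated_{len(window)}")] = dist.accuracies
                train, test = days[:-1], days[-1]
                hold_acc = run_across_day_holdout(regional, model, train, test)
                scheme = FoldScheme(kind="day_holdout", train_days=tuple(train), test_day=test)
                res = permutation_test(
                    regional, model, scheme, n_iterations=config.n_null_iterations,
                    seed=_derive(config.seed, mode, region, "holdout"),
                )
                hold_rows.append(
                    dict(region=region, drift=mode, model=_model_name(model),
                         train_days="-".join(map(str, train)), test_day=test,
                         accuracy=hold_acc, permutation_p=res.p_value)
                )
                distributions[(region, mode, "holdout_null")] = res.null_accuracies
                perm_rows.append(_perm_row(region, mode, "holdout", test, res))

    results = PipelineResults(
        within_day=pd.DataFrame(within_rows),
        accumulated=pd.DataFrame(acc_rows),
        holdout=pd.DataFrame(hold_rows),
        permutation=pd.DataFrame(perm_rows),
        distributions=distributions,
        manifest=_manifest(config, table),
    )
    if out_dir is not None:
        write_results(results, out_dir, table=table, plots=plots)
    return results


def _perm_row(region, mode, stage, day, res: PermutationResult) -> dict:
    return dict(region=region, drift=mode, stage=stage, day=day,
                observed_median=res.observed_median, null_mean=res.null_mean,
                p_value=res.p_value, n_iterations=res.n_iterations)


def _derive(seed: int, *key) -> int:
    digest = hashlib.sha256(("|".join(map(str, (seed,) + key))).encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _manifest(config: PipelineConfig, table: EndpointTable) -> dict:
    source = (
        {"kind": "synthetic", "cohort": config_to_dict(config.cohort)}
        if config.cohort is not None
        else {"kind": "csv", "path": str(config.csv_path),
              "sha256": _file_sha(config.csv_path), "dialect": config.csv_dialect}
    )
    return {
        "software": {"name": "odorid", "version": __version__},
        "seed": config.seed,
        "n_iterations": config.n_iterations,
        "n_null_iterations": config.n_null_iterations,
        "models": {r: _model_name(m) for r, m in config.models.items()},
        "drift_modes": list(config.drift_modes),
        "n_rows": len(table),
        "source": source,
    }


def _file_sha(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(results: PipelineResults, out_dir: str | Path,
                  table: Optional[EndpointTable] = None, plots: bool = False) -> dict:
    """Write CSV/JSON artifacts (and optionally figures); returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("within_day", "accumulated", "holdout", "permutation"):
        frame = getattr(results, name)
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.12g")
        paths[name] = str(path)
    if table is not None:
        path = out / "endpoints.csv"
        write_endpoint_csv(table, path)
        paths["endpoints"] = str(path)
    manifest = dict(results.manifest, outputs=paths)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = str(out / "manifest.json")
    if plots:
        paths.update(report(results, out))
    return paths


def report(results: PipelineResults, out_dir: str | Path) -> dict:
    """Render figure analogues: per-day bars with the 1/C chance line, and
    real-vs-null histograms with median markers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not len(results.within_day):
        raise ValueError("no within-day results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    n_classes = _n_classes_from(results)
    chance = 1.0 / n_classes

    regions = list(results.within_day["region"].unique())
    modes = list(results.within_day["drift"].unique())
    fig, axes = plt.subplots(len(modes), len(regions),
                             figsize=(4 * len(regions), 3 * len(modes)), squeeze=False)
    for i, mode in enumerate(modes):
        for j, region in enumerate(regions):
            ax = axes[i][j]
            sub = results.within_day.query("region == @region and drift == @mode")
            ax.bar(sub["day"], sub["cv_mean"], yerr=sub["cv_sd"], color="tab:gray")
            ax.axhline(chance, ls="--", color="black",
                       label=f"chance {chance:.1%}")
            ax.set_ylim(0, 1)
            ax.set_title(f"{region} ({mode})", fontsize=9)
            ax.set_xlabel("day")
            ax.set_ylabel("accuracy")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    path = out / "fig_within_day.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    paths["fig_within_day"] = str(path)

    null_keys = [k for k in results.distributions if k[2].startswith("null_")]
    if null_keys:
        fig, axes = plt.subplots(1, len(null_keys),
                                 figsize=(3.2 * len(null_keys), 3), squeeze=False)
        for ax, key in zip(axes[0], null_keys):
            region, mode, stage = key
            null = results.distributions[key]
            ax.hist(null, bins=20, alpha=0.6, color="tab:blue", label="null")
            ax.axvline(float(np.median(null)), ls="--", color="tab:blue")
            perm = results.permutation
            row = perm[(perm["region"] == region) & (perm["drift"] == mode)
                       & (perm["stage"] == stage.replace("null_", "within_day_"))]
            if len(row):
                day = int(row.iloc[0]["day"])
                real = results.distributions.get((region, mode, f"within_day_{day}"))
                if real is not None:
                    ax.hist(real, bins=20, alpha=0.6, color="tab:orange", label="real")
                    ax.axvline(float(np.median(real)), ls="--", color="tab:orange")
            ax.set_title(f"{region} {mode} {stage}", fontsize=7)
        axes[0][0].legend(fontsize=7)
        fig.tight_layout()
        path = out / "fig_real_vs_null.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths["fig_real_vs_null"] = str(path)

    if len(results.accumulated):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for (region, mode), sub in results.accumulated.groupby(["region", "drift"]):
            ax.errorbar(sub["n_days"], sub["cv_mean"], yerr=sub["cv_sd"],
                        marker="o", label=f"{region}/{mode}")
        ax.axhline(chance, ls="--", color="black")
        ax.set_xlabel("days accumulated")
        ax.set_ylabel("mean accuracy")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = out / "fig_accumulated.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths["fig_accumulated"] = str(path)

    if len(results.holdout):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        labels = results.holdout["region"] + "/" + results.holdout["drift"]
        ax.bar(labels, results.holdout["accuracy"], color="tab:gray")
        ax.axhline(chance, ls="--", color="black")
        ax.set_ylabel("holdout accuracy")
        ax.tick_params(axis="x", labelrotation=45, labelsize=7)
        fig.tight_layout()
        path = out / "fig_holdout.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths["fig_holdout"] = str(path)
    return paths


def _n_classes_from(results: PipelineResults) -> int:
    manifest = results.manifest
    if manifest.get("source", {}).get("kind") == "synthetic":
        return int(manifest["source"]["cohort"]["n_participants"])
    # fall back: a null distribution's mean is ~1/C
    for key, arr in results.distributions.items():
        if "null" in key[2]:
            mean = float(np.mean(arr))
            if mean > 0:
                return max(2, round(1.0 / mean))
    return 12
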