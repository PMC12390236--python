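"""Experiment orchestration and result reporting.

Experiments sweep a grid of data scopes (single sensor x exercise, single
exercise, single device, or everything), prediction targets, model
families and cross-validation schemes, producing one metrics row per
cell. Symptom-severity results are visualized as one violin of predicted
values per true class (with per-class MAE annotations); overall-state
(TRS) results as a true-vs-predicted scatter with the identity line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as _stats

from .features import FeatureTable
from .modeling import (
    CVScheme,
    ModelSpec,
    PredictionSet,
    SelectionConfig,
    compute_metrics,
    cross_validate,
    discretize,
)

SCOPES = (
    "single-sensor-single-exercise",
    "single-exercise",
    "single-device",
    "all-data",
    "all-devices",
)


def _target_kind(target: str) -> str:
    return "trs" if target.startswith("trs") else "symptom"


def scope_column_sets(table: FeatureTable, scope: str) -> dict:
    """Map dataset labels (e.g. ``Phone-ACC-#1``) to column subsets for a
    scope. Metadata columns ride along in every subset."""
    meta = table.metadata_columns()
    sensor = table.sensor_columns()
    if scope in ("all-data", "all-devices"):
        return {"All": sensor + meta}
    if scope == "single-device":
        out = {}
        for device, label in (("phone", "Phone"), ("myo", "MYO")):
            cols = table.sensor_columns(device)
            if cols:
                out[label] = cols + meta
        return out
    if scope == "single-exercise":
        out = {}
        for ex in (1, 2, 3):
            cols = [c for c in sensor if f"-#{ex}/" in c]
            if cols:
                out[f"#{ex}"] = cols + meta
        return out
    if scope == "single-sensor-single-exercise":
        datasets = sorted({c.split("/", 1)[0] for c in sensor})
        return {d: [c for c in sensor if c.startswith(f"{d}/")] + meta
                for d in datasets}
    raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")


@dataclass
class ExperimentGrid:
    scopes: list = field(default_factory=lambda: ["all-data"])
    targets: list = field(default_factory=lambda: ["tremor"])
    models: list = field(default_factory=lambda: [ModelSpec("rf")])
    schemes: list = field(default_factory=lambda: [CVScheme("kfold-10")])
    selection: SelectionConfig | None = None


def run_grid(table: FeatureTable, grid: ExperimentGrid) -> pd.DataFrame:
    """One metrics row per (scope, dataset, target, model, scheme) cell.

    The best cell per (target, scheme) — highest R², ties broken by lower
    bMAE — is flagged in the ``best`` column. Deterministic given the
    seeds inside the grid's model and scheme specs.
    """
    rows = []
    for scope in grid.scopes:
        for dataset, cols in scope_column_sets(table, scope).items():
            sub = table.features[cols]
            for target in grid.targets:
                y = table.labels[target].to_numpy(float)
                for spec in grid.models:
                    for scheme in grid.schemes:
                        pred = cross_validate(
                            sub, y, spec, scheme,
                            patient_ids=table.patient_ids.to_numpy(),
                            target_kind=_target_kind(target),
                            selection=grid.selection,
                        )
                        report = compute_metrics(pred)
                        rows.append(
                            {
                                "scope": scope,
                                "dataset": dataset,
                                "target": target,
                                "model": spec.kind,
                                "scheme": scheme.kind,
                                "r2": report.r2,
                                "r": report.r,
                                "mae": report.mae,
                                "mse": report.mse,
                                "bmae": report.bmae,
                                "bmse": report.bmse,
                            }
                        )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["best"] = False
    for (_, _), block in result.groupby(["target", "scheme"]):
        ranked = block.sort_values(["r2", "bmae"], ascending=[False, True])
        result.loc[ranked.index[0], "best"] = True
    return result


def severity_violin_report(
    pred: PredictionSet, path: str | Path | None = None
) -> pd.DataFrame:
    """Violin of predicted values per true severity class, annotated with
    the per-class MAE; returns the per-class MAE table."""
    report = compute_metrics(pred)
    classes = sorted(report.per_class_mae)
    grid = discretize(pred.y_true, pred.target_kind)
    groups = [pred.y_pred[grid == k] for k in classes]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.violinplot(groups, positions=classes, widths=0.7, showmedians=True)
    for k in classes:
        ax.annotate(
            f"MAE {report.per_class_mae[k]:.2f}",
            (k, float(np.max(pred.y_pred)) if pred.y_pred.size else 0.0),
            ha="center", fontsize=8,
        )
    ax.set_xlabel("true severity")
    ax.set_ylabel("predicted severity")
    if path is not None:
        fig.savefig(path, dpi=120)
    plt.close(fig)
    return pd.DataFrame(
        {
            "class": classes,
            "mae": [report.per_class_mae[k] for k in classes],
            "n": [report.class_counts[k] for k in classes],
        }
    )


def trs_scatter_report(pred: PredictionSet, path: str | Path | None = None):
    """True-vs-predicted scatter for the -4..4 treatment-response scale,
    with the identity line; returns the figure axes limits and point count."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pred.y_true, pred.y_pred, s=12, alpha=0.6)
    ax.plot([-4, 4], [-4, 4], color="black", linewidth=1)
    ax.set_xlim(-4.3, 4.3)
    ax.set_ylim(-4.3, 4.3)
    ax.set_xlabel("true state")
    ax.set_ylabel("predicted state")
    if path is not None:
        fig.savefig(path, dpi=120)
    plt.close(fig)
    return {"n_points": int(pred.y_true.size), "xlim": (-4.3, 4.3)}


def compare_models_wilcoxon(scores_a, scores_b) -> dict:
    """Paired Wilcoxon signed-rank comparison of two models' per-cell
    scores (routine significance check, reported for completeness)."""
    stat, p = _stats.wilcoxon(np.asarray(scores_a), np.asarray(scores_b))
    return {"statistic": float(stat), "p_value": float(p)}
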