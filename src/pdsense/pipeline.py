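"""End-to-end study pipeline on the synthetic cohort.

Ties the stages together the way the analysis is meant to be run: generate
a labeled cohort, extract the feature bank, run the two-step feature
selection, and evaluate support-vector regression (the family that
performs best on this kind of data) under 10-fold and leave-one-patient-
out cross-validation, for individual symptoms and the overall-state TRS
targets, on all-device and single-device data scopes.

Problem sizes: the study runs use 200 patients with recordings from both
devices and both inertial sensors on the examined (right) hand for the
rest and pronation-supination exercises — the two exercises that carry
the tremor/dyskinesia and bradykinesia/stiffness information respectively
— and the greedy selection walks the top 40 ranked features. These sizes
keep a full run in the minutes range on one CPU while leaving every
stage's behavior intact.
"""

from __future__ import annotations

import numpy as np

from .cohort import SyntheticConfig, generate_cohort
from .features import BLOCK_CARDINALITIES, assemble_feature_table
from .modeling import (
    CVScheme,
    ModelSpec,
    build_model,
    compute_metrics,
    cross_validate,
)
from .selection import SelectionResult, prune_correlated, select_features

STUDY_N_PATIENTS = 200
STUDY_HANDS = ("right",)
STUDY_EXERCISES = (1, 3)
GREEDY_CANDIDATES = 40


def study_config(seed: int, n_patients: int = STUDY_N_PATIENTS) -> SyntheticConfig:
    """Default study conditions (generator defaults; reduced block grid)."""
    return SyntheticConfig(
        n_patients=n_patients,
        seed=seed,
        hands=STUDY_HANDS,
        exercises=STUDY_EXERCISES,
    )


def run_study(seed: int, n_patients: int = STUDY_N_PATIENTS) -> dict:
    """Run the full pipeline and return its headline quantities.

    Returns a flat dict with cross-validated R² / r / bMAE per target and
    scope, the feature-bank block cardinalities, and the cohort sizes
    actually used. Selection runs once globally per target (correlation
    pruning is unsupervised and shared across targets).
    """
    config = study_config(seed, n_patients)
    cohort = generate_cohort(config)
    table = assemble_feature_table(cohort)
    patient_ids = table.patient_ids.to_numpy()
    pruned = prune_correlated(table.features)

    model = ModelSpec("svm", seed=seed)
    kfold = CVScheme("kfold-10", seed=seed)
    loo = CVScheme("loo-by-patient", seed=seed)
    out = {
        "n_patients": n_patients,
        "n_examinations": int(table.features.shape[0]),
        "n_features": int(table.features.shape[1]),
        "n_features_after_pruning": len(pruned.retained_features),
    }
    for block, count in BLOCK_CARDINALITIES.items():
        out[f"features_per_recording_{block}"] = count

    def evaluate(target, kind, columns, scheme):
        features = table.features[columns]
        y = table.labels[target].to_numpy(float)
        colset = set(columns)
        sub_pruned = SelectionResult(
            retained_features=[
                c for c in pruned.retained_features if c in colset
            ],
            pruned_pairs=pruned.pruned_pairs,
        )
        sel = select_features(
            features, y, seed=seed, model=build_model(model),
            max_candidates=GREEDY_CANDIDATES, pruned=sub_pruned,
        )
        pred = cross_validate(
            features[sel.retained_features], y, model, scheme,
            patient_ids=patient_ids, target_kind=kind,
        )
        return compute_metrics(pred), sel

    all_cols = list(table.features.columns)
    meta = table.metadata_columns()

    m, sel_tremor = evaluate("tremor", "symptom", all_cols, kfold)
    out["tremor_r2_10f"] = m.r2
    out["tremor_bmae_10f"] = m.bmae
    pred_loo = cross_validate(
        table.features[sel_tremor.retained_features],
        table.labels["tremor"].to_numpy(float), model, loo,
        patient_ids=patient_ids, target_kind="symptom",
    )
    out["tremor_r2_loo"] = compute_metrics(pred_loo).r2

    m, _ = evaluate("dyskinesia", "symptom", all_cols, kfold)
    out["dyskinesia_r2_10f"] = m.r2
    out["dyskinesia_bmae_10f"] = m.bmae

    for scope, cols in (
        ("all", all_cols),
        ("phone", table.sensor_columns("phone") + meta),
        ("myo", table.sensor_columns("myo") + meta),
    ):
        m, _ = evaluate("trs_patient", "trs", cols, kfold)
        out[f"trs_patient_r2_{scope}"] = m.r2
    return out


def summarize(results: dict) -> str:
    lines = []
    for key, value in results.items():
        if isinstance(value, float):
            lines.append(f"{key:36s} {value: .3f}")
        else:
            lines.append(f"{key:36s} {value}")
    return "\n".join(lines)
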