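"""Regression models, cross-validation schemes and evaluation metrics.

Three regressor families are supported with their library defaults —
random forest, gradient-boosted trees (XGBoost) and an RBF-kernel support
vector regressor — each wrapped in a pipeline that z-normalizes features
on the training rows of the current fold only.

Evaluation covers the standard regression metrics (MSE, R², MAE,
Pearson r) plus class-balanced variants for imbalanced ordinal targets:
the true labels are discretized back to their grid (integers for the 0-4
symptom scores, 0.5 steps for the -4..4 treatment-response scale), MAE
and MSE are computed per class, and bMAE / bMSE average those per-class
errors over the classes present, weighting a rare severity-4 examination
as much as the abundant low-severity ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn import inspection as _inspection
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, LeaveOneGroupOut, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .selection import prune_correlated, select_features

MODEL_KINDS = ("rf", "xgb", "svm")
TARGET_RANGES = {"symptom": (0.0, 4.0), "trs": (-4.0, 4.0)}
CLASS_GRID_STEP = {"symptom": 1.0, "trs": 0.5}


@dataclass(frozen=True)
class ModelSpec:
    """One of the three regressor families, at library defaults."""

    kind: str = "rf"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")


@dataclass(frozen=True)
class CVScheme:
    kind: str = "kfold-10"  # or "stratified-kfold", "loo-by-patient"
    seed: int = 0
    n_splits: int = 10


@dataclass(frozen=True)
class SelectionConfig:
    """How feature selection participates in cross-validation.

    ``mode='global'`` runs the two-step selection once on the full table
    before splitting (the fast, leak-tolerant reading); ``mode='nested'``
    re-runs it inside every training fold, so the evaluation rows never
    influence which features are kept.
    """

    mode: str = "nested"
    max_candidates: int | None = None
    seed: int = 0


@dataclass
class PredictionSet:
    y_true: np.ndarray
    y_pred: np.ndarray
    fold_ids: np.ndarray
    target_kind: str = "symptom"
    fold_selections: list = field(default_factory=list)

    def __post_init__(self):
        self.y_true = np.asarray(self.y_true, dtype=float)
        self.y_pred = np.asarray(self.y_pred, dtype=float)
        self.fold_ids = np.asarray(self.fold_ids)
        if not (self.y_true.shape == self.y_pred.shape == self.fold_ids.shape):
            raise ValueError("y_true, y_pred and fold_ids must be equal length")


@dataclass
class MetricsReport:
    mse: float
    r2: float
    mae: float
    r: float
    per_class_mae: dict
    per_class_mse: dict
    class_counts: dict
    bmae: float
    bmse: float
    n_classes: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def build_model(spec: ModelSpec) -> Pipeline:
    """Scaler + regressor pipeline; the scaler is fitted per training fold."""
    if spec.kind == "rf":
        est = RandomForestRegressor(random_state=spec.seed, n_jobs=1)
    elif spec.kind == "xgb":
        est = XGBRegressor(random_state=spec.seed, n_jobs=1, verbosity=0)
    else:
        est = SVR()
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def fit_regressor(features: pd.DataFrame, labels, spec: ModelSpec) -> Pipeline:
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a regressor")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in features or labels")
    model = build_model(spec)
    model.fit(X, y)
    return model


def _folds(y: np.ndarray, groups, scheme: CVScheme, target_kind: str):
    n = len(y)
    if scheme.kind == "kfold-10":
        cv = KFold(n_splits=min(scheme.n_splits, n), shuffle=True,
                   random_state=scheme.seed)
        return list(cv.split(np.zeros(n)))
    if scheme.kind == "stratified-kfold":
        grid = discretize(y, target_kind)
        cv = StratifiedKFold(n_splits=min(scheme.n_splits, n), shuffle=True,
                             random_state=scheme.seed)
        return list(cv.split(np.zeros(n), grid))
    if scheme.kind == "loo-by-patient":
        if groups is None:
            raise ValueError("loo-by-patient requires patient ids")
        cv = LeaveOneGroupOut()
        return list(cv.split(np.zeros(n), groups=np.asarray(groups)))
    raise ValueError(f"unknown CV scheme {scheme.kind!r}")


def cross_validate(
    features: pd.DataFrame,
    labels,
    model_spec: ModelSpec,
    cv_scheme: CVScheme,
    patient_ids=None,
    target_kind: str = "symptom",
    selection: SelectionConfig | None = None,
) -> PredictionSet:
    """Out-of-fold predictions for every examination.

    Each row is predicted exactly once; leave-one-patient-out folds never
    split a patient across train and test. With a ``SelectionConfig`` the
    two-step feature selection runs globally once or nested per fold.
    """
    y = np.asarray(labels, dtype=float)
    folds = _folds(y, patient_ids, cv_scheme, target_kind)
    y_pred = np.full(len(y), np.nan)
    fold_ids = np.full(len(y), -1, dtype=int)
    fold_selections = []
    greedy_model = build_model(model_spec)
    global_cols = None
    pruned = None
    if selection is not None:
        pruned = prune_correlated(features)
        if selection.mode == "global":
            sel = select_features(
                features, y, seed=selection.seed, model=clone(greedy_model),
                max_candidates=selection.max_candidates, pruned=pruned,
            )
            global_cols = sel.retained_features
            fold_selections.append(sel)
    for k, (train, test) in enumerate(folds):
        if selection is not None and selection.mode == "nested":
            sel = select_features(
                features.iloc[train], y[train], seed=selection.seed,
                model=clone(greedy_model),
                max_candidates=selection.max_candidates, pruned=pruned,
            )
            cols = sel.retained_features
            fold_selections.append(sel)
        else:
            cols = global_cols if global_cols is not None else list(
                features.columns
            )
        model = build_model(model_spec)
        model.fit(features.iloc[train][cols].to_numpy(float), y[train])
        y_pred[test] = model.predict(features.iloc[test][cols].to_numpy(float))
        fold_ids[test] = k
    return PredictionSet(
        y_true=y, y_pred=y_pred, fold_ids=fold_ids, target_kind=target_kind,
        fold_selections=fold_selections,
    )


def discretize(y: np.ndarray, target_kind: str) -> np.ndarray:
    """Snap true labels back to their class grid (1 for symptoms, 0.5 for
    TRS). Predictions are never discretized."""
    step = CLASS_GRID_STEP[target_kind]
    return np.round(np.asarray(y, dtype=float) / step) * step


def compute_metrics(pred: PredictionSet) -> MetricsReport:
    """Standard and class-balanced regression metrics.

    A zero-variance truth (or prediction) vector makes R² / r undefined;
    they are reported as NaN with the ``degenerate`` flag set, never
    silently as 0.
    """
    yt, yp = pred.y_true, pred.y_pred
    if yt.size == 0:
        raise ValueError("empty prediction set")
    err = yt - yp
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    sst = float(np.sum((yt - yt.mean()) ** 2))
    degenerate = sst == 0.0 or np.std(yp) == 0.0
    r2 = float(1.0 - np.sum(err**2) / sst) if sst > 0 else float("nan")
    r = (
        float(np.corrcoef(yt, yp)[0, 1])
        if sst > 0 and np.std(yp) > 0
        else float("nan")
    )
    classes = discretize(yt, pred.target_kind)
    per_mae, per_mse, counts = {}, {}, {}
    for k in np.unique(classes):
        mask = classes == k
        per_mae[float(k)] = float(np.mean(np.abs(err[mask])))
        per_mse[float(k)] = float(np.mean(err[mask] ** 2))
        counts[float(k)] = int(mask.sum())
    return MetricsReport(
        mse=mse,
        r2=r2,
        mae=mae,
        r=r,
        per_class_mae=per_mae,
        per_class_mse=per_mse,
        class_counts=counts,
        bmae=float(np.mean(list(per_mae.values()))),
        bmse=float(np.mean(list(per_mse.values()))),
        n_classes=len(per_mae),
        degenerate=degenerate,
    )


def clip_predictions(pred: PredictionSet, bounds: tuple | None = None) -> PredictionSet:
    """Clip predictions to the target's valid range ([0, 4] for symptoms,
    [-4, 4] for TRS); order is preserved."""
    lo, hi = bounds if bounds is not None else TARGET_RANGES[pred.target_kind]
    return PredictionSet(
        y_true=pred.y_true,
        y_pred=np.clip(pred.y_pred, lo, hi),
        fold_ids=pred.fold_ids,
        target_kind=pred.target_kind,
        fold_selections=pred.fold_selections,
    )


def permutation_importance(
    model,
    features: pd.DataFrame,
    labels,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict:
    """Mean decrease in R² when each feature is shuffled, per feature name."""
    if len(features) < 2:
        raise ValueError("need at least 2 rows for permutation importance")
    result = _inspection.permutation_importance(
        model, features.to_numpy(float), np.asarray(labels, dtype=float),
        scoring="r2", n_repeats=n_repeats, random_state=seed,
    )
    return {
        name: float(score)
        for name, score in zip(features.columns, result.importances_mean)
    }
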