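"""Two-step feature selection.

Step one removes near-duplicate features: whenever two columns correlate
above |r| = 0.97, the later one (in canonical column order) is dropped.
Step two ranks the survivors with random-forest impurity importances,
keeps the top 60%, and then walks the ranking greedily: starting from the
most important feature, each candidate is added to the retained set only
if it strictly improves the model's cross-validated R².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_score

CORRELATION_THRESHOLD = 0.97
KEEP_FRACTION = 0.60
GREEDY_CV_FOLDS = 5


@dataclass
class SelectionResult:
    retained_features: list
    pruned_pairs: list = field(default_factory=list)  # (kept, dropped, r)
    ranking: dict = field(default_factory=dict)       # name -> importance
    cv_trace: list = field(default_factory=list)      # (name, score, retained)

    @property
    def retained_scores(self) -> list:
        """Cross-validated score after each retained greedy step."""
        return [s for _, s, kept in self.cv_trace if kept]


def _abs_corr(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    constant = sd == 0
    Xs = (X - X.mean(axis=0)) / np.where(constant, 1.0, sd)
    Xs[:, constant] = 0.0  # constant columns correlate with nothing
    corr = np.abs(Xs.T @ Xs) / X.shape[0]
    np.fill_diagonal(corr, 1.0)
    return corr


def prune_correlated(
    features: pd.DataFrame, threshold: float = CORRELATION_THRESHOLD
) -> SelectionResult:
    """Drop the later column of every pair with |Pearson r| > threshold.

    Deterministic given column order; constant columns are retained
    (their correlation is undefined and treated as 0).
    """
    if features.shape[0] < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    X = features.to_numpy(dtype=float)
    corr = _abs_corr(X)
    columns = list(features.columns)
    kept_idx: list = []
    pruned = []
    for j in range(len(columns)):
        if kept_idx:
            against = corr[j, kept_idx]
            offender = int(np.argmax(against))
            if against[offender] > threshold:
                pruned.append(
                    (columns[kept_idx[offender]], columns[j],
                     float(against[offender]))
                )
                continue
        kept_idx.append(j)
    return SelectionResult(
        retained_features=[columns[j] for j in kept_idx], pruned_pairs=pruned
    )


def rank_and_cut(
    features: pd.DataFrame,
    labels: np.ndarray,
    keep_fraction: float = KEEP_FRACTION,
    seed: int = 0,
) -> tuple:
    """Importance-rank features with a random forest; keep the top fraction.

    Returns ``(ordered_names, ranking_dict)``. The ranking forest uses
    sqrt-feature splits for tractability on wide tables; ties resolve to
    canonical column order (stable sort). Fewer than 2 features pass
    through unranked.
    """
    columns = list(features.columns)
    if len(columns) < 2:
        return columns, {c: 1.0 for c in columns}
    forest = RandomForestRegressor(
        n_estimators=100, max_features="sqrt", random_state=seed, n_jobs=1
    )
    forest.fit(features.to_numpy(dtype=float), np.asarray(labels, dtype=float))
    importances = forest.feature_importances_
    order = np.argsort(-importances, kind="stable")
    n_keep = ceil(keep_fraction * len(columns))
    ranked = [columns[i] for i in order[:n_keep]]
    ranking = {columns[i]: float(importances[i]) for i in order}
    return ranked, ranking


def _cv_score(model, X: np.ndarray, y: np.ndarray, seed: int) -> float:
    cv = KFold(n_splits=min(GREEDY_CV_FOLDS, len(y)), shuffle=True,
               random_state=seed)
    return float(np.mean(cross_val_score(model, X, y, cv=cv, scoring="r2")))


def greedy_forward_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    ranked: list,
    model=None,
    seed: int = 0,
    epsilon: float = 0.0,
) -> SelectionResult:
    """Greedy forward pass over the importance ranking.

    The most important feature is always retained; each subsequent
    candidate is kept only if adding it raises the cross-validated R² by
    more than ``epsilon`` (0 = strict improvement). ``model`` defaults to
    a seeded random forest; any scikit-learn regressor (or pipeline)
    works.
    """
    if not ranked:
        raise ValueError("ranked feature list is empty")
    if model is None:
        model = RandomForestRegressor(
            n_estimators=100, max_features="sqrt", random_state=seed, n_jobs=1
        )
    y = np.asarray(labels, dtype=float)
    retained = [ranked[0]]
    best = _cv_score(model, features[retained].to_numpy(float), y, seed)
    trace = [(ranked[0], best, True)]
    for name in ranked[1:]:
        candidate = retained + [name]
        score = _cv_score(model, features[candidate].to_numpy(float), y, seed)
        keep = score > best + epsilon
        trace.append((name, score, keep))
        if keep:
            retained = candidate
            best = score
    return SelectionResult(retained_features=retained, cv_trace=trace)


def select_features(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    model=None,
    threshold: float = CORRELATION_THRESHOLD,
    keep_fraction: float = KEEP_FRACTION,
    max_candidates: int | None = None,
    pruned: SelectionResult | None = None,
) -> SelectionResult:
    """Full two-step pipeline: prune, rank-and-cut, greedy forward pass.

    ``max_candidates`` optionally caps how far down the ranking the greedy
    pass walks; ``pruned`` lets callers reuse a precomputed (unsupervised)
    pruning result across targets.
    """
    if pruned is None:
        pruned = prune_correlated(features, threshold)
    surviving = features[pruned.retained_features]
    ranked, ranking = rank_and_cut(surviving, labels, keep_fraction, seed)
    if max_candidates is not None:
        ranked = ranked[:max_candidates]
    result = greedy_forward_select(surviving, labels, ranked, model, seed)
    result.pruned_pairs = pruned.pruned_pairs
    result.ranking = ranking
    return result
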