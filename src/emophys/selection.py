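"""Ensemble feature selection.

Every feature is scored by four importance algorithms:

* **CR** — the correlation ratio eta^2, between-class sum of squares over
  total sum of squares;
* **MI** — plug-in mutual information (nats) between the label and the
  feature discretised by equal-frequency binning (10 bins by default);
* **RF** — mean impurity-decrease importance of a 1000-tree Gini random
  forest;
* **SVML1** — mean absolute weight of an L1-regularised linear SVM
  (C = 1.0, one-vs-rest for more than two classes) fitted on
  standardised features.

Each algorithm's scores are min-max normalised to [0, 1], averaged, and
the features sorted descending by the mean; the top k (default 10) are
selected.  Ties are broken by the fixed registry order so rankings are
reproducible.

MI uses natural logarithms; any fixed base gives identical rankings
after min-max normalisation.  CR and MI are scale-invariant and the
forest scale-robust, so only the SVM sees standardised inputs;
zero-variance columns are dropped from the SVM fit and scored 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .registry import ALL_FEATURES

__all__ = [
    "ImportanceVector",
    "EnsembleRanking",
    "correlation_ratio",
    "mutual_information",
    "cr_importance",
    "mi_importance",
    "rf_importance",
    "svml1_importance",
    "minmax_normalize",
    "ensemble_rank",
    "rank_features",
]

ALGORITHMS = ("CR", "MI", "RF", "SVML1")


@dataclass
class ImportanceVector:
    """Non-negative per-feature scores from one selection algorithm."""

    algorithm: str
    scores: dict[str, float]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.scores.items() if not np.isfinite(v) or v < 0}
        if bad:
            raise ValueError(f"non-finite or negative importances: {bad}")


@dataclass
class EnsembleRanking:
    """Normalised, averaged and ranked importances of the four algorithms."""

    raw: dict[str, dict[str, float]]
    normalized: dict[str, dict[str, float]]
    mean_importance: dict[str, float]
    ranking: list[str] = field(default_factory=list)
    top_k: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.top_k)


def correlation_ratio(values, labels) -> float:
    """Correlation ratio eta^2 between a categorical label and a feature.

    Between-class sum of squares divided by the total sum of squares,
    both with squared deviations; defined as 0 when the total variance
    is zero.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if x.size != y.size or x.size == 0:
        raise ValueError("values and labels must be equal-length and non-empty")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("correlation ratio needs >= 2 label classes")
    grand = x.mean()
    total = float(np.sum((x - grand) ** 2))
    if total == 0.0:
        return 0.0
    between = 0.0
    for c in classes:
        xc = x[y == c]
        between += xc.size * (xc.mean() - grand) ** 2
    return float(between / total)


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Assign samples to equal-frequency bins (ties may merge bins)."""
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="left")


def mutual_information(values, labels, bins: int = 10) -> float:
    """Plug-in mutual information (nats) after equal-frequency binning."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if x.size != y.size or x.size < 2:
        raise ValueError("mutual information needs >= 2 paired samples")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    xb = _equal_frequency_bins(x, bins)
    joint = pd.crosstab(xb, y).to_numpy(dtype=float)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    mi = float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))
    return max(mi, 0.0)  # clip away negative rounding residue


def cr_importance(table: pd.DataFrame, labels) -> ImportanceVector:
    scores = {c: correlation_ratio(table[c].to_numpy(), labels) for c in table.columns}
    return ImportanceVector("CR", scores)


def mi_importance(table: pd.DataFrame, labels, bins: int = 10) -> ImportanceVector:
    scores = {
        c: mutual_information(table[c].to_numpy(), labels, bins) for c in table.columns
    }
    return ImportanceVector("MI", scores)


def rf_importance(
    table: pd.DataFrame, labels, n_trees: int = 1000, seed: int = 0
) -> ImportanceVector:
    """Impurity-decrease importances of a Gini random forest.

    1000 trees, unlimited depth, min-split 2, bootstrap resampling;
    importances are the forest's tree-averaged normalised impurity
    decreases and sum to 1.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("random forest importance needs >= 2 classes")
    if table.isna().to_numpy().any():
        raise ValueError("feature table passed to the forest contains missing values")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_depth=None,
        min_samples_split=2,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(table.to_numpy(), y)
    scores = dict(zip(table.columns, forest.feature_importances_.astype(float)))
    return ImportanceVector("RF", scores)


def svml1_importance(
    table: pd.DataFrame, labels, C: float = 1.0, seed: int = 0
) -> ImportanceVector:
    """Mean absolute weight of an L1-penalised linear SVM.

    Features are standardised before the fit (L1 weights are
    scale-dependent); zero-variance columns are dropped and scored 0.
    More than two classes are handled one-vs-rest and the importance of
    a feature is the mean of \\|w\\| across class vectors.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("SVM importance needs >= 2 classes")
    X = table.to_numpy(dtype=float)
    variances = X.var(axis=0)
    keep = variances > 0
    scores = {c: 0.0 for c in table.columns}
    if keep.any():
        Xs = StandardScaler().fit_transform(X[:, keep])
        svm = LinearSVC(
            penalty="l1", C=C, dual=False, max_iter=20000, random_state=seed
        )
        with warnings.catch_warnings():
            # near-converged weights rank features identically
            warnings.simplefilter("ignore", ConvergenceWarning)
            svm.fit(Xs, y)
        weights = np.mean(np.abs(np.atleast_2d(svm.coef_)), axis=0)
        for name, w in zip(np.asarray(table.columns)[keep], weights):
            scores[name] = float(w)
    return ImportanceVector("SVML1", scores)


def minmax_normalize(v: ImportanceVector | dict[str, float]) -> dict[str, float]:
    """Rescale scores so the maximum is 1 and the minimum 0.

    A constant vector maps to all zeros (degenerate range).
    """
    scores = v.scores if isinstance(v, ImportanceVector) else v
    if not scores:
        raise ValueError("cannot normalise an empty score map")
    values = np.array(list(scores.values()), dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return {k: 0.0 for k in scores}
    return {k: float((s - lo) / (hi - lo)) for k, s in scores.items()}


def ensemble_rank(
    vectors: list[ImportanceVector],
    k: int = 10,
    registry: tuple[str, ...] = ALL_FEATURES,
) -> EnsembleRanking:
    """Average the four normalised score maps and keep the top k.

    Ties in the mean importance are broken by position in ``registry``
    so the ranking is deterministic.
    """
    if len(vectors) != len(ALGORITHMS):
        raise ValueError(f"expected {len(ALGORITHMS)} importance vectors, got {len(vectors)}")
    feature_sets = [frozenset(v.scores) for v in vectors]
    if len(set(feature_sets)) != 1:
        raise ValueError("importance vectors cover mismatched feature sets")
    features = feature_sets[0]
    order = {name: i for i, name in enumerate(registry)}
    unknown = features - set(order)
    if unknown:
        # features outside the registry still rank, after registered ones
        for i, name in enumerate(sorted(unknown)):
            order[name] = len(registry) + i
    raw = {v.algorithm: dict(v.scores) for v in vectors}
    normalized = {alg: minmax_normalize(scores) for alg, scores in raw.items()}
    mean_importance = {
        f: float(np.mean([normalized[alg][f] for alg in raw])) for f in features
    }
    ranking = sorted(features, key=lambda f: (-mean_importance[f], order[f]))
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k must be in 1..{len(ranking)}, got {k}")
    return EnsembleRanking(
        raw=raw,
        normalized=normalized,
        mean_importance=mean_importance,
        ranking=ranking,
        top_k=ranking[:k],
    )


def rank_features(
    table: pd.DataFrame,
    labels,
    k: int = 10,
    bins: int = 10,
    n_trees: int = 1000,
    C: float = 1.0,
    seed: int = 0,
) -> EnsembleRanking:
    """Score a feature table with all four algorithms and rank.

    Rows containing any missing value are dropped (windowed features are
    undefined until their window fills) so every algorithm sees the same
    complete-case sample.
    """
    table = table.reset_index(drop=True)
    mask = ~table.isna().any(axis=1).to_numpy()
    complete = table.loc[mask].reset_index(drop=True)
    y = np.asarray(labels)[mask]
    vectors = [
        cr_importance(complete, y),
        mi_importance(complete, y, bins=bins),
        rf_importance(complete, y, n_trees=n_trees, seed=seed),
        svml1_importance(complete, y, C=C, seed=seed),
    ]
    return ensemble_rank(vectors, k=k)
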