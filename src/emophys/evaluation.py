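"""Cross-validated evaluation of emotion classifiers.

Feature combinations are organised into 21 groups: six fixed families
(#1 EEG, #2 MA15 EEG, #3 time-domain HRV, #4 frequency-domain HRV,
#5 TD+FD HRV, #6 all 36) plus the top-10 lists of each selection method
(ensemble, CR, MI, RF, SVML1) for each of the three tasks (#7–#21).

Each (group, task) cell is scored by stratified 10-fold cross-validation
of a feed-forward network — three 256-unit ReLU hidden layers, softmax
output, SGD optimiser, no dropout — with Macro F1 (the unweighted mean
over classes of the per-class harmonic mean of precision and recall) per
fold.  Features are standardised inside each fold using training-fold
statistics only.  The no-learning reference is a uniform-random
predictor over the observed class set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .labeling import TASKS
from .registry import ALL_FEATURES, EEG_BASE, EEG_MA15, HRV_FREQ, HRV_TIME

__all__ = [
    "FeatureGroup",
    "ModelSpec",
    "CVResult",
    "build_groups",
    "stratified_kfold",
    "macro_f1",
    "random_baseline",
    "make_classifier",
    "train_eval",
]

SELECTION_METHODS = ("ENSEMBLE", "CR", "MI", "RF", "SVML1")


@dataclass(frozen=True)
class FeatureGroup:
    id: int  # 1..21
    name: str
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"group {self.name!r} has duplicate features")


@dataclass
class ModelSpec:
    """Feed-forward classifier hyperparameters.

    The architecture (three 256-unit ReLU layers, softmax output, SGD,
    dropout 0) is fixed by design; training-loop parameters are
    configurable with conventional defaults.
    """

    hidden_layers: tuple[int, ...] = (256, 256, 256)
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_layers):
            raise ValueError("hidden layer sizes must be positive")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


@dataclass
class CVResult:
    """Per-fold Macro F1 for one (feature group, task) cell."""

    group_id: int
    group_name: str
    task: str
    fold_scores: list[float]
    n_samples: int
    n_features: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_scores))


def build_groups(rankings: dict[tuple[str, str], list[str]]) -> list[FeatureGroup]:
    """Assemble the 21 feature groups.

    Parameters
    ----------
    rankings
        ``{(method, task): top-10 feature list}`` for the five selection
        methods and three tasks (15 entries).
    """
    groups = [
        FeatureGroup(1, "EEG", EEG_BASE),
        FeatureGroup(2, "MA15 EEG", EEG_MA15),
        FeatureGroup(3, "TD HRV", HRV_TIME),
        FeatureGroup(4, "FD HRV", HRV_FREQ),
        FeatureGroup(5, "TD HRV + FD HRV", HRV_TIME + HRV_FREQ),
        FeatureGroup(6, "ALL", ALL_FEATURES),
    ]
    gid = 7
    for method in SELECTION_METHODS:
        for task in TASKS:
            try:
                selected = rankings[(method, task)]
            except KeyError:
                raise ValueError(f"missing ranking for method {method!r}, task {task!r}") from None
            unknown = [f for f in selected if f not in ALL_FEATURES]
            if unknown:
                raise ValueError(
                    f"ranking for ({method}, {task}) has unregistered features: {unknown}"
                )
            groups.append(FeatureGroup(gid, f"{method} ({task})", tuple(selected)))
            gid += 1
    return groups


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Disjoint stratified test-index sets covering all samples.

    Data of all participants are merged before splitting; per-class
    counts across folds differ by at most one.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValueError(
            f"class(es) {small.tolist()} have fewer than k={k} samples"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros((y.size, 1)), y)]


def macro_f1(y_true, y_pred) -> float:
    """Unweighted mean over classes of the per-class F1 score.

    The class set is taken from ``y_true``; a class never predicted (or
    absent from the fold) contributes F1 = 0.
    """
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.size == 0 or yt.size != yp.size:
        raise ValueError("label sequences must be non-empty and equal length")
    f1s = []
    for c in np.unique(yt):
        tp = float(np.sum((yt == c) & (yp == c)))
        fp = float(np.sum((yt != c) & (yp == c)))
        fn = float(np.sum((yt == c) & (yp != c)))
        if tp == 0.0:
            f1s.append(0.0)
            continue
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f1s.append(2 * precision * recall / (precision + recall))
    return float(np.mean(f1s))


def random_baseline(labels, n_rep: int = 200, seed: int = 0) -> tuple[float, float]:
    """Expected Macro F1 of a uniform-random, no-learning predictor.

    Predictions are drawn uniformly over the observed class set and
    Macro F1 averaged over ``n_rep`` repetitions.

    Returns
    -------
    (mean, standard error) of the Monte-Carlo estimate.
    """
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("labels must be non-empty")
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    scores = np.array(
        [macro_f1(y, rng.choice(classes, size=y.size)) for _ in range(n_rep)]
    )
    return float(scores.mean()), float(scores.std(ddof=1) / np.sqrt(n_rep))


def make_classifier(spec: ModelSpec) -> MLPClassifier:
    """Instantiate the feed-forward network for one fold."""
    return MLPClassifier(
        hidden_layer_sizes=spec.hidden_layers,
        activation="relu",
        solver="sgd",
        learning_rate_init=spec.learning_rate,
        batch_size=spec.batch_size,
        max_iter=spec.epochs,
        alpha=0.0,
        momentum=0.9,
        early_stopping=False,
        random_state=spec.seed,
    )


def train_eval(
    table: pd.DataFrame,
    labels,
    group: FeatureGroup,
    task: str,
    spec: ModelSpec | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Cross-validate the classifier on one feature group.

    Rows with a missing value in any of the group's features are dropped
    before splitting.  Within each fold the features are standardised
    with statistics of the training part only, the network fitted on the
    training part and Macro F1 computed on the held-out part.
    """
    spec = spec or ModelSpec()
    missing = [f for f in group.features if f not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    X_all = table[list(group.features)].to_numpy(dtype=float)
    y_all = np.asarray(labels)
    keep = ~np.isnan(X_all).any(axis=1)
    X_all, y_all = X_all[keep], y_all[keep]
    folds = stratified_kfold(y_all, k=k, seed=seed)
    all_idx = np.arange(y_all.size)
    scores = []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        if np.unique(y_all[train_idx]).size < 2:
            raise ValueError("degenerate training fold with a single class")
        scaler = StandardScaler().fit(X_all[train_idx])
        clf = make_classifier(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter at small epoch budgets
            clf.fit(scaler.transform(X_all[train_idx]), y_all[train_idx])
        y_pred = clf.predict(scaler.transform(X_all[test_idx]))
        scores.append(macro_f1(y_all[test_idx], y_pred))
    return CVResult(
        group_id=group.id,
        group_name=group.name,
        task=task,
        fold_scores=scores,
        n_samples=int(y_all.size),
        n_features=len(group.features),
    )
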