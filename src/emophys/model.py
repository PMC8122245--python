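"""Model/Results interface over the full pipeline.

:class:`EmotionStudy` is built from an extracted feature table and a
trial label table; :meth:`EmotionStudy.fit` runs the cross-validated
evaluation over feature groups and tasks and returns an
:class:`EmotionResults` holding every cell's fold scores, the random
baselines, and a ``summary()`` table.

Typical use::

    study = simulate_study(SimConfig(seed=1))
    model = EmotionStudy.from_study(study)
    rankings = {task: model.rank(task) for task in TASKS}
    results = model.fit()          # all 21 groups x 3 tasks
    print(results.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import selection
from .evaluation import (
    CVResult,
    FeatureGroup,
    ModelSpec,
    build_groups,
    random_baseline,
    train_eval,
)
from .features import extract_features, read_study_dir
from .labeling import TASKS, label_table, task_labels
from .registry import ALL_FEATURES
from .selection import EnsembleRanking

__all__ = ["EmotionStudy", "EmotionResults", "run_experiment"]


class EmotionStudy:
    """Emotion-classification model over a feature table and labels.

    Parameters
    ----------
    features
        Tidy table with ``pid, trial, time_s`` keys and the 36 feature
        columns (one row per second of stimulus).
    labels
        Per-trial table with ``pid, trial, quadrant, arousal_class,
        valence_class``.
    """

    def __init__(self, features: pd.DataFrame, labels: pd.DataFrame):
        missing = [c for c in ALL_FEATURES if c not in features.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        self.features = features.reset_index(drop=True)
        merged = self.features[["pid", "trial"]].merge(labels, on=["pid", "trial"], how="left")
        if merged["quadrant"].isna().any():
            raise ValueError("some feature rows have no matching trial label")
        self.labels = merged  # one row per feature row
        self._rankings: dict[str, EnsembleRanking] = {}

    # -- constructors -------------------------------------------------
    @classmethod
    def from_study(cls, study, convention: str = "threshold") -> "EmotionStudy":
        """Extract features and labels from a simulated study."""
        feats = extract_features(study.trials, study.config.span, study.config.eeg_rate)
        labs = label_table(study.sam_table, convention)
        return cls(feats, labs)

    @classmethod
    def from_directory(cls, path: str | Path, span=None, convention: str = "threshold") -> "EmotionStudy":
        """Read stream CSVs (synthetic-module layout) and build the model."""
        trials, sam, stored_span = read_study_dir(path)
        span = span or stored_span
        if span is None:
            raise ValueError("no labelled span stored with the streams; pass span=")
        if sam is None:
            raise ValueError("sam.csv not found alongside the streams")
        feats = extract_features(trials, tuple(span))
        return cls(feats, label_table(sam, convention))

    # -- selection ----------------------------------------------------
    def rank(self, task: str, k: int = 10, **kw) -> EnsembleRanking:
        """Ensemble feature ranking for one task (cached per task)."""
        key = f"{task}|{k}|{sorted(kw.items())}"
        if key not in self._rankings:
            y = task_labels(self.labels, task)
            self._rankings[key] = selection.rank_features(
                self.features[list(ALL_FEATURES)], y, k=k, **kw
            )
        return self._rankings[key]

    def method_rankings(self, k: int = 10, **kw) -> dict[tuple[str, str], list[str]]:
        """Top-k lists for every (selection method, task) pair."""
        out: dict[tuple[str, str], list[str]] = {}
        for task in TASKS:
            ens = self.rank(task, k=k, **kw)
            out[("ENSEMBLE", task)] = list(ens.top_k)
            for alg, scores in ens.normalized.items():
                order = {name: i for i, name in enumerate(ALL_FEATURES)}
                ranked = sorted(scores, key=lambda f: (-scores[f], order[f]))
                out[({"CR": "CR", "MI": "MI", "RF": "RF", "SVML1": "SVML1"}[alg], task)] = ranked[:k]
        return out

    def build_groups(self, k: int = 10, **kw) -> list[FeatureGroup]:
        """The 21 canonical feature groups for this dataset."""
        return build_groups(self.method_rankings(k=k, **kw))

    # -- fitting ------------------------------------------------------
    def fit(
        self,
        groups: list[FeatureGroup] | None = None,
        tasks: tuple[str, ...] = TASKS,
        spec: ModelSpec | None = None,
        k: int = 10,
        seed: int = 0,
        baseline_reps: int = 200,
    ) -> "EmotionResults":
        """Cross-validate every (group, task) cell and score baselines."""
        groups = groups if groups is not None else self.build_groups()
        spec = spec or ModelSpec(seed=seed)
        cells = []
        for task in tasks:
            y = task_labels(self.labels, task)
            for group in groups:
                cells.append(train_eval(self.features, y, group, task, spec, k=k, seed=seed))
        baselines = {}
        for task in tasks:
            y = task_labels(self.labels, task)
            mean, se = random_baseline(y, n_rep=baseline_reps, seed=seed)
            baselines[task] = {"mean": mean, "se": se}
        return EmotionResults(cells=cells, baselines=baselines, spec=spec, k=k, seed=seed)


@dataclass
class EmotionResults:
    """Cross-validation results over feature groups and tasks."""

    cells: list[CVResult]
    baselines: dict[str, dict[str, float]]
    spec: ModelSpec
    k: int
    seed: int
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        """One row per cell: group, task, mean and sd of fold Macro F1."""
        rows = [
            {
                "group_id": c.group_id,
                "group": c.group_name,
                "task": c.task,
                "mean_macro_f1": c.mean,
                "sd_macro_f1": c.std,
                "n_samples": c.n_samples,
                "n_features": c.n_features,
                "baseline": self.baselines[c.task]["mean"],
            }
            for c in self.cells
        ]
        return pd.DataFrame(rows)

    def fold_frame(self) -> pd.DataFrame:
        """Long table of per-fold scores (group, task, fold, macro_f1)."""
        rows = []
        for c in self.cells:
            for i, s in enumerate(c.fold_scores):
                rows.append(
                    {"group_id": c.group_id, "group": c.group_name, "task": c.task,
                     "fold": i, "macro_f1": s}
                )
        return pd.DataFrame(rows)

    def best(self, task: str) -> CVResult:
        """Best-scoring group for a task (argmax of the mean)."""
        candidates = [c for c in self.cells if c.task == task]
        if not candidates:
            raise ValueError(f"no results for task {task!r}")
        return max(candidates, key=lambda c: c.mean)

    def to_json(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "baselines": self.baselines,
            "best": {
                task: {"group": self.best(task).group_name, "mean": self.best(task).mean}
                for task in self.baselines
            },
            "cells": [
                {
                    "group_id": c.group_id,
                    "group": c.group_name,
                    "task": c.task,
                    "fold_scores": c.fold_scores,
                    "mean": c.mean,
                    "sd": c.std,
                }
                for c in self.cells
            ],
        }

    def save(self, outdir: str | Path) -> None:
        """Persist results.csv (per-fold), summary.json and a run log."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fold_frame().to_csv(outdir / "results.csv", index=False)
        (outdir / "summary.json").write_text(json.dumps(self.to_json(), indent=1))
        (outdir / "run.log").write_text(
            f"seed={self.seed} k={self.k} spec={self.spec}\n"
        )

    def plot(self, task: str, ax=None):
        """Bar chart of mean Macro F1 per group with sd error bars."""
        import matplotlib.pyplot as plt

        cells = [c for c in self.cells if c.task == task]
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        names = [c.group_name for c in cells]
        means = [c.mean for c in cells]
        sds = [c.std for c in cells]
        ax.bar(range(len(cells)), means, yerr=sds, color="steelblue")
        ax.axhline(self.baselines[task]["mean"], ls="--", color="grey", label="random baseline")
        ax.set_xticks(range(len(cells)), names, rotation=90)
        ax.set_ylabel("Macro F1")
        ax.set_title(f"task: {task}")
        ax.legend()
        return ax


def run_experiment(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    spec: ModelSpec | None = None,
    k: int = 10,
    seed: int = 0,
    tasks: tuple[str, ...] = TASKS,
    select_kw: dict | None = None,
) -> EmotionResults:
    """Full result matrix: 21 feature groups x the requested tasks."""
    model = EmotionStudy(features, labels)
    groups = model.build_groups(**(select_kw or {}))
    return model.fit(groups=groups, tasks=tasks, spec=spec, k=k, seed=seed)
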