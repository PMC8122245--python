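"""Feature groups, cross-validation, Macro F1, baselines, experiment matrix."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import f1_score

import emophys.evaluation as ev
from emophys.evaluation import (
    CVResult,
    FeatureGroup,
    ModelSpec,
    build_groups,
    macro_f1,
    random_baseline,
    stratified_kfold,
    train_eval,
)
from emophys.labeling import TASKS
from emophys.model import EmotionStudy, run_experiment
from emophys.registry import ALL_FEATURES

# ------------------------------------------------------------------ groups


def _dummy_rankings():
    top10 = list(ALL_FEATURES[:10])
    return {
        (m, t): top10
        for m in ("ENSEMBLE", "CR", "MI", "RF", "SVML1")
        for t in TASKS
    }


def test_build_groups_structure():
    groups = build_groups(_dummy_rankings())
    assert len(groups) == 21
    assert [g.id for g in groups] == list(range(1, 22))
    by_name = {g.name: g for g in groups}
    assert by_name["FD HRV"].features == ("lf", "hf", "lf_hf")
    assert len(by_name["ALL"].features) == 36
    assert len(by_name["EEG"].features) == 11
    assert len(by_name["MA15 EEG"].features) == 11
    assert len(by_name["TD HRV"].features) == 11
    assert len(by_name["TD HRV + FD HRV"].features) == 14
    for g in groups[6:]:
        assert len(g.features) == 10


def test_build_groups_missing_ranking_errors():
    rankings = _dummy_rankings()
    del rankings[("MI", "valence")]
    with pytest.raises(ValueError, match="MI"):
        build_groups(rankings)


def test_feature_group_validation():
    rankings = _dummy_rankings()
    rankings[("CR", "arousal")] = ["lf", "nope"]
    with pytest.raises(ValueError, match="nope"):
        build_groups(rankings)
    with pytest.raises(ValueError):
        FeatureGroup(1, "dup", ("lf", "lf"))


# -------------------------------------------------------------------- folds


def test_stratified_folds_pigeonhole():
    y = np.repeat(["a", "b", "c", "d"], 25)
    folds = stratified_kfold(y, k=10, seed=0)
    assert len(folds) == 10
    for fold in folds:
        assert len(fold) == 10
        _, counts = np.unique(y[fold], return_counts=True)
        assert set(counts) <= {2, 3}


def test_stratified_folds_partition_and_determinism():
    y = np.array(["a"] * 40 + ["b"] * 60)
    folds = stratified_kfold(y, k=10, seed=3)
    flat = np.concatenate(folds)
    assert np.array_equal(np.sort(flat), np.arange(100))  # disjoint cover
    again = stratified_kfold(y, k=10, seed=3)
    for f1_, f2_ in zip(folds, again):
        assert np.array_equal(f1_, f2_)


def test_stratified_folds_balance_within_one():
    y = np.array(["a"] * 37 + ["b"] * 63)
    for fold in stratified_kfold(y, k=10, seed=0):
        n_a = int(np.sum(y[fold] == "a"))
        assert abs(n_a - 3.7) <= 1.0


def test_stratified_folds_small_class_named_in_error():
    y = np.array(["rare"] * 4 + ["common"] * 96)
    with pytest.raises(ValueError, match="rare"):
        stratified_kfold(y, k=10)


# ----------------------------------------------------------------- macro F1


def test_macro_f1_hand_cases():
    assert macro_f1(["A", "B"], ["A", "B"]) == 1.0
    assert macro_f1(list("AABB"), list("ABBB")) == pytest.approx(1.4666666 / 2, abs=1e-6)
    assert macro_f1(list("ABAB"), list("AAAA")) == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        macro_f1([], [])


def _oracle_macro_f1(y_true, y_pred):
    """Explicit confusion-matrix recomputation."""
    scores = []
    for c in sorted(set(y_true)):
        tp = sum(t == c and p == c for t, p in zip(y_true, y_pred))
        fp = sum(t != c and p == c for t, p in zip(y_true, y_pred))
        fn = sum(t == c and p != c for t, p in zip(y_true, y_pred))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        scores.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return sum(scores) / len(scores)


def test_macro_f1_matches_oracles(rng):
    for _ in range(200):
        n = int(rng.integers(2, 40))
        classes = list("ABCD")[: int(rng.integers(2, 5))]
        y_true = rng.choice(classes, size=n)
        y_pred = rng.choice(classes, size=n)
        ours = macro_f1(y_true, y_pred)
        assert ours == pytest.approx(_oracle_macro_f1(list(y_true), list(y_pred)), abs=1e-12)
        theirs = f1_score(y_true, y_pred, labels=sorted(set(y_true)), average="macro", zero_division=0)
        assert ours == pytest.approx(theirs, abs=1e-12)


# ----------------------------------------------------------------- baseline


def _closed_form_baseline(counts):
    n = sum(counts)
    k = len(counts)
    return sum(2 * (c / n) * (1 / k) / (c / n + 1 / k) for c in counts) / k


def test_random_baseline_closed_forms():
    y4 = np.repeat(["a", "b", "c", "d"], 50)
    mean, se = random_baseline(y4, n_rep=200, seed=0)
    assert mean == pytest.approx(0.25, abs=max(4 * se, 0.02))
    y2 = np.repeat(["a", "b"], 100)
    mean2, se2 = random_baseline(y2, n_rep=200, seed=0)
    assert mean2 == pytest.approx(0.5, abs=max(4 * se2, 0.02))


def test_random_baseline_unbalanced_closed_form():
    counts = (30, 50, 120)
    y = np.repeat(["a", "b", "c"], counts)
    mean, se = random_baseline(y, n_rep=300, seed=1)
    assert mean == pytest.approx(_closed_form_baseline(counts), abs=max(4 * se, 0.02))
    with pytest.raises(ValueError):
        random_baseline([], 10)


# --------------------------------------------------------------- train_eval

_FAST = ModelSpec(hidden_layers=(16,), epochs=40, batch_size=16, seed=0)


def _blob_table(rng, n_per=150, informative=2, noise=0):
    cols = {}
    y = np.array(["p"] * n_per + ["q"] * n_per)
    shift = np.where(y == "p", 2.5, -2.5)
    for i in range(informative):
        cols[f"inf{i}"] = rng.normal(size=2 * n_per) + shift
    for i in range(noise):
        cols[f"noise{i}"] = rng.normal(size=2 * n_per)
    return pd.DataFrame(cols), y


def test_train_eval_separable_data_scores_high(rng):
    X, y = _blob_table(rng)
    group = FeatureGroup(1, "blobs", ("inf0", "inf1"))
    res = train_eval(X, y, group, "arousal", _FAST, k=5, seed=0)
    assert res.mean >= 0.9
    assert len(res.fold_scores) == 5
    assert min(res.fold_scores) <= res.mean <= max(res.fold_scores)


def test_train_eval_standardizes_on_training_folds_only(rng, monkeypatch):
    """The scaler must never see held-out rows."""
    X, y = _blob_table(rng, n_per=50)
    fit_sizes = []
    original = ev.StandardScaler.fit

    def spy(self, data, *a, **kw):
        fit_sizes.append(len(data))
        return original(self, data, *a, **kw)

    monkeypatch.setattr(ev.StandardScaler, "fit", spy)
    train_eval(X, y, FeatureGroup(1, "blobs", ("inf0", "inf1")), "arousal", _FAST, k=5, seed=0)
    assert fit_sizes == [80] * 5  # 100 rows, 5 folds -> 80 training rows each


def test_train_eval_null_labels_score_near_baseline(rng):
    X = pd.DataFrame(rng.normal(size=(400, 3)), columns=list("abc"))
    y = rng.permutation(["p", "q"] * 200)
    res = train_eval(X, y, FeatureGroup(1, "noise", ("a", "b", "c")), "arousal", _FAST, k=5, seed=0)
    base_mean, base_se = random_baseline(y, n_rep=200, seed=0)
    tol = 3 * np.sqrt(res.std**2 / len(res.fold_scores) + base_se**2)
    assert abs(res.mean - base_mean) <= max(tol, 0.1)


def test_train_eval_noise_features_do_not_help(rng):
    X, y = _blob_table(rng, noise=4)
    lean = train_eval(X, y, FeatureGroup(1, "lean", ("inf0", "inf1")), "arousal", _FAST, k=5, seed=0)
    fat = train_eval(
        X, y,
        FeatureGroup(2, "fat", ("inf0", "inf1", "noise0", "noise1", "noise2", "noise3")),
        "arousal", _FAST, k=5, seed=0,
    )
    pooled = np.sqrt(lean.std**2 / 5 + fat.std**2 / 5)
    assert fat.mean <= lean.mean + 3 * max(pooled, 0.01)


def test_train_eval_drops_rows_with_missing_group_values(rng):
    X, y = _blob_table(rng, n_per=60)
    X.loc[:9, "inf0"] = np.nan
    res = train_eval(X, y, FeatureGroup(1, "g", ("inf0", "inf1")), "arousal", _FAST, k=5, seed=0)
    assert res.n_samples == 110
    with pytest.raises(ValueError):
        train_eval(X, y, FeatureGroup(1, "g", ("inf0", "missing_col")), "arousal", _FAST, k=5)


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(hidden_layers=(0,))
    with pytest.raises(ValueError):
        ModelSpec(epochs=0)
    spec = ModelSpec()
    assert spec.hidden_layers == (256, 256, 256)


# ----------------------------------------------------- experiment orchestra


def _tiny_dataset(rng, n_trials=40, rows_per_trial=8):
    quads = np.array((["HAHV", "HALV", "LALV", "LAHV"] * (n_trials // 4)))
    rows = []
    labels = []
    for trial, quad in enumerate(quads):
        labels.append(
            {"pid": 0, "trial": trial, "quadrant": quad,
             "arousal_class": "High" if quad.startswith("HA") else "Low",
             "valence_class": "High" if quad.endswith("HV") else "Low"}
        )
        shift = {"HAHV": 2.0, "HALV": 1.0, "LALV": -1.0, "LAHV": -2.0}[quad]
        for second in range(rows_per_trial):
            row = {"pid": 0, "trial": trial, "time_s": second + 1}
            for i, name in enumerate(ALL_FEATURES):
                row[name] = rng.normal() + (shift if i < 4 else 0.0)
            rows.append(row)
    return pd.DataFrame(rows), pd.DataFrame(labels)


def test_run_experiment_matrix_and_determinism(rng):
    feats, labels = _tiny_dataset(rng)
    spec = ModelSpec(hidden_layers=(8,), epochs=10, batch_size=32, seed=0)
    kw = dict(spec=spec, k=3, seed=0, select_kw={"n_trees": 30})
    res = run_experiment(feats, labels, **kw)
    summary = res.summary()
    assert len(summary) == 21 * 3  # 63 cells
    assert set(res.baselines) == set(TASKS)
    again = run_experiment(feats, labels, **kw)
    pd.testing.assert_frame_equal(summary, again.summary())
    for task in TASKS:
        best = res.best(task)
        task_cells = summary[summary["task"] == task]
        assert best.mean == task_cells["mean_macro_f1"].max()


def test_results_persist_and_reload(tmp_path, rng):
    feats, labels = _tiny_dataset(rng, n_trials=16)
    spec = ModelSpec(hidden_layers=(8,), epochs=5, seed=0)
    model = EmotionStudy(feats, labels)
    groups = [FeatureGroup(1, "EEG", tuple(ALL_FEATURES[:11]))]
    res = model.fit(groups=groups, tasks=("arousal",), spec=spec, k=4, seed=0)
    res.save(tmp_path)
    persisted = pd.read_csv(tmp_path / "results.csv")
    assert len(persisted) == 4  # one row per fold
    import json

    summary = json.loads((tmp_path / "summary.json").read_text())
    assert summary["cells"][0]["mean"] == pytest.approx(res.cells[0].mean)


def test_model_rejects_unlabelled_rows(rng):
    feats, labels = _tiny_dataset(rng, n_trials=8)
    with pytest.raises(ValueError):
        EmotionStudy(feats, labels[labels["trial"] > 3])


def test_method_rankings_cover_methods_and_tasks(tiny_model):
    rankings = tiny_model.method_rankings(n_trees=30, seed=0)
    assert set(rankings) == {(m, t) for m in ("ENSEMBLE", "CR", "MI", "RF", "SVML1") for t in TASKS}
    for top in rankings.values():
        assert len(top) == 10 and len(set(top)) == 10
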