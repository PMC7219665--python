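"""NCA weighting, feature selection, classifiers and subject-independent CV."""

import math

import numpy as np
import pandas as pd
import pytest

from liftchar.classify_cv import (
    ModelSpec,
    cross_validate,
    gnb_log_posteriors,
    nca_weights,
    select_features,
    subject_folds,
    train_predict_gnb,
    train_predict_knn,
)


# ---------------------------------------------------------------------------
# NCA
# ---------------------------------------------------------------------------

def _toy_table(rng, n=60, noise_cols=4):
    y = rng.integers(0, 2, n)
    data = {"label": y.astype(str)}
    data["signal"] = y + rng.normal(0, 0.05, n)
    for i in range(noise_cols):
        data[f"noise{i}"] = rng.normal(0, 1.0, n)
    return pd.DataFrame(data)


def test_nca_ranks_perfect_predictor_highest():
    rng = np.random.default_rng(8)
    table = _toy_table(rng)
    weights = nca_weights(table, "label")
    assert (weights >= 0).all()
    assert weights.idxmax() == "signal"
    assert weights["signal"] > 2 * weights.drop("signal").max()


def test_nca_duplicated_feature_gets_near_equal_weight():
    rng = np.random.default_rng(9)
    table = _toy_table(rng, noise_cols=2)
    table["signal_copy"] = table["signal"]
    weights = nca_weights(table, "label")
    a, b = weights["signal"], weights["signal_copy"]
    assert abs(a - b) <= 0.10 * max(a, b)


def test_nca_rejects_single_class():
    table = pd.DataFrame({"label": ["a"] * 10, "x": np.arange(10.0)})
    with pytest.raises(ValueError):
        nca_weights(table, "label")


# ---------------------------------------------------------------------------
# select_features
# ---------------------------------------------------------------------------

def test_select_features_relative_threshold():
    weights = pd.Series({"a": 1.0, "b": 0.99, "c": 0.5})
    assert set(select_features(weights, 0.02)) == {"a", "b"}
    assert set(select_features(weights, 1.0)) == {"a", "b", "c"}
    assert select_features(pd.Series({"a": 1.0, "b": 0.99}), 0.02,
                           exclusions=("b",)) == ["a"]
    with pytest.raises(ValueError):
        select_features(weights, 0.02, exclusions=("a", "b"))
    with pytest.raises(ValueError):
        select_features(pd.Series(dtype=float))


def test_select_features_count_mode():
    weights = pd.Series({"a": 1.0, "b": 0.9, "c": 0.8, "d": 0.1})
    assert select_features(weights, 0.5, mode="count") == ["a", "b"]


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

def brute_force_knn(X_train, y_train, X_test, k, standardize=True):
    """Independent exhaustive-distance reimplementation of the vote rules."""
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    if standardize:
        mu = X_train.mean(0)
        sd = X_train.std(0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd
    preds = []
    for q in X_test:
        d = np.sqrt(((X_train - q) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")[:k]
        labels = [y_train[i] for i in order]
        dists = d[order]
        best = None
        for lab in sorted(set(labels)):
            votes = labels.count(lab)
            total = sum(dd for dd, ll in zip(dists, labels) if ll == lab)
            key = (-votes, total, lab)
            if best is None or key < best[0]:
                best = (key, lab)
        preds.append(best[1])
    return np.array(preds)


def test_knn_identical_query_with_k1():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
    y = np.array(["a", "b", "c"])
    assert train_predict_knn(X, y, X[1:2], k=1)[0] == "b"


def test_knn_k_equal_to_all_rows_gives_majority():
    X = np.array([[0.0], [0.1], [0.2], [0.3], [5.0], [5.1], [5.2]])
    y = np.array(["maj"] * 4 + ["min"] * 3)
    pred = train_predict_knn(X, y, np.array([[2.0], [6.0]]), k=7)
    assert list(pred) == ["maj", "maj"]


def test_knn_matches_brute_force_on_seeded_instances():
    rng = np.random.default_rng(123)
    for _ in range(15):
        n = int(rng.integers(8, 40))
        d = int(rng.integers(1, 5))
        k = int(rng.integers(1, n + 1))
        X_train = rng.normal(size=(n, d))
        y_train = rng.choice(list("abc"), n)
        X_test = rng.normal(size=(6, d))
        got = train_predict_knn(X_train, y_train, X_test, k=k)
        expected = brute_force_knn(X_train, y_train, X_test, k=k)
        assert list(got) == list(expected)


def test_knn_argument_errors():
    X = np.zeros((3, 2))
    y = np.array(["a", "b", "a"])
    with pytest.raises(ValueError):
        train_predict_knn(X, y, X, k=0)
    with pytest.raises(ValueError):
        train_predict_knn(X, y, X, k=4)


# ---------------------------------------------------------------------------
# Gaussian naive Bayes
# ---------------------------------------------------------------------------

def test_gnb_log_posteriors_match_hand_computation():
    # 4 training rows, 1 feature: class a = {0, 1}, class b = {4, 6}
    X = np.array([[0.0], [1.0], [4.0], [6.0]])
    y = np.array(["a", "a", "b", "b"])
    query = np.array([[2.0]])
    classes, log_post = gnb_log_posteriors(X, y, query)
    assert list(classes) == ["a", "b"]

    # hand arithmetic: a ~ N(0.5, 0.25), b ~ N(5, 1) (population variances)
    def log_density(x, mean, var):
        return -0.5 * (math.log(2 * math.pi * var) + (x - mean) ** 2 / var)

    assert log_post[0, 0] == pytest.approx(log_density(2.0, 0.5, 0.25), abs=1e-9)
    assert log_post[0, 1] == pytest.approx(log_density(2.0, 5.0, 1.0), abs=1e-9)
    assert train_predict_gnb(X, y, query)[0] == "a"


def test_gnb_symmetric_query_ties_break_lexicographically():
    X = np.array([[-2.0], [0.0], [2.0], [4.0]])
    y = np.array(["beta", "beta", "alfa", "alfa"])  # means -1 and 3, equal var
    classes, log_post = gnb_log_posteriors(X, y, np.array([[1.0]]))
    assert log_post[0, 0] == pytest.approx(log_post[0, 1], abs=1e-9)
    assert train_predict_gnb(X, y, np.array([[1.0]]))[0] == "alfa"


def test_gnb_priors_stay_uniform_under_class_imbalance():
    # 4 vs 26 rows (the protocol's light/heavy ratio); a query with equal
    # likelihood under both classes must not drift toward the majority
    rng = np.random.default_rng(3)
    minority = np.concatenate([[-1.2, -0.8], -1 + 0.2 * rng.standard_normal(2)])
    majority = np.concatenate([[0.8, 1.2], 1 + 0.2 * rng.standard_normal(24)])
    minority = minority - minority.mean() - 1.0   # mean exactly -1
    majority = majority - majority.mean() + 1.0   # mean exactly +1
    scale = np.sqrt(minority.var() / majority.var())
    majority = 1.0 + (majority - 1.0) * scale     # equal variances
    X = np.concatenate([minority, majority])[:, None]
    y = np.array(["a_minority"] * 4 + ["z_majority"] * 26)
    pred = train_predict_gnb(X, y, np.array([[0.0]]))
    # equidistant in likelihood: uniform priors leave a lexicographic tie,
    # frequency priors would have picked the 26-row class
    assert pred[0] == "a_minority"


def test_gnb_warns_on_zero_variance_feature():
    X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 10.0], [1.0, 11.0]])
    y = np.array(["a", "a", "b", "b"])
    with pytest.warns(RuntimeWarning, match="zero"):
        train_predict_gnb(X, y, np.array([[1.0, 0.5]]))


# ---------------------------------------------------------------------------
# folds and cross-validation
# ---------------------------------------------------------------------------

def test_subject_folds_24_into_5():
    ids = [f"P{i:02d}" for i in range(1, 25)]
    folds = subject_folds(ids, n_folds=5, seed=0)
    sizes = sorted(
        (sum(1 for f in folds.values() if f == k) for k in range(5)), reverse=True
    )
    assert sizes == [5, 5, 5, 5, 4]
    assert subject_folds(ids, 5, seed=0) == folds  # deterministic


def test_subject_folds_edge_cases():
    assert sorted(subject_folds(list("abcde"), 5, seed=1).values()) == [0, 1, 2, 3, 4]
    with pytest.raises(ValueError):
        subject_folds(list("abc"), 5)


def _labeled_table(rng, n_participants=10, per=12, informative=True):
    rows = []
    for p in range(n_participants):
        for _ in range(per):
            label = rng.choice(["u", "v", "w"])
            base = {"u": 0.0, "v": 3.0, "w": 6.0}[label] if informative else 0.0
            rows.append({
                "participant_id": f"P{p:02d}",
                "posture": label,
                "f1": base + rng.normal(0, 0.3),
                "f2": rng.normal(),
            })
    return pd.DataFrame(rows)


def test_cross_validate_leakage_sanity_label_equals_feature():
    rng = np.random.default_rng(11)
    table = _labeled_table(rng)
    report = cross_validate(
        table, "posture", model_spec=ModelSpec("knn", k=1), features=["f1"]
    )
    assert report.accuracy > 99.0
    # confusion-matrix bookkeeping
    cm = report.confusion.to_numpy()
    assert report.accuracy == pytest.approx(100.0 * np.trace(cm) / cm.sum())
    assert report.n_trials == len(table)


def test_cross_validate_matches_manual_per_fold_loop():
    rng = np.random.default_rng(12)
    table = _labeled_table(rng)
    folds = subject_folds(table["participant_id"], 5, seed=3)
    report = cross_validate(
        table, "posture", model_spec=ModelSpec("knn", k=5),
        fold_assignment=folds, features=["f1", "f2"],
    )
    # recompute fold-by-fold with training statistics from training rows only
    correct = total = 0
    fold_of_row = table["participant_id"].map(folds).to_numpy()
    X = table[["f1", "f2"]].to_numpy()
    y = table["posture"].to_numpy()
    for f in range(5):
        test = fold_of_row == f
        pred = train_predict_knn(X[~test], y[~test], X[test], k=5)
        correct += int((pred == y[test]).sum())
        total += int(test.sum())
    assert report.accuracy == pytest.approx(100.0 * correct / total)


def test_cross_validate_permuted_balanced_labels_fall_to_chance():
    rng = np.random.default_rng(13)
    table = _labeled_table(rng, n_participants=12, per=30)
    table["posture"] = rng.permutation(table["posture"].to_numpy())
    report = cross_validate(
        table, "posture", model_spec=ModelSpec("knn", k=10), features=["f1", "f2"]
    )
    n = len(table)
    p = 1.0 / 3.0
    band = 4.0 * math.sqrt(p * (1 - p) / n)
    assert report.accuracy / 100.0 <= p + band + 0.05


def test_cross_validate_argument_errors():
    table = pd.DataFrame({"participant_id": ["a"], "f1": [1.0]})
    with pytest.raises(ValueError):
        cross_validate(table, "posture", features=["f1"])
    with pytest.raises(ValueError):
        cross_validate(table, "colors")
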