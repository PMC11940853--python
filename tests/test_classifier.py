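"""Boosted decision trees: splitting, gain selection, reweighting, voting."""

import math

import numpy as np
import pandas as pd
import pytest

from plumap.classifier import (
    BoostConfig,
    BoostedTreeModel,
    DecisionTree,
    TreeNode,
    best_split,
    load_model,
    predict,
    reweight,
    save_model,
    split_samples,
    train_boosted,
    train_tree,
)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _labels(counts: dict[str, int]) -> pd.Series:
    values = [cls for cls, n in counts.items() for _ in range(n)]
    return pd.Series(values, index=range(len(values)))


@pytest.mark.parametrize(
    "n, expected_train, expected_test",
    [(48, 33, 15), (20, 14, 6)],  # floor(0.7 * n) per class, remainder to test
)
def test_stratified_split_counts(n, expected_train, expected_test):
    labels = _labels({"PLU1": n, "PLU2": 10})
    train, test = split_samples(labels, 0.7, seed=1)
    assert sum(labels.loc[train] == "PLU1") == expected_train
    assert sum(labels.loc[test] == "PLU1") == expected_test


def test_split_is_disjoint_and_deterministic():
    labels = _labels({"PLU1": 48, "PLU2": 48, "PLU4": 20})
    a_train, a_test = split_samples(labels, 0.7, seed=9)
    b_train, b_test = split_samples(labels, 0.7, seed=9)
    assert set(a_train) | set(a_test) == set(labels.index)
    assert not set(a_train) & set(a_test)
    assert list(a_train) == list(b_train) and list(a_test) == list(b_test)
    c_train, _ = split_samples(labels, 0.7, seed=10)
    assert list(c_train) != list(a_train)


def test_degenerate_split_fractions_rejected():
    labels = _labels({"PLU1": 10, "PLU2": 10})
    for frac in (0.0, 1.0, 1.5):
        with pytest.raises(ValueError):
            split_samples(labels, frac)
    with pytest.raises(ValueError, match="fewer than 2"):
        split_samples(_labels({"PLU1": 1, "PLU2": 5}), 0.7)


# ---------------------------------------------------------------------------
# single-tree induction
# ---------------------------------------------------------------------------

def test_separable_one_feature_single_split():
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    y = np.array([0, 0, 1, 1])
    w = np.full(4, 0.25)
    tree = train_tree(X, y, w, n_classes=2)
    assert not tree.root.is_leaf
    assert tree.root.left.is_leaf and tree.root.right.is_leaf
    assert (tree.predict(X) == y).all()


def test_pure_input_gives_single_leaf():
    X = np.random.default_rng(0).normal(size=(6, 3))
    tree = train_tree(X, np.zeros(6, dtype=int), np.full(6, 1 / 6), n_classes=3)
    assert tree.root.is_leaf
    assert tree.root.label == 0


def test_identical_rows_mixed_labels_fall_to_majority_leaf():
    X = np.ones((5, 2))
    y = np.array([0, 0, 0, 1, 1])
    tree = train_tree(X, y, np.full(5, 0.2), n_classes=2)
    assert tree.root.is_leaf
    assert tree.root.label == 0


def _exhaustive_best_gain(X, y, w, n_classes):
    """Oracle: enumerate every (feature, midpoint) split and its gain."""

    def entropy(weights):
        total = sum(weights)
        if total == 0:
            return 0.0
        return -sum(
            (v / total) * math.log2(v / total) for v in weights if v > 0
        )

    parent = entropy(
        [w[y == k].sum() for k in range(n_classes)]
    )
    best = None
    for j in range(X.shape[1]):
        values = sorted(set(X[:, j]))
        for lo, hi in zip(values, values[1:]):
            threshold = (lo + hi) / 2
            left = X[:, j] <= threshold
            child = sum(
                w[mask].sum()
                / w.sum()
                * entropy([w[mask & (y == k)].sum() for k in range(n_classes)])
                for mask in (left, ~left)
            )
            gain = parent - child
            if best is None or gain > best[2] + 1e-12:
                best = (j, threshold, gain)
    return best


def test_root_split_matches_exhaustive_gain_search():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(12, 4))
    y = rng.integers(0, 3, size=12)
    w = rng.random(12)
    w /= w.sum()
    found = best_split(X, y, w, n_classes=3, min_leaf=1)
    expected = _exhaustive_best_gain(X, y, w, 3)
    assert found is not None
    assert found[0] == expected[0]
    assert found[1] == pytest.approx(expected[1])
    assert found[2] == pytest.approx(expected[2])


# ---------------------------------------------------------------------------
# boosting
# ---------------------------------------------------------------------------

def test_separable_data_stabilizes_at_first_iteration(toy_labels):
    features, labels = toy_labels
    model = train_boosted(features, labels)
    assert model.stopping_reason == "stabilized"
    assert model.stopping_iteration == 1
    assert model.epsilons == [0.0]
    assert len(model.trees) == 1


def test_samme_reweighting_hand_computed():
    """4 samples, 1 misclassified, K = 5: weights match the closed form."""
    w = np.full(4, 0.25)
    miscl = np.array([1.0, 0.0, 0.0, 0.0])
    epsilon = 0.25
    new_w, alpha = reweight(w, miscl, epsilon, n_classes=5)
    expected_alpha = math.log(0.75 / 0.25) + math.log(4)
    assert alpha == pytest.approx(expected_alpha)
    raw = 0.25 * math.exp(expected_alpha)  # = 0.25 * 12 = 3.0
    total = raw + 0.75
    assert new_w[0] == pytest.approx(raw / total)
    assert new_w[1:] == pytest.approx(np.full(3, 0.25 / total))
    assert new_w.sum() == pytest.approx(1.0, abs=1e-9)


def test_weights_stay_normalized_across_iterations():
    rng = np.random.default_rng(4)
    w = rng.random(50)
    w /= w.sum()
    for _ in range(20):
        miscl = (rng.random(50) < 0.3).astype(float)
        eps = float((w * miscl).sum())
        if eps == 0 or eps >= 0.8:
            continue
        w, _ = reweight(w, miscl, eps, n_classes=5)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)


def test_ensemble_not_worse_than_first_tree_on_training_data(toy_labels):
    features, labels = toy_labels
    model = train_boosted(features, labels)
    first = DecisionTree(model.trees[0].root, model.n_classes)
    y = np.array([model.class_order.index(v) for v in labels])
    first_acc = (first.predict(features.to_numpy()) == y).mean()
    ensemble_acc = (predict(model, features).to_numpy() == labels.to_numpy()).mean()
    assert ensemble_acc >= first_acc


def test_empty_training_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        train_boosted(pd.DataFrame(columns=["f0"]), pd.Series(dtype=str))


# ---------------------------------------------------------------------------
# prediction and voting
# ---------------------------------------------------------------------------

def _leaf_model(leaf_labels: list[int], classes=("PLU1", "PLU2", "PLU3", "PLU4")):
    trees = [DecisionTree(TreeNode(label=i), len(classes)) for i in leaf_labels]
    return BoostedTreeModel(
        trees=trees,
        epsilons=[0.1] * len(trees),
        alphas=[1.0] * len(trees),
        stopping_reason="max_iterations",
        stopping_iteration=len(trees),
        class_order=classes,
        train_prevalence=tuple([10] * len(classes)),
        feature_names=("f0",),
    )


def test_single_tree_prediction_is_that_tree():
    model = _leaf_model([2])
    out = predict(model, pd.DataFrame({"f0": [0.0, 1.0]}))
    assert list(out) == ["PLU3", "PLU3"]


def test_majority_vote():
    model = _leaf_model([1, 1, 3])  # votes PLU2, PLU2, PLU4
    out = predict(model, pd.DataFrame({"f0": [0.0]}))
    assert list(out) == ["PLU2"]


def test_vote_tie_breaks_by_prevalence_then_class_order():
    model = _leaf_model([0, 1])
    model.train_prevalence = (5, 9, 0, 0)
    assert list(predict(model, pd.DataFrame({"f0": [0.0]}))) == ["PLU2"]
    model.train_prevalence = (9, 9, 0, 0)
    assert list(predict(model, pd.DataFrame({"f0": [0.0]}))) == ["PLU1"]


def test_majority_vote_matches_independent_tally(region_features, region):
    """Ensemble prediction equals a per-tree vote count done by hand."""
    features, _, _ = region_features
    labels = pd.Series(region.truth_labels)
    model = train_boosted(features, labels, BoostConfig(max_depth=2, max_iter=7))
    X = features.to_numpy(dtype=float)
    out = predict(model, features)
    for i, cid in enumerate(features.index):
        tally: dict[int, int] = {}
        for tree in model.trees:
            vote = int(tree.predict(X[i : i + 1])[0])
            tally[vote] = tally.get(vote, 0) + 1
        best = max(tally.values())
        winners = [model.class_order[k] for k, v in tally.items() if v == best]
        assert out.loc[cid] in winners


def test_unknown_feature_columns_rejected(toy_labels):
    features, labels = toy_labels
    model = train_boosted(features, labels)
    with pytest.raises(ValueError, match="schema"):
        predict(model, features.rename(columns={"f0": "other"}))


def test_model_roundtrips_through_json(tmp_path, toy_labels):
    features, labels = toy_labels
    model = train_boosted(features, labels)
    path = save_model(model, tmp_path / "model.json")
    loaded = load_model(path)
    assert loaded.class_order == model.class_order
    assert loaded.epsilons == model.epsilons
    assert loaded.stopping_reason == model.stopping_reason
    assert list(predict(loaded, features)) == list(predict(model, features))


def test_training_is_deterministic(region_features, region):
    features, _, _ = region_features
    labels = pd.Series(region.truth_labels)
    a = train_boosted(features, labels, BoostConfig(max_iter=5, max_depth=4))
    b = train_boosted(features, labels, BoostConfig(max_iter=5, max_depth=4))
    assert a.epsilons == b.epsilons
    assert [t.root.to_dict() for t in a.trees] == [t.root.to_dict() for t in b.trees]


def test_tree_matches_sklearn_on_training_accuracy(toy_labels):
    """Independent route: an entropy tree from scikit-learn also separates
    the toy set perfectly, so both routes agree on the training labels."""
    sklearn = pytest.importorskip("sklearn.tree")
    features, labels = toy_labels
    y = pd.Categorical(labels).codes
    X = features.to_numpy()
    ours = train_tree(X, np.asarray(y), np.full(len(y), 1 / len(y)), n_classes=3)
    theirs = sklearn.DecisionTreeClassifier(criterion="entropy", random_state=0).fit(X, y)
    assert (ours.predict(X) == y).all()
    assert (theirs.predict(X) == y).all()
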