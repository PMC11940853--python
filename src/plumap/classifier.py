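"""Boosted decision-tree classifier for production landscape units.

The classifier is deliberately written from first principles, because its
behavior — entropy/information-gain splitting, multiplicative reweighting
of misclassified samples across iterations, and a final *unweighted*
majority vote over the trees — is the method under study, not an
off-the-shelf fit.

Design choices, all deterministic and documented:

* thresholds for continuous attributes are midpoints between consecutive
  distinct sorted values; gain ties break toward the lower column index,
  then the lower threshold;
* reweighting follows the multi-class AdaBoost (SAMME) factor
  ``alpha_t = ln((1 - eps_t)/eps_t) + ln(K - 1)`` with K classes, but the
  final decision is the most frequent class over the trees (one tree one
  vote), with ties broken by higher training prevalence and then by fixed
  class order;
* boosting stops early the moment a tree fits the training set perfectly
  (``eps_t = 0``, recorded as "stabilized") or when ``eps_t >= 1 - 1/K``;
* the random seed governs only the train/test split — tree induction
  itself is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PLU_CLASSES


@dataclass
class BoostConfig:
    max_iter: int = 99
    max_depth: int = 10
    min_leaf: int = 2
    train_frac: float = 0.7
    seed: int = 0


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def split_samples(
    labels: pd.Series,
    train_frac: float = 0.7,
    seed: int = 0,
) -> tuple[pd.Index, pd.Index]:
    """Stratified train/test split of labeled cells.

    Per class, ``floor(train_frac * n)`` samples go to training and the
    remainder to test; the within-class ordering is shuffled by the seed.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for cls in sorted(labels.unique()):
        ids = labels.index[labels == cls].to_numpy()
        if len(ids) < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        ids = ids[rng.permutation(len(ids))]
        n_train = math.floor(train_frac * len(ids))
        n_train = max(1, min(n_train, len(ids) - 1))
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])
    return pd.Index(train_ids), pd.Index(test_ids)


# ---------------------------------------------------------------------------
# decision tree with weighted information gain
# ---------------------------------------------------------------------------

def _weighted_entropy(class_weights: np.ndarray) -> float:
    total = class_weights.sum()
    if total <= 0:
        return 0.0
    p = class_weights[class_weights > 0] / total
    return float(-(p * np.log2(p)).sum())


def best_split(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, n_classes: int, min_leaf: int
) -> tuple[int, float, float] | None:
    """Exhaustive search for the (attribute, threshold) maximizing gain.

    Returns ``(feature, threshold, gain)`` or None when no split with
    positive gain leaves at least ``min_leaf`` samples on each side.
    """
    n, p = X.shape
    parent = _weighted_entropy(np.bincount(y, weights=w, minlength=n_classes))
    total_w = w.sum()
    best: tuple[int, float, float] | None = None
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys, ws = X[order, j], y[order], w[order]
        # cumulative per-class weights along the sorted axis
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = ws
        cum = np.cumsum(onehot, axis=0)
        distinct = np.nonzero(np.diff(xs) > 0)[0]  # split after position i
        for i in distinct:
            n_left = i + 1
            if n_left < min_leaf or n - n_left < min_leaf:
                continue
            left = cum[i]
            right = cum[-1] - left
            child = (
                left.sum() / total_w * _weighted_entropy(left)
                + right.sum() / total_w * _weighted_entropy(right)
            )
            gain = parent - child
            threshold = (xs[i] + xs[i + 1]) / 2.0
            if gain > 1e-12 and (best is None or gain > best[2] + 1e-12):
                best = (j, float(threshold), float(gain))
    return best


@dataclass
class TreeNode:
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: int | None = None  # leaf class index

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"label": int(self.label)}
        return {
            "feature": int(self.feature),
            "threshold": float(self.threshold),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TreeNode":
        if "label" in payload:
            return cls(label=int(payload["label"]))
        return cls(
            feature=int(payload["feature"]),
            threshold=float(payload["threshold"]),
            left=cls.from_dict(payload["left"]),
            right=cls.from_dict(payload["right"]),
        )


@dataclass
class DecisionTree:
    root: TreeNode
    n_classes: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X), dtype=np.int64)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.label
        return out

    def depth(self) -> int:
        def _d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)


def train_tree(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    *,
    n_classes: int,
    max_depth: int = 10,
    min_leaf: int = 2,
) -> DecisionTree:
    """Greedy top-down induction with weighted information gain.

    Splitting stops at node purity, at ``max_depth``, or when no candidate
    split leaves ``min_leaf`` samples per side with positive gain; leaves
    take the weighted-majority class (ties to the lower class index, i.e.
    the fixed class order).
    """
    if len(X) == 0:
        raise ValueError("cannot train on an empty sample set")
    if not math.isclose(w.sum(), 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError("sample weights must sum to 1")

    def _grow(idx: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(y[idx], weights=w[idx], minlength=n_classes)
        if np.count_nonzero(counts) == 1 or depth >= max_depth:
            return TreeNode(label=int(np.argmax(counts)))
        found = best_split(X[idx], y[idx], w[idx], n_classes, min_leaf)
        if found is None:
            return TreeNode(label=int(np.argmax(counts)))
        j, threshold, _ = found
        mask = X[idx, j] <= threshold
        return TreeNode(
            feature=j,
            threshold=threshold,
            left=_grow(idx[mask], depth + 1),
            right=_grow(idx[~mask], depth + 1),
        )

    return DecisionTree(root=_grow(np.arange(len(X)), 0), n_classes=n_classes)


# ---------------------------------------------------------------------------
# boosting
# ---------------------------------------------------------------------------

@dataclass
class BoostedTreeModel:
    trees: list[DecisionTree] = field(default_factory=list)
    epsilons: list[float] = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)
    stopping_reason: str = "untrained"
    stopping_iteration: int = 0
    class_order: tuple[str, ...] = PLU_CLASSES
    train_prevalence: tuple[int, ...] = ()
    feature_names: tuple[str, ...] = ()
    config: BoostConfig = field(default_factory=BoostConfig)

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    def schema_hash(self) -> str:
        return hashlib.sha256("|".join(self.feature_names).encode()).hexdigest()[:16]


def reweight(
    w: np.ndarray, misclassified: np.ndarray, epsilon: float, n_classes: int
) -> tuple[np.ndarray, float]:
    """One SAMME reweighting step; returns normalized weights and alpha."""
    alpha = math.log((1.0 - epsilon) / epsilon) + math.log(n_classes - 1)
    w = w * np.exp(alpha * misclassified)
    return w / w.sum(), alpha


def train_boosted(
    features: pd.DataFrame,
    labels: pd.Series,
    config: BoostConfig | None = None,
) -> BoostedTreeModel:
    """Fit the boosted ensemble on labeled cells.

    Weights start uniform; each iteration fits a full tree on the current
    weights, records its weighted training error ``eps_t``, multiplicatively
    up-weights the misclassified samples and renormalizes. Training stops
    when a tree is exact (``eps_t = 0``), when ``eps_t >= 1 - 1/K``, or at
    ``max_iter``.
    """
    config = config or BoostConfig()
    if len(features) == 0:
        raise ValueError("empty training set")
    class_order = tuple(c for c in PLU_CLASSES if c in set(labels)) or tuple(
        sorted(set(labels))
    )
    if set(labels) - set(class_order):
        class_order = tuple(sorted(set(labels)))
    index = {c: i for i, c in enumerate(class_order)}
    X = features.to_numpy(dtype=float)
    y = np.array([index[v] for v in labels.loc[features.index]])
    k = len(class_order)
    model = BoostedTreeModel(
        class_order=class_order,
        train_prevalence=tuple(int(n) for n in np.bincount(y, minlength=k)),
        feature_names=tuple(features.columns),
        config=config,
    )
    w = np.full(len(X), 1.0 / len(X))
    for t in range(config.max_iter):
        tree = train_tree(
            X, y, w, n_classes=k, max_depth=config.max_depth, min_leaf=config.min_leaf
        )
        pred = tree.predict(X)
        miscl = (pred != y).astype(float)
        epsilon = float((w * miscl).sum())
        if epsilon >= 1.0 - 1.0 / k:
            model.stopping_reason = "error_too_high"
            model.stopping_iteration = t + 1
            if not model.trees:  # keep at least the first tree
                model.trees.append(tree)
                model.epsilons.append(epsilon)
                model.alphas.append(0.0)
            break
        model.trees.append(tree)
        model.epsilons.append(epsilon)
        if epsilon == 0.0:
            model.alphas.append(math.inf)
            model.stopping_reason = "stabilized"
            model.stopping_iteration = t + 1
            break
        w, alpha = reweight(w, miscl, epsilon, k)
        model.alphas.append(alpha)
    else:
        model.stopping_reason = "max_iterations"
        model.stopping_iteration = config.max_iter
    return model


def predict(model: BoostedTreeModel, features: pd.DataFrame) -> pd.Series:
    """Unweighted majority vote over the ensemble's trees.

    Ties break toward the class with higher training prevalence, then
    toward the fixed class order.
    """
    if not model.trees:
        raise ValueError("model is untrained")
    if tuple(features.columns) != model.feature_names:
        raise ValueError("feature columns do not match the training schema")
    X = features.to_numpy(dtype=float)
    votes = np.zeros((len(X), model.n_classes), dtype=np.int64)
    for tree in model.trees:
        pred = tree.predict(X)
        votes[np.arange(len(X)), pred] += 1
    prevalence = np.asarray(model.train_prevalence)
    # strict class preference for ties: higher prevalence, then class order
    pref = np.array(sorted(range(model.n_classes), key=lambda i: (-prevalence[i], i)))
    winners = pref[np.argmax(votes[:, pref], axis=1)]
    labels = [model.class_order[i] for i in winners]
    return pd.Series(labels, index=features.index, name="plu_label")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: BoostedTreeModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "class_order": list(model.class_order),
        "train_prevalence": list(model.train_prevalence),
        "feature_names": list(model.feature_names),
        "schema_hash": model.schema_hash(),
        "epsilons": model.epsilons,
        "alphas": [a if math.isfinite(a) else None for a in model.alphas],
        "stopping_reason": model.stopping_reason,
        "stopping_iteration": model.stopping_iteration,
        "config": vars(model.config),
        "trees": [t.root.to_dict() for t in model.trees],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def load_model(path: str | Path) -> BoostedTreeModel:
    with open(path) as fh:
        payload = json.load(fh)
    model = BoostedTreeModel(
        class_order=tuple(payload["class_order"]),
        train_prevalence=tuple(payload["train_prevalence"]),
        feature_names=tuple(payload["feature_names"]),
        epsilons=[float(e) for e in payload["epsilons"]],
        alphas=[math.inf if a is None else float(a) for a in payload["alphas"]],
        stopping_reason=payload["stopping_reason"],
        stopping_iteration=int(payload["stopping_iteration"]),
        config=BoostConfig(**payload["config"]),
    )
    k = len(model.class_order)
    model.trees = [
        DecisionTree(root=TreeNode.from_dict(t), n_classes=k) for t in payload["trees"]
    ]
    return model
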