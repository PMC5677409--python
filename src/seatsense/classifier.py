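"""Gain-ratio decision tree for activity and activity-level recognition.

A C4.5-style learner specialised to the feature space at hand: all features
are numeric, so every split is a binary threshold test ``feature <= t``.
At each node the candidate (feature, threshold) pair maximising the gain
ratio — information gain divided by split information, both in bits — is
chosen; thresholds are midpoints between consecutive distinct observed
values.  Growth stops when a node is pure, holds fewer than ``2 * min_leaf``
instances, or no candidate split has positive gain.

Pruning is pessimistic error-based with confidence ``C`` (default 0.25):
each leaf's training error count is inflated to the upper confidence bound
of the binomial error rate, and a subtree is replaced by a leaf when the
leaf's pessimistic error does not exceed the subtree's (subtree replacement
only).  Ties everywhere are broken deterministically — in gain ratio by
feature name then threshold, in leaf prediction by lexicographic class
order — so training is reproducible from the data alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import ValidationError

__all__ = ["TreeParams", "Node", "DecisionTreeModel", "train", "predict"]

_EPS_GAIN = 1e-12  # a split must gain strictly more than this to be used


@dataclass(frozen=True)
class TreeParams:
    """Learner parameters: pruning confidence C and minimum leaf size M."""

    pruning_confidence: float = 0.25
    min_leaf: int = 2
    max_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.pruning_confidence <= 1.0:
            raise ValidationError("pruning confidence must be in (0, 1]")
        if self.min_leaf < 1:
            raise ValidationError("min_leaf must be >= 1")


@dataclass
class Node:
    """A tree node; internal nodes carry a threshold test, leaves a class.

    ``counts`` is the training class distribution reaching the node (same
    order as the model's class list); ``prediction`` is the majority class
    with lexicographic tie-break.
    """

    counts: np.ndarray
    prediction: str
    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["Node"] = None
    right: Optional["Node"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def walk(self):
        """Iterative pre-order traversal (trees can be deep before pruning)."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.append(node.right)
                stack.append(node.left)

    def n_nodes(self) -> int:
        return sum(1 for _ in self.walk())

    def depth(self) -> int:
        best = 0
        stack = [(self, 0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf:
                best = max(best, d)
            else:
                stack.append((node.left, d + 1))
                stack.append((node.right, d + 1))
        return best


@dataclass
class DecisionTreeModel:
    """A trained tree: root node, ordered class list, feature names."""

    root: Node
    classes: list[str]
    feature_names: list[str]
    params: TreeParams = field(default_factory=TreeParams)
    target: str = "activity"

    def n_nodes(self) -> int:
        return self.root.n_nodes()

    def depth(self) -> int:
        return self.root.depth()

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        def node_dict(node: Node) -> dict:
            d: dict = {
                "counts": node.counts.tolist(),
                "prediction": node.prediction,
            }
            if not node.is_leaf:
                d["feature"] = node.feature
                d["threshold"] = node.threshold
                d["left"] = node_dict(node.left)
                d["right"] = node_dict(node.right)
            return d

        payload = {
            "classes": self.classes,
            "feature_names": self.feature_names,
            "target": self.target,
            "params": {
                "pruning_confidence": self.params.pruning_confidence,
                "min_leaf": self.params.min_leaf,
                "max_depth": self.params.max_depth,
            },
            "root": node_dict(self.root),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DecisionTreeModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)

        def build(d: dict) -> Node:
            node = Node(
                counts=np.array(d["counts"], dtype=float),
                prediction=d["prediction"],
            )
            if "feature" in d:
                node.feature = d["feature"]
                node.threshold = float(d["threshold"])
                node.left = build(d["left"])
                node.right = build(d["right"])
            return node

        p = payload["params"]
        return cls(
            root=build(payload["root"]),
            classes=list(payload["classes"]),
            feature_names=list(payload["feature_names"]),
            params=TreeParams(
                pruning_confidence=p["pruning_confidence"],
                min_leaf=p["min_leaf"],
                max_depth=p["max_depth"],
            ),
            target=payload.get("target", "activity"),
        )


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------


def _entropy_bits(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy in bits of count vectors along the last axis."""
    total = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, counts / np.maximum(total, 1), 0.0)
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=-1)


def _best_split(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    feature_order: Sequence[int],
    min_leaf: int,
) -> Optional[tuple[float, int, float]]:
    """Best (gain_ratio, feature index, threshold) at a node, or None.

    Candidate thresholds are midpoints between consecutive distinct values;
    each side of a candidate must hold at least ``min_leaf`` instances and
    the information gain must be positive.  Features are scanned in
    name-sorted order and strict improvement is required, which implements
    the tie-break by feature name then (lower) threshold.
    """
    n = len(y)
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    base = _entropy_bits(onehot.sum(axis=0))
    best: Optional[tuple[float, int, float]] = None
    for f in feature_order:
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        left = np.cumsum(onehot[order], axis=0)[:-1]  # counts left of cut i
        right = left[-1] + onehot[order[-1]] - left
        left_n = np.arange(1, n)
        right_n = n - left_n
        ok = (
            (xs[:-1] < xs[1:])
            & (left_n >= min_leaf)
            & (right_n >= min_leaf)
        )
        if not ok.any():
            continue
        info = (left_n * _entropy_bits(left) + right_n * _entropy_bits(right)) / n
        gain = base - info
        pl = left_n / n
        split_info = -(pl * np.log2(pl) + (1 - pl) * np.log2(1 - pl))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(
                ok & (gain > _EPS_GAIN) & (split_info > 0), gain / split_info, -np.inf
            )
        i = int(np.argmax(ratio))
        if ratio[i] == -np.inf:
            continue
        threshold = (xs[i] + xs[i + 1]) / 2.0
        if best is None or ratio[i] > best[0] + 1e-12:
            best = (float(ratio[i]), f, float(threshold))
    return best


# ---------------------------------------------------------------------------
# Growth and pruning
# ---------------------------------------------------------------------------


def _majority(counts: np.ndarray, classes: Sequence[str]) -> str:
    """Majority class; ties broken by lexicographic class order."""
    top = counts.max()
    candidates = [classes[i] for i in np.flatnonzero(counts == top)]
    return min(candidates)


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    classes: list[str],
    feature_order: Sequence[int],
    params: TreeParams,
) -> Node:
    """Grow the full tree with an explicit stack (trees on noisy features
    can exceed Python's recursion depth)."""

    def make_node(idx: np.ndarray) -> Node:
        counts = np.bincount(y[idx], minlength=len(classes)).astype(float)
        return Node(counts=counts, prediction=_majority(counts, classes))

    root = make_node(np.arange(len(y)))
    stack: list[tuple[Node, np.ndarray, int]] = [(root, np.arange(len(y)), 0)]
    while stack:
        node, idx, depth = stack.pop()
        pure = (node.counts > 0).sum() <= 1
        if (
            pure
            or len(idx) < 2 * params.min_leaf
            or (params.max_depth is not None and depth >= params.max_depth)
        ):
            continue
        best = _best_split(
            X[idx], y[idx], len(classes), feature_order, params.min_leaf
        )
        if best is None:
            continue
        _, f, threshold = best
        mask = X[idx, f] <= threshold
        node.feature = f  # feature index during growth; renamed after
        node.threshold = threshold
        node.left = make_node(idx[mask])
        node.right = make_node(idx[~mask])
        stack.append((node.left, idx[mask], depth + 1))
        stack.append((node.right, idx[~mask], depth + 1))
    return root


def _rename_features(root: Node, names: Sequence[str]) -> None:
    for node in root.walk():
        if not node.is_leaf:
            node.feature = names[node.feature]


def _add_errs(n: float, e: float, cf: float) -> float:
    """Pessimistic extra errors for a leaf with n instances and e errors.

    Upper confidence bound of the binomial error at confidence ``cf``,
    using the standard normal approximation with continuity correction
    (and the exact form for e = 0); returns the increment over e.
    """
    if n <= 0:
        return 0.0
    if cf >= 1.0:
        return 0.0
    if e < 1e-9:
        return n * (1.0 - cf ** (1.0 / n))
    if e < 1.0:
        base = n * (1.0 - cf ** (1.0 / n))
        return base + e * (_add_errs(n, 1.0, cf) - base)
    if e + 0.5 >= n:
        return max(n - e, 0.0)
    # normal deviate for the one-sided upper bound
    z = norm.ppf(1.0 - cf)
    f = (e + 0.5) / n
    r = (
        f
        + z * z / (2.0 * n)
        + z * math.sqrt(f / n - f * f / n + z * z / (4.0 * n * n))
    ) / (1.0 + z * z / n)
    return r * n - e


def _prune(root: Node, classes: Sequence[str], cf: float) -> Node:
    """Bottom-up subtree replacement by the pessimistic-error criterion.

    Iterative post-order: children are resolved before their parent, and a
    replaced subtree becomes a leaf in place, so each node is visited once.
    """
    post: list[Node] = list(root.walk())
    post.reverse()  # children before parents
    est: dict[int, float] = {}
    for node in post:
        n = node.counts.sum()
        e_leaf = n - node.counts.max()
        leaf_est = e_leaf + _add_errs(n, e_leaf, cf)
        if node.is_leaf:
            est[id(node)] = leaf_est
            continue
        subtree_est = est[id(node.left)] + est[id(node.right)]
        if leaf_est <= subtree_est + 0.1:
            node.feature = None
            node.threshold = None
            node.left = None
            node.right = None
            node.prediction = _majority(node.counts, classes)
            est[id(node)] = leaf_est
        else:
            est[id(node)] = subtree_est
    return root


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def train(
    rows: pd.DataFrame,
    target: str = "activity",
    params: TreeParams = TreeParams(),
    feature_names: Optional[Sequence[str]] = None,
    prune: bool = True,
) -> DecisionTreeModel:
    """Fit a gain-ratio tree on a feature table.

    ``rows`` is a DataFrame with numeric feature columns and a ``target``
    column (``activity`` or ``level``).  ``feature_names`` restricts the
    features used (default: every numeric non-metadata column).  Training is
    deterministic: ties in gain ratio resolve by feature name then lower
    threshold, leaf predictions by lexicographic class order.
    """
    if len(rows) == 0:
        raise ValidationError("empty training set")
    if target not in rows.columns:
        raise ValidationError(f"target column {target!r} missing")
    if feature_names is None:
        meta = {"activity", "level", "subject", "window_start_s"}
        feature_names = [
            c
            for c in rows.columns
            if c not in meta and pd.api.types.is_numeric_dtype(rows[c])
        ]
    feature_names = sorted(feature_names)
    if not feature_names:
        raise ValidationError("no feature columns")
    X = rows[feature_names].to_numpy(dtype=float)
    labels = rows[target].astype(str).to_numpy()
    classes = sorted(set(labels))
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[c] for c in labels])
    root = _grow(X, y, classes, range(len(feature_names)), params)
    _rename_features(root, feature_names)
    if prune:
        root = _prune(root, classes, params.pruning_confidence)
    return DecisionTreeModel(
        root=root,
        classes=classes,
        feature_names=list(feature_names),
        params=params,
        target=target,
    )


def predict(model: DecisionTreeModel, rows: pd.DataFrame) -> np.ndarray:
    """Deterministic root-to-leaf routing of each row; returns class labels."""
    missing = [f for f in model.feature_names if f not in rows.columns]
    if missing:
        raise ValidationError(f"rows missing model feature(s) {missing}")
    X = rows[model.feature_names].to_numpy(dtype=float)
    col = {name: j for j, name in enumerate(model.feature_names)}
    out = np.empty(len(rows), dtype=object)
    stack: list[tuple[Node, np.ndarray]] = [(model.root, np.arange(len(rows)))]
    while stack:
        node, idx = stack.pop()
        if idx.size == 0:
            continue
        if node.is_leaf:
            out[idx] = node.prediction
            continue
        mask = X[idx, col[node.feature]] <= node.threshold
        stack.append((node.left, idx[mask]))
        stack.append((node.right, idx[~mask]))
    return out
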