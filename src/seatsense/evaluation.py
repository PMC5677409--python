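"""Cross-validation protocols, metrics and the window-size sweep.

Two protocols are provided:

* **Stratified k-fold CV** (default k = 10) on pooled windows.  Pooling
  windows across subjects is optimistic for subject-generalisation — the
  same person's highly autocorrelated windows appear in both train and test
  folds — which is exactly why the second protocol exists.
* **Leave-one-subject-out CV (LOSO)**: each subject's windows form one
  held-out fold, so the reported accuracy reflects generalisation to an
  unseen sitter.

Metrics are computed from an aggregate confusion matrix: per-class precision,
recall and F-measure (F = 2pr/(p+r), 0 when p + r = 0) plus overall accuracy
(trace / total).  "Macro F" is the unweighted mean of per-class F values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import classifier as clf
from .classifier import DecisionTreeModel, TreeParams
from .cop import compute_cop
from .datamodel import RawStream, ValidationError
from .features import ApEnParams, WindowConfig, extract_features, feature_frame

__all__ = ["EvalReport", "kfold_cv", "loso_cv", "window_sweep"]

logger = logging.getLogger(__name__)

#: train/predict contract used by the CV harness; any classifier satisfying
#: it (e.g. a library tree) can be swapped in for cross-checking.
TrainFn = Callable[[pd.DataFrame, str, TreeParams], DecisionTreeModel]
PredictFn = Callable[[DecisionTreeModel, pd.DataFrame], np.ndarray]


@dataclass
class EvalReport:
    """Confusion matrix (rows = true, cols = predicted) plus derived metrics."""

    confusion: np.ndarray
    classes: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        k = len(self.classes)
        if self.confusion.shape != (k, k):
            raise ValidationError("confusion matrix shape does not match classes")
        if (self.confusion < 0).any():
            raise ValidationError("confusion entries must be >= 0")

    @classmethod
    def from_predictions(
        cls,
        y_true: Sequence[str],
        y_pred: Sequence[str],
        classes: Optional[Sequence[str]] = None,
        **metadata,
    ) -> "EvalReport":
        y_true = np.asarray(y_true, dtype=object)
        y_pred = np.asarray(y_pred, dtype=object)
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        classes = list(classes)
        index = {c: i for i, c in enumerate(classes)}
        confusion = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            confusion[index[t], index[p]] += 1
        return cls(confusion=confusion, classes=classes, metadata=dict(metadata))

    # -- derived metrics ----------------------------------------------------

    @property
    def total(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.total) if self.total else 0.0

    def precision(self, c: str) -> float:
        j = self.classes.index(c)
        col = self.confusion[:, j].sum()
        return float(self.confusion[j, j] / col) if col else 0.0

    def recall(self, c: str) -> float:
        i = self.classes.index(c)
        row = self.confusion[i, :].sum()
        return float(self.confusion[i, i] / row) if row else 0.0

    def f_measure(self, c: str) -> float:
        p, r = self.precision(c), self.recall(c)
        return 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0

    @property
    def macro_f(self) -> float:
        return float(np.mean([self.f_measure(c) for c in self.classes]))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "macro_f": self.macro_f,
            "per_class": {
                c: {
                    "precision": self.precision(c),
                    "recall": self.recall(c),
                    "f_measure": self.f_measure(c),
                }
                for c in self.classes
            },
            "metadata": self.metadata,
        }

    def __str__(self) -> str:
        width = max(12, max(len(c) for c in self.classes) + 2)
        lines = [
            "".join([" " * width] + [c.rjust(width) for c in self.classes])
        ]
        for i, c in enumerate(self.classes):
            lines.append(
                "".join(
                    [c.rjust(width)]
                    + [str(v).rjust(width) for v in self.confusion[i]]
                )
            )
        lines.append(f"accuracy = {self.accuracy:.4f}   macro F = {self.macro_f:.4f}")
        return "\n".join(lines)


def _check_rows(rows: pd.DataFrame, target: str) -> None:
    if target not in rows.columns:
        raise ValidationError(f"target column {target!r} missing")
    if len(rows) == 0:
        raise ValidationError("no feature rows")


def _restrict(
    rows: pd.DataFrame, feature_names: Optional[Sequence[str]]
) -> pd.DataFrame:
    """Keep only the requested feature columns (plus metadata)."""
    if feature_names is None:
        return rows
    meta = [c for c in ("activity", "level", "subject", "window_start_s")
            if c in rows.columns]
    return rows[list(feature_names) + meta]


def kfold_cv(
    rows: pd.DataFrame,
    target: str = "activity",
    params: TreeParams = TreeParams(),
    k: int = 10,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
    train_fn: TrainFn = clf.train,
    predict_fn: PredictFn = clf.predict,
) -> EvalReport:
    """Stratified k-fold cross-validation with a seeded shuffle.

    The confusion matrix aggregates every held-out fold, and all metrics
    derive from that aggregate.  When some class has fewer than ``k``
    instances, stratification is impossible and the split degrades to plain
    shuffled k-fold (logged).
    """
    _check_rows(rows, target)
    rows = _restrict(rows, feature_names)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if len(rows) < k:
        raise ValidationError(f"fewer rows ({len(rows)}) than folds ({k})")
    labels = rows[target].astype(str).to_numpy()
    classes = sorted(set(labels))
    min_count = pd.Series(labels).value_counts().min()
    if min_count >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        logger.warning(
            "smallest class has %d < k=%d instances; using unstratified folds",
            min_count,
            k,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for train_idx, test_idx in splitter.split(rows, labels):
        model = train_fn(rows.iloc[train_idx], target, params)
        pred = predict_fn(model, rows.iloc[test_idx])
        for t, p in zip(labels[test_idx], pred):
            confusion[index[t], index[p]] += 1
    return EvalReport(
        confusion=confusion,
        classes=classes,
        metadata={
            "protocol": f"{k}-fold stratified CV",
            "seed": seed,
            "target": target,
            "stratified": bool(min_count >= k),
            "n_rows": len(rows),
        },
    )


def loso_cv(
    rows: pd.DataFrame,
    target: str = "activity",
    params: TreeParams = TreeParams(),
    feature_names: Optional[Sequence[str]] = None,
    train_fn: TrainFn = clf.train,
    predict_fn: PredictFn = clf.predict,
) -> tuple[dict[str, EvalReport], EvalReport]:
    """Leave-one-subject-out CV: per-subject reports and the pooled report.

    For each subject, a model is trained on every other subject's windows
    and tested on that subject's.  The pooled confusion matrix is the sum of
    the per-subject matrices.  Deterministic given rows and params.
    """
    _check_rows(rows, target)
    rows = _restrict(rows, feature_names)
    if "subject" not in rows.columns:
        raise ValidationError("rows must carry a subject column for LOSO")
    subjects = sorted(rows["subject"].astype(str).unique())
    if len(subjects) < 2:
        raise ValidationError("LOSO needs at least 2 distinct subjects")
    labels = rows[target].astype(str).to_numpy()
    classes = sorted(set(labels))
    index = {c: i for i, c in enumerate(classes)}
    per_subject: dict[str, EvalReport] = {}
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    subj_col = rows["subject"].astype(str).to_numpy()
    for s in subjects:
        test_mask = subj_col == s
        model = train_fn(rows[~test_mask], target, params)
        pred = predict_fn(model, rows[test_mask])
        confusion = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(labels[test_mask], pred):
            confusion[index[t], index[p]] += 1
        per_subject[s] = EvalReport(
            confusion=confusion,
            classes=classes,
            metadata={"protocol": "LOSO", "held_out_subject": s, "target": target},
        )
        pooled += confusion
    pooled_report = EvalReport(
        confusion=pooled,
        classes=classes,
        metadata={
            "protocol": "LOSO pooled",
            "target": target,
            "subjects": subjects,
            "n_rows": len(rows),
        },
    )
    return per_subject, pooled_report


def window_sweep(
    streams: Sequence[RawStream],
    tw_values: Sequence[float] = tuple(range(5, 61, 5)),
    feature_sets: Sequence[str] = ("std", "apen"),
    target: str = "activity",
    params: TreeParams = TreeParams(),
    apen_params: ApEnParams = ApEnParams(),
    overlap: float = 0.5,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Full pipeline (CoP -> features -> k-fold CV) per (tw, feature set).

    Returns a table with columns ``tw, feature_set, n_windows, accuracy,
    macro_f``; used to choose the window length by the accuracy/latency
    trade-off.
    """
    records = []
    for tw in tw_values:
        cfg = WindowConfig(tw=tw, overlap=overlap, fs=streams[0].fs)
        for fset in feature_sets:
            rows = []
            for stream in streams:
                cop = compute_cop(stream)
                rows.extend(
                    extract_features(stream, cop, cfg, apen_params, sets=fset)
                )
            table = feature_frame(rows)
            report = kfold_cv(table, target=target, params=params, k=k, seed=seed)
            records.append(
                {
                    "tw": tw,
                    "feature_set": fset,
                    "n_windows": len(table),
                    "accuracy": report.accuracy,
                    "macro_f": report.macro_f,
                }
            )
    return pd.DataFrame.from_records(records)
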