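"""MinMax scaling, KNN classification, k-fold CV and confusion metrics.

The classifier is a plain k-nearest-neighbour vote under Euclidean
distance (k odd, so two-class votes cannot tie; distance ties are broken
by lower training-row index for fully deterministic runs).  Validation is
a seeded k-fold scheme — 23 folds of 3 for the 69-subject study layout —
with one *pooled* confusion matrix over all held-out predictions: with
fold size 3, per-fold sensitivity/specificity are frequently undefined, so
pooling is the only well-defined reading.  The positive class is CHF.

The fitness used by the feature-subset search is the error rate
``theta = 1 - Ac/100``.

MinMax scaling is applied to the full table before cross-validation by
default (a dataset-level preprocessing step); ``minmax='fold'`` fits the
scaler on the training folds only, for leakage-free comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

__all__ = [
    "FoldPlan",
    "PerfMetrics",
    "minmax_scale",
    "knn_predict",
    "make_folds",
    "cross_validate",
    "confusion_metrics",
]

POSITIVE_LABEL = "CHF"
NEGATIVE_LABEL = "NSR"


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint fold assignment covering all rows, sizes differing by <= 1."""

    k: int
    assignment: np.ndarray
    seed: int


@dataclass
class PerfMetrics:
    """Pooled confusion counts and the derived percentages.

    ``se`` / ``sp`` are ``nan`` when their denominator is zero (undefined,
    reported as missing rather than 0).
    """

    tp: int
    tn: int
    fp: int
    fn: int
    se: float
    sp: float
    ac: float
    theta: float


def minmax_scale(table):
    """Per-column MinMax to [0, 1]; constant columns map to 0.

    Accepts a DataFrame (only numeric feature columns are scaled; label /
    id columns pass through) or a 2-D ndarray.
    """
    if isinstance(table, pd.DataFrame):
        out = table.copy()
        cols = [c for c in table.columns if c in FEATURE_NAMES] or [
            c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
        ]
        out[cols] = _minmax_array(table[cols].to_numpy(dtype=float))
        return out
    return _minmax_array(np.asarray(table, dtype=float))


def _minmax_array(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    span = np.where(span == 0, 1.0, span)
    return (x - lo) / span


def knn_predict(train_x: np.ndarray, train_y, query: np.ndarray, k: int = 5):
    """Majority vote among the k nearest training rows (Euclidean).

    ``k`` must be odd (even values are rejected: a two-class vote could
    tie).  Distance ties are resolved in favour of the lower row index via
    a stable sort.
    """
    train_x = np.asarray(train_x, dtype=float)
    query = np.asarray(query, dtype=float)
    train_y = np.asarray(train_y)
    if train_x.shape[0] == 0:
        raise ValueError("empty training set")
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if k > train_x.shape[0]:
        raise ValueError("k exceeds the number of training rows")
    single = query.ndim == 1
    q = query[None, :] if single else query
    d2 = ((q[:, None, :] - train_x[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    preds = []
    for row in order:
        labels, counts = np.unique(train_y[row], return_counts=True)
        preds.append(labels[np.argmax(counts)])
    preds = np.array(preds)
    return preds[0] if single else preds


def make_folds(n: int, k: int = 23, seed: int = 0) -> FoldPlan:
    """Seeded random permutation, round-robin fold assignment."""
    if k > n:
        raise ValueError("more folds than samples")
    if k < 1:
        raise ValueError("need at least one fold")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[perm] = np.arange(n) % k
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> PerfMetrics:
    """Sensitivity, specificity, accuracy (percent) and error rate theta."""
    if min(tp, tn, fp, fn) < 0 or tp + tn + fp + fn == 0:
        raise ValueError("counts must be non-negative with positive sum")
    se = 100.0 * tp / (tp + fn) if tp + fn > 0 else math.nan
    sp = 100.0 * tn / (tn + fp) if tn + fp > 0 else math.nan
    ac = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    return PerfMetrics(tp=tp, tn=tn, fp=fp, fn=fn, se=se, sp=sp,
                       ac=ac, theta=1.0 - ac / 100.0)


def cross_validate(
    table: pd.DataFrame,
    mask=None,
    k_nn: int = 5,
    folds: FoldPlan | None = None,
    minmax: str | None = "global",
    positive_label: str = POSITIVE_LABEL,
) -> PerfMetrics:
    """Pooled k-fold cross-validation of KNN on the masked features.

    ``table`` must hold a ``label`` column plus the 16 feature columns;
    ``mask`` is a boolean/index selection over :data:`FEATURE_NAMES`
    (``None`` = all features).  Each fold is held out once, the classifier
    trained on the rest, and all held-out predictions pooled into a single
    confusion matrix.
    """
    feature_cols = [c for c in table.columns if c in FEATURE_NAMES]
    if mask is not None:
        mask = np.asarray(mask)
        if mask.dtype == bool:
            if mask.size != len(feature_cols):
                raise ValueError("boolean mask length mismatch")
            feature_cols = [c for c, m in zip(feature_cols, mask) if m]
        else:
            feature_cols = [feature_cols[i] for i in mask]
    if not feature_cols:
        raise ValueError("mask selects no features")

    y = table["label"].to_numpy()
    x = table[feature_cols].to_numpy(dtype=float)
    n = x.shape[0]
    if folds is None:
        folds = make_folds(n, k=min(23, n), seed=0)
    if folds.assignment.size != n:
        raise ValueError("fold plan does not match table size")
    if minmax == "global":
        x = _minmax_array(x)

    tp = tn = fp = fn = 0
    for fold in range(folds.k):
        test = folds.assignment == fold
        train = ~test
        xt, yt = x[train], y[train]
        xq, yq = x[test], y[test]
        if minmax == "fold":
            lo, hi = xt.min(axis=0), xt.max(axis=0)
            span = np.where(hi - lo == 0, 1.0, hi - lo)
            xt = (xt - lo) / span
            xq = (xq - lo) / span
        pred = knn_predict(xt, yt, xq, k=k_nn)
        for yhat, ytrue in zip(np.atleast_1d(pred), yq):
            if ytrue == positive_label:
                tp += yhat == ytrue
                fn += yhat != ytrue
            else:
                tn += yhat == ytrue
                fp += yhat != ytrue
    return confusion_metrics(int(tp), int(tn), int(fp), int(fn))
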