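"""Tabular preprocessing: mean imputation, min-max scaling, one-hot labels,
seeded train/test split.

The pipeline order is leakage-safe: imputation means and scaler min/max are
learned on the training partition only and then applied to held-out rows,
so test values may fall outside [0, 1] (they are not clipped).  Missing
values are represented as NaN; the dataset CSV dialect is a header row,
numeric feature columns, a final ``label`` column in {0, 1}, and empty
cells for missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer

__all__ = [
    "ScalerModel",
    "SplitSpec",
    "MeanImputer",
    "impute_mean",
    "fit_minmax",
    "apply_minmax",
    "one_hot_encode",
    "train_test_split",
    "load_dataset_csv",
    "save_dataset_csv",
]


class MeanImputer:
    """Column-mean imputation fitted on training rows (wraps sklearn's
    SimpleImputer; rejects fully missing columns instead of dropping them)."""

    def __init__(self):
        self._imp = SimpleImputer(strategy="mean", keep_empty_features=True)
        self.means_ = None

    def fit(self, X) -> "MeanImputer":
        X = np.asarray(X, dtype=float)
        if np.any(np.all(np.isnan(X), axis=0)):
            raise ValueError("cannot impute a fully missing feature")
        self._imp.fit(X)
        self.means_ = self._imp.statistics_.copy()
        return self

    def transform(self, X) -> np.ndarray:
        if self.means_ is None:
            raise RuntimeError("imputer not fitted")
        return self._imp.transform(np.asarray(X, dtype=float))

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).transform(X)


def impute_mean(X, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Replace missing entries (NaN, or True in ``mask``) by the column's
    observed mean, learned from ``X`` itself."""
    X = np.array(X, dtype=float, copy=True)
    if mask is not None:
        X[np.asarray(mask, dtype=bool)] = np.nan
    return MeanImputer().fit_transform(X)


@dataclass(frozen=True)
class ScalerModel:
    """Per-feature min and max learned from training rows only."""
    min_: np.ndarray
    max_: np.ndarray


def fit_minmax(train: np.ndarray) -> ScalerModel:
    train = np.asarray(train, dtype=float)
    return ScalerModel(min_=np.nanmin(train, axis=0), max_=np.nanmax(train, axis=0))


def apply_minmax(model: ScalerModel, X: np.ndarray) -> np.ndarray:
    """x' = (x - min) / (max - min); constant features map to 0; values are
    deliberately not clipped, so held-out rows can leave [0, 1]."""
    X = np.asarray(X, dtype=float)
    span = model.max_ - model.min_
    safe = np.where(span > 0, span, 1.0)
    out = (X - model.min_) / safe
    return np.where(span > 0, out, 0.0)


def one_hot_encode(labels, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    return np.eye(n_classes)[labels]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: Optional[int] = None
    stratified: bool = True

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


def _stratified_counts(y, n_train):
    """Per-class training counts via largest remainder, preserving the class
    ratio within one sample per class."""
    classes, counts = np.unique(y, return_counts=True)
    exact = counts * n_train / counts.sum()
    base = np.floor(exact).astype(int)
    short = n_train - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:short]] += 1
    return dict(zip(classes.tolist(), base.tolist()))


def train_test_split(X, y, spec: SplitSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Return (train_idx, test_idx): disjoint, exhaustive, seeded, with
    floor(train_fraction * n) training rows; the stratified option keeps the
    class ratio within one sample per class."""
    y = np.asarray(y)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    n_train = int(np.floor(spec.train_fraction * n))
    rng = np.random.default_rng(spec.seed)
    if spec.stratified:
        want = _stratified_counts(y, n_train)
        train_parts = []
        for cls, k in want.items():
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            train_parts.append(idx[:k])
        train_idx = rng.permutation(np.concatenate(train_parts))
    else:
        perm = rng.permutation(n)
        train_idx = perm[:n_train]
    test_idx = np.setdiff1d(np.arange(n), train_idx)
    return train_idx, test_idx


def load_dataset_csv(path) -> Tuple[pd.DataFrame, np.ndarray]:
    """Read the dataset dialect: numeric features + final ``label`` column;
    empty cells become NaN."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("dataset CSV must have a final 'label' column")
    y = df["label"].to_numpy(dtype=int)
    X = df.drop(columns=["label"]).astype(float)
    return X, y


def save_dataset_csv(path, X: pd.DataFrame, y) -> None:
    out = X.copy()
    out["label"] = np.asarray(y, dtype=int)
    out.to_csv(path, index=False)
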