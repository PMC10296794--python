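"""Model/Results facade for swarm- and gradient-trained sigmoid MLP classifiers.

:class:`SwarmMLP` bundles the preprocessing pipeline (train-fitted mean
imputation, min-max scaling, one-hot targets, stratified 80/20 split) with
a sigmoid MLP over a flat parameter vector.  ``fit`` dispatches to the
derivative-free swarm optimizers ("hms_pso", "pso", "hms") or the
first-order baselines ("grad", "sgd", "adadelta", "rmsprop", "adam") and
returns a :class:`SwarmMLPResults` carrying the trained parameter vector,
train/test error metrics, the convergence trace and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import network as net
from .gradients import GRADIENT_METHODS, GradientConfig, train_gradient
from .preprocessing import (MeanImputer, SplitSpec, apply_minmax, fit_minmax,
                            one_hot_encode, train_test_split)
from .swarm import SwarmConfig, optimize

__all__ = ["SwarmMLP", "SwarmMLPResults"]

SWARM_METHODS = ("hms_pso", "pso", "hms")


class SwarmMLP:
    """A sigmoid MLP classification model bound to a dataset.

    Parameters
    ----------
    X : array-like or DataFrame, shape (n, p)
        Numeric features; NaN marks missing values.
    y : array-like of int
        Class labels 0..K-1.
    hidden : sequence of int
        Hidden layer widths (default the selected ``24-18-9-3-2`` depth
        pattern's hidden part, ``(18, 9, 3)``).
    test_fraction : float
        Held-out fraction (default 0.2).
    stratified : bool
        Stratify the split on the labels (default True).
    seed : int
        Seed for the train/test split.
    """

    def __init__(self, X, y, hidden: Sequence[int] = (18, 9, 3),
                 test_fraction: float = 0.2, stratified: bool = True,
                 seed: Optional[int] = 0):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        self.n_classes = int(y.max()) + 1
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        self.topology = net.Topology(X.shape[1], tuple(hidden), self.n_classes)
        self.split_seed = seed

        tr, te = train_test_split(
            X, y, SplitSpec(1.0 - test_fraction, seed=seed, stratified=stratified))
        self.imputer = MeanImputer().fit(X[tr])
        self.scaler = fit_minmax(self.imputer.transform(X[tr]))
        self.X_train = apply_minmax(self.scaler, self.imputer.transform(X[tr]))
        self.X_test = apply_minmax(self.scaler, self.imputer.transform(X[te]))
        self.y_train, self.y_test = y[tr], y[te]
        self.Y_train = one_hot_encode(self.y_train, self.n_classes)
        self.Y_test = one_hot_encode(self.y_test, self.n_classes)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "label", **kwargs):
        """Build from a DataFrame holding features plus a label column."""
        y = df[label].to_numpy(dtype=int)
        return cls(df.drop(columns=[label]), y, **kwargs)

    # -- fitting -----------------------------------------------------------

    def _objective(self):
        top = self.topology
        Xtr, Ytr = self.X_train, self.Y_train

        def objective(theta):
            return net.mse(net.forward(top, theta, Xtr), Ytr)

        return objective

    def fit(self, method: str = "hms_pso", iterations: int = 2000,
            population: int = 50, seed: Optional[int] = None,
            weight_bounds=(-10.0, 10.0), w: Union[float, tuple] = 0.6,
            c1: float = 1.45, c2: float = 1.45,
            **kwargs) -> "SwarmMLPResults":
        """Train the network weights and return a results object.

        Swarm methods search the flat weight vector inside ``weight_bounds``
        with constant inertia ``w`` and coefficients ``c1``/``c2`` (the
        dataset-training defaults 0.6 / 1.45 / 1.45); extra ``kwargs`` pass
        through to :class:`SwarmConfig` or :class:`GradientConfig`.
        """
        n_params = net.count_parameters(self.topology)
        if method in SWARM_METHODS:
            config = SwarmConfig(
                dimension=n_params, bounds=weight_bounds,
                population_size=population, max_iterations=iterations,
                w=w, c1=c1, c2=c2, seed=seed, **kwargs)
            result = optimize(self._objective(), config, algorithm=method)
        elif method in GRADIENT_METHODS:
            config = GradientConfig(method=method, iterations=iterations, **kwargs)
            result = train_gradient(self.topology, self.X_train, self.Y_train,
                                    config, seed=seed)
        else:
            raise ValueError(f"unknown training method {method!r}")
        return SwarmMLPResults(self, result, method)


@dataclass
class SwarmMLPResults:
    """Fitted-network results: parameter estimates, fit diagnostics, metrics."""

    model: SwarmMLP
    optimization: object
    method: str

    def __post_init__(self):
        m, top = self.model, self.model.topology
        self.params = np.asarray(self.optimization.best_position, dtype=float)
        self.fitness_trace = self.optimization.fitness_trace
        self.evaluation_count = self.optimization.evaluation_count
        self.seed = self.optimization.seed
        self.converged = bool(np.isfinite(self.optimization.best_fitness))
        out_tr = net.forward(top, self.params, m.X_train)
        out_te = net.forward(top, self.params, m.X_test)
        self.mse_train = net.mse(out_tr, m.Y_train)
        self.mse_test = net.mse(out_te, m.Y_test)
        self.rmse_test = float(np.sqrt(self.mse_test))
        self.accuracy_test = float(
            np.mean(net.predict_labels(out_te) == m.y_test))
        if m.n_classes == 2 and len(np.unique(m.y_test)) == 2:
            self.auc_test = net.roc_auc(out_te[:, 1], m.y_test)
        else:
            self.auc_test = float("nan")

    def predict_proba(self, X=None) -> np.ndarray:
        """Sigmoid outputs for raw (unscaled) features; defaults to the
        held-out test rows."""
        m = self.model
        if X is None:
            Xs = m.X_test
        else:
            if isinstance(X, pd.DataFrame):
                X = X.to_numpy(dtype=float)
            Xs = apply_minmax(m.scaler, m.imputer.transform(np.atleast_2d(X)))
        return net.forward(m.topology, self.params, Xs)

    def predict(self, X=None) -> np.ndarray:
        return net.predict_labels(self.predict_proba(X))

    def summary(self) -> str:
        m = self.model
        rows = [
            ("Topology", str(m.topology)),
            ("Parameters", str(net.count_parameters(m.topology))),
            ("Optimizer", self.method),
            ("Seed", str(self.seed)),
            ("Objective evaluations", str(self.evaluation_count)),
            ("Train samples / Test samples",
             f"{m.X_train.shape[0]} / {m.X_test.shape[0]}"),
            ("Train MSE", f"{self.mse_train:.5f}"),
            ("Test MSE", f"{self.mse_test:.5f}"),
            ("Test RMSE", f"{self.rmse_test:.5f}"),
            ("Test AUC", f"{self.auc_test:.4f}"),
            ("Test accuracy", f"{self.accuracy_test:.4f}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Sigmoid MLP classification results",
                 "=" * (width + 26)]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        lines.append("=" * (width + 26))
        return "\n".join(lines)

    def __repr__(self):
        return (f"<SwarmMLPResults method={self.method} "
                f"test_mse={self.mse_test:.4f} auc={self.auc_test:.3f}>")
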