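"""Backpropagation baselines for the sigmoid MLP.

Exact analytic gradients of the all-entries MSE through sigmoid layers,
plus the classic first-order update rules used as comparison optimizers:
full-batch gradient descent, mini-batch SGD, Adadelta, RMSprop and Adam.
Learning rates default to the conventional framework defaults per method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network import Topology, count_parameters, decode_parameters, forward, mse, sigmoid
from .swarm import OptimizationResult

__all__ = ["GradientConfig", "backprop_gradient", "train_gradient", "GRADIENT_METHODS"]

GRADIENT_METHODS = ("grad", "sgd", "adadelta", "rmsprop", "adam")

_DEFAULT_LR = {"grad": 0.1, "sgd": 0.1, "adadelta": 1.0, "rmsprop": 0.001,
               "adam": 0.001}


@dataclass
class GradientConfig:
    """First-order training settings.

    ``grad`` is full-batch fixed-step descent; ``sgd`` is the same rule on
    shuffled mini-batches of ``batch_size`` (one iteration = one epoch).
    Remaining hyper-parameters follow the usual defaults: Adadelta
    (rho=0.95, eps=1e-6), RMSprop (rho=0.9), Adam (beta1=0.9, beta2=0.999,
    eps=1e-8).
    """

    method: str = "adam"
    learning_rate: Optional[float] = None
    iterations: int = 2000
    batch_size: int = 32        # sgd only
    rho: float = 0.95           # adadelta decay
    rms_rho: float = 0.9        # rmsprop decay
    eps: float = 1e-6           # adadelta epsilon
    rms_eps: float = 1e-8
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    init_scale: float = 0.5     # uniform(-s, s) initialization

    def __post_init__(self):
        if self.method not in GRADIENT_METHODS:
            raise ValueError(f"unknown gradient method {self.method!r}")
        if self.learning_rate is None:
            self.learning_rate = _DEFAULT_LR[self.method]
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def backprop_gradient(topology: Topology, flat: np.ndarray,
                      X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Exact gradient of ``mse(forward(topology, flat, X), Y)`` w.r.t. ``flat``.

    Standard reverse-mode chain rule with sigma'(z) = a(1-a); validated in
    the test suite against central finite differences.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    layers = decode_parameters(flat, topology)
    activations = [X]
    a = X
    for W, b in layers:
        a = sigmoid(a @ W + b)
        activations.append(a)
    out = activations[-1]
    if out.shape != Y.shape:
        raise ValueError("target shape does not match network output")
    n_entries = out.size
    # d(mean squared error)/d(output), then through each sigmoid
    delta = 2.0 * (out - Y) / n_entries * out * (1.0 - out)
    grads = [None] * len(layers)
    for li in range(len(layers) - 1, -1, -1):
        a_prev = activations[li]
        gW = a_prev.T @ delta
        gb = delta.sum(axis=0)
        grads[li] = (gW, gb)
        if li > 0:
            W, _ = layers[li]
            a_prev_act = activations[li]
            delta = (delta @ W.T) * a_prev_act * (1.0 - a_prev_act)
    return np.concatenate([np.concatenate([gW.ravel(), gb]) for gW, gb in grads])


def _make_stepper(config: GradientConfig, n_params: int):
    """Return step(theta, grad, t) implementing the configured update rule."""
    lr = config.learning_rate
    if config.method in ("grad", "sgd"):
        def step(theta, g, t):
            return theta - lr * g
    elif config.method == "adadelta":
        Eg = np.zeros(n_params)
        Ed = np.zeros(n_params)

        def step(theta, g, t):
            nonlocal Eg, Ed
            Eg = config.rho * Eg + (1 - config.rho) * g * g
            upd = -np.sqrt(Ed + config.eps) / np.sqrt(Eg + config.eps) * g
            Ed = config.rho * Ed + (1 - config.rho) * upd * upd
            return theta + lr * upd
    elif config.method == "rmsprop":
        Eg = np.zeros(n_params)

        def step(theta, g, t):
            nonlocal Eg
            Eg = config.rms_rho * Eg + (1 - config.rms_rho) * g * g
            return theta - lr * g / (np.sqrt(Eg) + config.rms_eps)
    else:  # adam
        m = np.zeros(n_params)
        v = np.zeros(n_params)

        def step(theta, g, t):
            nonlocal m, v
            m = config.beta1 * m + (1 - config.beta1) * g
            v = config.beta2 * v + (1 - config.beta2) * g * g
            mhat = m / (1 - config.beta1 ** t)
            vhat = v / (1 - config.beta2 ** t)
            return theta - lr * mhat / (np.sqrt(vhat) + config.adam_eps)
    return step


def train_gradient(topology: Topology, X: np.ndarray, Y: np.ndarray,
                   config: GradientConfig,
                   seed: Optional[int] = None) -> OptimizationResult:
    """Train the sigmoid MLP with a first-order method.

    Parameters start uniform(-init_scale, init_scale) from ``seed``.  The
    fitness trace records the best-so-far full-batch training MSE per
    iteration.  A non-finite loss marks the run failed (``best_fitness``
    NaN) and stops it.
    """
    rng = np.random.default_rng(seed)
    n_params = count_parameters(topology)
    theta = rng.uniform(-config.init_scale, config.init_scale, size=n_params)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = X.shape[0]

    step = _make_stepper(config, n_params)
    best_theta = theta.copy()
    best_loss = mse(forward(topology, theta, X), Y)
    trace = np.empty(config.iterations)
    mean_trace = np.empty(config.iterations)
    n_evals = 1
    failed = False

    for t in range(1, config.iterations + 1):
        if config.method == "sgd":
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                g = backprop_gradient(topology, theta, X[idx], Y[idx])
                theta = step(theta, g, t)
        else:
            g = backprop_gradient(topology, theta, X, Y)
            theta = step(theta, g, t)
        loss = mse(forward(topology, theta, X), Y)
        n_evals += 1
        if not math.isfinite(loss):
            trace[t - 1:] = np.nan
            mean_trace[t - 1:] = np.nan
            failed = True
            break
        if loss < best_loss:
            best_loss = loss
            best_theta = theta.copy()
        trace[t - 1] = best_loss
        mean_trace[t - 1] = loss

    return OptimizationResult(
        best_position=best_theta,
        best_fitness=float("nan") if failed else float(best_loss),
        fitness_trace=trace,
        mean_fitness_trace=mean_trace,
        evaluation_count=n_evals,
        seed=seed,
        algorithm=config.method,
        config={"method": config.method, "learning_rate": config.learning_rate,
                "iterations": config.iterations,
                "batch_size": config.batch_size if config.method == "sgd" else None},
    )
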