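"""Feed-forward sigmoid multilayer perceptron on a flat parameter vector.

The network is deliberately minimal: every neuron (hidden and output) uses
the logistic sigmoid, and all weights and biases live in one flat vector so
that derivative-free optimizers can treat the network as a black-box
objective.  Layout: for each consecutive layer pair, the weight matrix in
row-major order followed by the bias vector.

Fitness is the mean squared error between sigmoid outputs and one-hot
targets, averaged over every (sample, output) entry — so a constant-0.5
predictor scores exactly 0.25 on one-hot targets regardless of topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "Topology",
    "count_parameters",
    "decode_parameters",
    "encode_parameters",
    "forward",
    "sigmoid",
    "mse",
    "rmse",
    "roc_auc",
    "predict_labels",
    "save_parameters",
    "load_parameters",
]


@dataclass(frozen=True)
class Topology:
    """Layer sizes of a fully connected network: inputs, hidden layers, outputs."""

    n_inputs: int
    hidden_sizes: tuple
    n_outputs: int

    def __post_init__(self):
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))
        sizes = (self.n_inputs, *self.hidden_sizes, self.n_outputs)
        if any(s < 1 for s in sizes):
            raise ValueError(f"all layer sizes must be >= 1, got {sizes}")

    @property
    def layer_sizes(self) -> tuple:
        return (self.n_inputs, *self.hidden_sizes, self.n_outputs)

    @classmethod
    def parse(cls, text: str) -> "Topology":
        """Parse '24-18-9-3-2' or '24,18,9,3,2' (inputs, hidden..., outputs)."""
        parts = [int(p) for p in text.replace(",", "-").split("-")]
        if len(parts) < 2:
            raise ValueError("need at least input and output sizes")
        return cls(parts[0], tuple(parts[1:-1]), parts[-1])

    def __str__(self):
        return "-".join(str(s) for s in self.layer_sizes)


def count_parameters(topology: Topology) -> int:
    """Total adjustable parameters: sum over layer pairs of (fan_in + 1) * fan_out."""
    sizes = topology.layer_sizes
    return int(sum((a + 1) * b for a, b in zip(sizes[:-1], sizes[1:])))


def decode_parameters(flat: np.ndarray, topology: Topology):
    """Flat vector -> list of (W, b) per layer; strict length check."""
    flat = np.asarray(flat, dtype=float).ravel()
    expected = count_parameters(topology)
    if flat.size != expected:
        raise ValueError(
            f"parameter vector of length {flat.size}; topology {topology} "
            f"needs {expected}")
    layers = []
    sizes = topology.layer_sizes
    pos = 0
    for a, b in zip(sizes[:-1], sizes[1:]):
        W = flat[pos:pos + a * b].reshape(a, b)
        pos += a * b
        bias = flat[pos:pos + b]
        pos += b
        layers.append((W, bias))
    return layers


def encode_parameters(layers, topology: Topology) -> np.ndarray:
    """Inverse of :func:`decode_parameters`."""
    parts = []
    sizes = topology.layer_sizes
    if len(layers) != len(sizes) - 1:
        raise ValueError("layer count does not match topology")
    for (W, b), (a, c) in zip(layers, zip(sizes[:-1], sizes[1:])):
        W = np.asarray(W, dtype=float)
        b = np.asarray(b, dtype=float)
        if W.shape != (a, c) or b.shape != (c,):
            raise ValueError("layer shapes do not match topology")
        parts.append(W.ravel())
        parts.append(b)
    return np.concatenate(parts)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic sigmoid (two-branch form, inputs clipped
    at +-500 before exponentiation)."""
    z = np.clip(z, -500.0, 500.0)
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(topology: Topology, flat: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Network outputs for a batch: sigmoid(W a + b) at every layer.

    Returns an (n_samples, n_outputs) array with entries in (0, 1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != topology.n_inputs:
        raise ValueError(
            f"X has {X.shape[1]} features; topology expects {topology.n_inputs}")
    a = X
    for W, b in decode_parameters(flat, topology):
        a = sigmoid(a @ W + b)
    return a


def mse(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared error over every (sample, output) entry."""
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.shape != targets.shape:
        raise ValueError("predictions and targets must share a shape")
    if predictions.size == 0:
        raise ValueError("empty batch")
    return float(np.mean((predictions - targets) ** 2))


def rmse(predictions: np.ndarray, targets: np.ndarray) -> float:
    return float(np.sqrt(mse(predictions, targets)))


def roc_auc(scores: np.ndarray, binary_labels: np.ndarray) -> float:
    """Rank-statistic (Mann-Whitney) AUC of the positive-class score; ties
    contribute one half.  Requires both classes present."""
    binary_labels = np.asarray(binary_labels).astype(int)
    if len(np.unique(binary_labels)) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(binary_labels, np.asarray(scores, dtype=float)))


def predict_labels(outputs: np.ndarray) -> np.ndarray:
    """Argmax class per row; ties break toward the lower class index."""
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float))
    return np.argmax(outputs, axis=1)


def save_parameters(path, flat: np.ndarray, topology: Topology) -> None:
    """Write the flat vector as CSV with a JSON sidecar recording the topology."""
    np.savetxt(path, np.asarray(flat, dtype=float).ravel(), delimiter=",")
    with open(str(path) + ".json", "w") as fh:
        json.dump({"n_inputs": topology.n_inputs,
                   "hidden_sizes": list(topology.hidden_sizes),
                   "n_outputs": topology.n_outputs}, fh)


def load_parameters(path):
    flat = np.loadtxt(path, delimiter=",")
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    top = Topology(meta["n_inputs"], tuple(meta["hidden_sizes"]), meta["n_outputs"])
    if flat.size != count_parameters(top):
        raise ValueError("parameter file does not match its topology sidecar")
    return flat.ravel(), top
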