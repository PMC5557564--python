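"""Multi-layer perceptron with logistic units throughout.

Architecture: the scaled input vector feeds one or more equal-width hidden
layers and an output layer with one logistic neuron per class; forward
propagation is

    a(1) = x,   a(l) = g(W(l-1) a(l-1) + b(l-1)),  l = 2..L.

The network is trained as a single multi-output model by minimizing the
mean squared error between one-hot class memberships and the output vector,

    J = (1/m) sum_i sum_k (y_k_i - a_k_i)^2,

with gradients by backpropagation and RProp as the minimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ModelIntegrityError
from ..selection import RPropSettings, rprop_minimize
from .nlr import Prediction, sigmoid, threshold_decision


@dataclass
class MLPModel:
    weights: list[np.ndarray]  # W(l): (width_out, width_in)
    biases: list[np.ndarray]   # b(l): (width_out,)
    th: float = 0.5

    def __post_init__(self):
        if len(self.weights) != len(self.biases):
            raise ModelIntegrityError("weights/biases layer counts differ")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape[0] != b.shape[0]:
                raise ModelIntegrityError(f"layer {l}: bias length != weight rows")
            if l > 0 and w.shape[1] != self.weights[l - 1].shape[0]:
                raise ModelIntegrityError(f"layer {l}: input width mismatch")

    @property
    def layout(self) -> tuple[int, ...]:
        return (self.weights[0].shape[1], *(w.shape[0] for w in self.weights))

    @property
    def n_classes(self) -> int:
        return self.weights[-1].shape[0]


def layer_shapes(input_dim: int, n_layers: int, n_neurons: int,
                 n_classes: int) -> list[tuple[int, int]]:
    widths = [input_dim] + [n_neurons] * n_layers + [n_classes]
    return [(widths[i + 1], widths[i]) for i in range(len(widths) - 1)]


def pack(weights: list[np.ndarray], biases: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([np.concatenate([w.ravel(), b])
                           for w, b in zip(weights, biases)])


def unpack(theta: np.ndarray, shapes: list[tuple[int, int]]
           ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases, pos = [], [], 0
    for out_w, in_w in shapes:
        weights.append(theta[pos:pos + out_w * in_w].reshape(out_w, in_w))
        pos += out_w * in_w
        biases.append(theta[pos:pos + out_w])
        pos += out_w
    return weights, biases


def forward_mlp(model: MLPModel, x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Forward propagation; returns the activation stack (a(1)..a(L)) and
    the output vector(s) Pv."""
    a = np.atleast_2d(np.asarray(x, float))
    if a.shape[1] != model.layout[0]:
        raise ModelIntegrityError(
            f"input width {a.shape[1]} != model input width {model.layout[0]}")
    stack = [a]
    for w, b in zip(model.weights, model.biases):
        a = sigmoid(a @ w.T + b)
        stack.append(a)
    return stack, stack[-1]


def mse_cost_and_gradient(theta: np.ndarray, shapes: list[tuple[int, int]],
                          X: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over one-hot targets and its backprop gradient."""
    weights, biases = unpack(theta, shapes)
    m = X.shape[0]
    activations = [X]
    a = X
    for w, b in zip(weights, biases):
        a = sigmoid(a @ w.T + b)
        activations.append(a)
    out = activations[-1]
    cost = float(np.sum((Y - out) ** 2) / m)

    grads_w, grads_b = [], []
    delta = (2.0 / m) * (out - Y) * out * (1.0 - out)
    for l in range(len(weights) - 1, -1, -1):
        grads_w.append(delta.T @ activations[l])
        grads_b.append(delta.sum(axis=0))
        if l > 0:
            a_prev = activations[l]
            delta = (delta @ weights[l]) * a_prev * (1.0 - a_prev)
    grads_w.reverse()
    grads_b.reverse()
    return cost, pack(grads_w, grads_b)


def train_mlp(split, n_layers: int, n_neurons: int, th: float = 0.5,
              settings: RPropSettings = RPropSettings(),
              seed: int = 0) -> MLPModel:
    """Train one multi-output MLP on TR (seeded uniform [-0.5, 0.5] init)."""
    X, y = split.TR.X, split.TR.y
    classes = int(y.max()) + 1
    Y = np.eye(classes)[y]
    shapes = layer_shapes(X.shape[1], n_layers, n_neurons, classes)
    rng = np.random.default_rng(seed)
    n_par = sum(o * i + o for o, i in shapes)
    theta0 = rng.uniform(-0.5, 0.5, n_par)
    theta, _ = rprop_minimize(
        lambda t: mse_cost_and_gradient(t, shapes, X, Y), theta0, settings)
    weights, biases = unpack(theta, shapes)
    return MLPModel(weights=weights, biases=biases, th=th)


def predict_mlp(model: MLPModel, x: np.ndarray) -> Prediction:
    _, pv = forward_mlp(model, x)
    labels, low_conf = threshold_decision(pv, model.th)
    return Prediction(probabilities=pv, labels=labels, low_confidence=low_conf)
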