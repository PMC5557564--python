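"""Nonlinear logistic regression (one-vs-all) on polynomial features.

Each of the K classes gets an independent binary logistic unit

    P(c | x) = g(theta_c . phi(x) + theta0_c),   g(z) = 1 / (1 + e^-z)

trained by minimizing the unregularized cross-entropy with RProp. The
per-class probabilities are used as-is (no softmax normalisation). A label
is emitted for the highest probability at or above the decision threshold
TH; if no class clears TH the argmax is still returned, flagged
low-confidence, so downstream scoring always has a label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ModelIntegrityError
from ..selection import RPropSettings, rprop_minimize
from .poly import PolyFeatureMap

_EPS = 1e-12


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class Prediction:
    """Class-membership probabilities plus thresholded labels."""

    probabilities: np.ndarray  # (n, K)
    labels: np.ndarray         # (n,)
    low_confidence: np.ndarray  # (n,) bool: no class reached TH


@dataclass
class NLRModel:
    weights: np.ndarray   # (K, n_terms)
    biases: np.ndarray    # (K,)
    feature_map: PolyFeatureMap
    th: float = 0.5

    def __post_init__(self):
        if self.weights.shape != (len(self.biases), self.feature_map.n_terms):
            raise ModelIntegrityError("NLR weight shape inconsistent with feature map")

    @property
    def n_classes(self) -> int:
        return len(self.biases)


def cross_entropy_cost(theta: np.ndarray, phi: np.ndarray, y: np.ndarray
                       ) -> tuple[float, np.ndarray]:
    """Binary cross-entropy and gradient; theta = [w..., b]."""
    m = len(y)
    z = phi @ theta[:-1] + theta[-1]
    p = np.clip(sigmoid(z), _EPS, 1.0 - _EPS)
    cost = -np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    resid = (p - y) / m
    return float(cost), np.concatenate([phi.T @ resid, [resid.sum()]])


def train_nlr(split, degree: int, th: float = 0.5,
              settings: RPropSettings = RPropSettings(),
              seed: int = 0) -> NLRModel:
    """Fit K one-vs-all logistic units on TR with RProp (seeded init in
    [-0.5, 0.5])."""
    X, y = split.TR.X, split.TR.y
    fmap = PolyFeatureMap(input_dim=X.shape[1], degree=degree)
    phi = fmap.expand(X)
    classes = int(y.max()) + 1
    rng = np.random.default_rng(seed)
    weights = np.empty((classes, fmap.n_terms))
    biases = np.empty(classes)
    for c in range(classes):
        target = (y == c).astype(float)
        theta0 = rng.uniform(-0.5, 0.5, fmap.n_terms + 1)
        theta, _ = rprop_minimize(
            lambda t: cross_entropy_cost(t, phi, target), theta0, settings)
        weights[c] = theta[:-1]
        biases[c] = theta[-1]
    return NLRModel(weights=weights, biases=biases, feature_map=fmap, th=th)


def nlr_probabilities(model: NLRModel, x: np.ndarray) -> np.ndarray:
    phi = model.feature_map.expand(np.atleast_2d(np.asarray(x, float)))
    return sigmoid(phi @ model.weights.T + model.biases)


def threshold_decision(probs: np.ndarray, th: float) -> tuple[np.ndarray, np.ndarray]:
    """Label = argmax over classes with P >= TH; fallback plain argmax,
    flagged low-confidence.  Ties resolve to the lowest class index."""
    probs = np.atleast_2d(probs)
    low_conf = probs.max(axis=1) < th
    return probs.argmax(axis=1), low_conf


def predict_nlr(model: NLRModel, x: np.ndarray) -> Prediction:
    probs = nlr_probabilities(model, x)
    labels, low_conf = threshold_decision(probs, model.th)
    return Prediction(probabilities=probs, labels=labels, low_confidence=low_conf)
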