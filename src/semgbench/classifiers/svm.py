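"""RBF-kernel support vector machine (one-vs-one) with landmark accounting.

The kernel similarity between an input x and a landmark (support vector)
s_j follows the convention

    f_j = exp(-|x - s_j|^2 / (2 gamma)),

where larger gamma means a wider kernel.  Most libraries (including
libsvm/scikit-learn) parameterise the exponent as gamma' * |x - s|^2 with
gamma' = 1 / (2 gamma); converters are provided.  Training is delegated to
the libsvm solver behind :class:`sklearn.svm.SVC`; multiclass prediction is
a one-vs-one majority vote over the signs of the pairwise decision values,
with ties resolved to the lowest class index.

The memory-relevant parameter count of a fitted model is the storage the
solver needs at run time: the support-vector matrix ``SVs`` (nSV x dim),
the dual coefficients ``sv_coef`` (nSV x (K-1)) and the pairwise offsets
``rho`` (K(K-1)/2 values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from ..errors import ConfigurationError


def gamma_to_sklearn(gamma: float) -> float:
    """Convert the 1/(2 gamma) exponent convention to sklearn's gamma'."""
    if gamma <= 0:
        raise ConfigurationError("gamma must be > 0")
    return 1.0 / (2.0 * gamma)


def gamma_from_sklearn(gamma_prime: float) -> float:
    if gamma_prime <= 0:
        raise ConfigurationError("gamma' must be > 0")
    return 1.0 / (2.0 * gamma_prime)


def rbf_kernel(x: np.ndarray, landmarks: np.ndarray, gamma: float) -> np.ndarray:
    """Kernel similarities f_j between rows of x and each landmark."""
    x = np.atleast_2d(np.asarray(x, float))
    d2 = ((x[:, None, :] - landmarks[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * gamma))


@dataclass
class SVMModel:
    """Fitted one-vs-one RBF SVM plus the stored-parameter views."""

    estimator: SVC
    C: float
    gamma: float  # 1/(2 gamma) convention

    @property
    def support_vectors(self) -> np.ndarray:
        return self.estimator.support_vectors_

    @property
    def sv_coef(self) -> np.ndarray:
        return self.estimator.dual_coef_

    @property
    def rho(self) -> np.ndarray:
        return self.estimator.intercept_

    @property
    def n_classes(self) -> int:
        return len(self.estimator.classes_)


def train_svm_rbf(split, C: float, gamma: float, seed: int = 0) -> SVMModel:
    """Train a one-vs-one C-SVM with RBF kernel on TR.

    ``gamma`` uses the 1/(2 gamma) exponent convention. The solver is
    deterministic for a fixed dataset; ``seed`` is accepted for interface
    uniformity.
    """
    if C <= 0 or gamma <= 0:
        raise ConfigurationError("require C > 0 and gamma > 0")
    est = SVC(C=C, kernel="rbf", gamma=gamma_to_sklearn(gamma),
              decision_function_shape="ovo", tol=1e-3, cache_size=256)
    est.fit(split.TR.X, split.TR.y)
    return SVMModel(estimator=est, C=C, gamma=gamma)


def ovo_vote(decision_values: np.ndarray, n_classes: int) -> np.ndarray:
    """Majority vote over pairwise decision values.

    Columns follow the (0,1), (0,2), ..., (1,2), ... pair order; a
    non-negative value votes for the first (lower-index) class of the pair.
    Vote ties resolve to the lowest class index (np.argmax convention).
    """
    dv = np.atleast_2d(decision_values)
    votes = np.zeros((dv.shape[0], n_classes))
    col = 0
    for i in range(n_classes):
        for j in range(i + 1, n_classes):
            first = dv[:, col] >= 0
            votes[first, i] += 1
            votes[~first, j] += 1
            col += 1
    return votes.argmax(axis=1)


def predict_svm_rbf(model: SVMModel, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, float))
    classes = model.estimator.classes_
    dv = model.estimator.decision_function(x)
    if model.n_classes == 2:
        # binary: sklearn's decision value is positive for classes_[1]
        return np.where(dv.ravel() > 0, classes[1], classes[0])
    return classes[ovo_vote(dv, model.n_classes)]
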