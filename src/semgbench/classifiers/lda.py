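"""Linear discriminant analysis, closed form, one-vs-all argmax.

Training evaluates class means mu_c, the pooled (within-class) covariance
Sigma, and priors Pi_c, then forms per-class linear scores

    score_c(x) = beta_c . x + beta0_c,
    beta_c  = Sigma^-1 mu_c,
    beta0_c = -beta_c . (mu_c / 2) + ln Pi_c,

with the predicted class the argmax over scores (ties to the lowest class
index).  For two classes this reduces algebraically to the classical sign
rule on beta = Sigma^-1 (mu_1 - mu_2).  When Sigma is ill-conditioned a
small ridge lambda = 1e-6 * trace(Sigma)/dim is added.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ModelIntegrityError, StratificationError

_COND_LIMIT = 1e12


@dataclass
class LDAModel:
    coefs: np.ndarray       # (K, d) per-class beta_c
    intercepts: np.ndarray  # (K,)  per-class beta0_c
    means: np.ndarray       # (K, d)
    pooled_cov: np.ndarray  # (d, d)
    priors: np.ndarray      # (K,)

    def __post_init__(self):
        if self.coefs.shape != self.means.shape:
            raise ModelIntegrityError("LDA coefs/means shapes differ")

    @property
    def n_classes(self) -> int:
        return self.coefs.shape[0]


def pooled_covariance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Within-class scatter divided by (n - K)."""
    classes = np.unique(y)
    d = X.shape[1]
    scatter = np.zeros((d, d))
    for c in classes:
        xc = X[y == c]
        if len(xc) < 2:
            raise StratificationError(f"class {c} needs >= 2 samples for covariance")
        diff = xc - xc.mean(axis=0)
        scatter += diff.T @ diff
    return scatter / (len(y) - len(classes))


def train_lda(X: np.ndarray, y: np.ndarray,
              priors: np.ndarray | None = None) -> LDAModel:
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.arange(int(y.max()) + 1)
    means = np.vstack([X[y == c].mean(axis=0) if np.any(y == c) else np.zeros(X.shape[1])
                       for c in classes])
    if priors is None:
        priors = np.array([np.mean(y == c) for c in classes])
    sigma = pooled_covariance(X, y)
    if np.linalg.cond(sigma) > _COND_LIMIT:
        sigma = sigma + (1e-6 * np.trace(sigma) / sigma.shape[0]) * np.eye(sigma.shape[0])
    sigma_inv = np.linalg.inv(sigma)
    coefs = means @ sigma_inv.T
    with np.errstate(divide="ignore"):
        log_priors = np.log(priors)
    intercepts = -0.5 * np.einsum("cd,cd->c", coefs, means) + log_priors
    return LDAModel(coefs=coefs, intercepts=intercepts, means=means,
                    pooled_cov=sigma, priors=priors)


def lda_scores(model: LDAModel, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, float))
    return x @ model.coefs.T + model.intercepts


def predict_lda(model: LDAModel, x: np.ndarray) -> np.ndarray:
    return lda_scores(model, x).argmax(axis=1)
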