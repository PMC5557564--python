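"""The four classifiers compared in the study, with a uniform
train / predict / count-parameters contract.

``count_parameters`` returns the memory-relevant cardinality of a trained
model's classification parameters (weights and biases included):

========  =======================================================
NLR       K x (n_poly_terms + 1)
MLP       sum over layers of (width_out x width_in + width_out)
SVM       nSV x dim  +  nSV x (K - 1)  +  K(K - 1)/2
LDA       K x (n_features + 1)
========  =======================================================
"""

from __future__ import annotations

import json

import numpy as np

from .lda import LDAModel, lda_scores, predict_lda, train_lda
from .mlp import MLPModel, forward_mlp, predict_mlp, train_mlp
from .nlr import (NLRModel, Prediction, nlr_probabilities, predict_nlr,
                  sigmoid, threshold_decision, train_nlr)
from .poly import PolyFeatureMap, expand_poly_features
from .svm import (SVMModel, gamma_from_sklearn, gamma_to_sklearn, ovo_vote,
                  predict_svm_rbf, rbf_kernel, train_svm_rbf)

CLASSIFIER_NAMES = ("nlr", "mlp", "svm", "lda")


def count_parameters(model) -> int:
    """Number of stored classification parameters of a trained model."""
    if isinstance(model, NLRModel):
        return model.weights.size + model.biases.size
    if isinstance(model, MLPModel):
        return sum(w.size + b.size for w, b in zip(model.weights, model.biases))
    if isinstance(model, SVMModel):
        return (model.support_vectors.size + model.sv_coef.size + model.rho.size)
    if isinstance(model, LDAModel):
        return model.coefs.size + model.intercepts.size
    raise TypeError(f"unknown model type {type(model).__name__}")


def model_to_dict(model) -> dict:
    """JSON-serializable view of a trained model's parameters."""
    if isinstance(model, NLRModel):
        return {"kind": "nlr", "th": model.th,
                "degree": model.feature_map.degree,
                "input_dim": model.feature_map.input_dim,
                "weights": model.weights.tolist(), "biases": model.biases.tolist()}
    if isinstance(model, MLPModel):
        return {"kind": "mlp", "th": model.th,
                "weights": [w.tolist() for w in model.weights],
                "biases": [b.tolist() for b in model.biases]}
    if isinstance(model, SVMModel):
        return {"kind": "svm", "C": model.C, "gamma": model.gamma,
                "support_vectors": model.support_vectors.tolist(),
                "sv_coef": model.sv_coef.tolist(), "rho": model.rho.tolist()}
    if isinstance(model, LDAModel):
        return {"kind": "lda", "coefs": model.coefs.tolist(),
                "intercepts": model.intercepts.tolist(),
                "priors": model.priors.tolist()}
    raise TypeError(f"unknown model type {type(model).__name__}")


def save_model(path, model) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)
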