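"""Confusion statistics, the F1Score, and the Embedding Optimization Factor.

Per class c the one-vs-rest tallies are nP (true positives), nFN, nFP and
nN; precision and recall combine into the per-class F1 on a 0-100 scale,

    F1 = 2 * PR * RE / (PR + RE) * 100,

and the reported aggregate is the unweighted macro mean over classes.

The EOF scores how well a model of nθ parameters exploits a fixed memory
budget: with NΘ the largest parameter count that fits the budget,

    P   = (NΘ - nθ) / NΘ * 100   if nθ < NΘ else 0,
    EOF = 2 * F1 * P / (F1 + P),

i.e. the harmonic mean of classification performance and the normalized
free-memory fraction; a model that does not fit scores 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K), rows = true class, cols = predicted

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int) -> dict[str, int]:
        """2x2 tallies for class ``c`` against the rest."""
        nP = int(self.counts[c, c])
        nFN = int(self.counts[c].sum() - nP)
        nFP = int(self.counts[:, c].sum() - nP)
        nN = self.total - nP - nFN - nFP
        return {"nP": nP, "nN": nN, "nFP": nFP, "nFN": nFN}


@dataclass
class ClassMetrics:
    precision: np.ndarray   # per class, 0-1
    recall: np.ndarray      # per class, 0-1
    f1_per_class: np.ndarray  # per class, 0-100
    aggregate_f1: float     # macro mean, 0-100


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, np.int64)
    y_pred = np.asarray(y_pred, np.int64)
    if y_true.shape != y_pred.shape:
        raise ConfigurationError("label vectors must have equal length")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    counts = np.zeros((n_classes, n_classes), np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts=counts)


def f1score(y_true: np.ndarray, y_pred: np.ndarray,
            n_classes: int | None = None) -> tuple[ConfusionMatrix, ClassMetrics]:
    """Per-class precision/recall/F1 and the macro-aggregate F1 (0-100)."""
    cm = confusion_matrix(y_true, y_pred, n_classes)
    K = cm.n_classes
    pr = np.zeros(K)
    re = np.zeros(K)
    f1 = np.zeros(K)
    for c in range(K):
        t = cm.one_vs_rest(c)
        denom_pr = t["nP"] + t["nFN"]
        denom_re = t["nP"] + t["nFP"]
        if denom_pr == 0 and denom_re == 0:
            warnings.warn(f"class {c} absent from both truth and predictions; "
                          "F1 defined 0", stacklevel=2)
            continue
        pr[c] = t["nP"] / denom_pr if denom_pr else 0.0
        re[c] = t["nP"] / denom_re if denom_re else 0.0
        if pr[c] + re[c] > 0:
            f1[c] = 2.0 * pr[c] * re[c] / (pr[c] + re[c]) * 100.0
    return cm, ClassMetrics(precision=pr, recall=re, f1_per_class=f1,
                            aggregate_f1=float(f1.mean()))


@dataclass(frozen=True)
class EOFConfig:
    """Memory budget for the embedded deployment (default 256 KB, 4-byte
    floats, hence at most 64000 storable parameters; the budget arithmetic
    uses decimal kilobytes, as microcontroller datasheets do)."""

    memory_bytes: int = 256_000
    bytes_per_parameter: int = 4

    def __post_init__(self):
        if self.max_parameters < 1:
            raise ConfigurationError("memory budget must hold at least one parameter")

    @property
    def max_parameters(self) -> int:
        return self.memory_bytes // self.bytes_per_parameter


def eof_index(f1: float, n_parameters: int,
              config: EOFConfig = EOFConfig()) -> float:
    """Embedding Optimization Factor on the 0-100 scale."""
    if not 0.0 <= f1 <= 100.0:
        raise ConfigurationError("f1 must be within [0, 100]")
    if n_parameters < 0:
        raise ConfigurationError("n_parameters must be >= 0")
    n_max = config.max_parameters
    p = (n_max - n_parameters) / n_max * 100.0 if n_parameters < n_max else 0.0
    if f1 + p == 0.0:
        return 0.0
    return 2.0 * f1 * p / (f1 + p)


@dataclass
class EvaluationResult:
    """Scoring of one trained model on one evaluation set."""

    set_label: str           # "TS", "GS" or "TS30"
    confusion: ConfusionMatrix
    metrics: ClassMetrics
    n_parameters: int
    eof: float

    @classmethod
    def from_predictions(cls, set_label: str, y_true, y_pred, n_parameters: int,
                         eof_config: EOFConfig = EOFConfig(),
                         n_classes: int | None = None) -> "EvaluationResult":
        cm, metrics = f1score(y_true, y_pred, n_classes)
        return cls(set_label=set_label, confusion=cm, metrics=metrics,
                   n_parameters=n_parameters,
                   eof=eof_index(metrics.aggregate_f1, n_parameters, eof_config))

    def to_dict(self) -> dict:
        return {"set": self.set_label,
                "f1": self.metrics.aggregate_f1,
                "f1_per_class": self.metrics.f1_per_class.tolist(),
                "n_parameters": self.n_parameters,
                "eof": self.eof,
                "confusion": self.confusion.counts.tolist()}
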