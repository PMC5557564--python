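"""Polynomial interaction-feature encoding for nonlinear logistic regression.

The degree code D maps to: all products of *distinct* input variables of
size d for every d <= D, plus the pure powers x_i^d for every d in 2..D.
D = 1 is the plain linear case.  For 6 inputs this gives 6, 27, 53, 74, 86,
93 and 99 features for D = 1..7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ..errors import ConfigurationError

MAX_DEGREE = 7


def _build_terms(input_dim: int, degree: int) -> list[tuple[int, ...]]:
    """Term list, degree-major; within a degree distinct-variable products
    (lexicographic) precede pure powers."""
    terms: list[tuple[int, ...]] = []
    for d in range(1, degree + 1):
        terms.extend(combinations(range(input_dim), d))
        if d >= 2:
            terms.extend((i,) * d for i in range(input_dim))
    return terms


@dataclass(frozen=True)
class PolyFeatureMap:
    """Deterministic polynomial feature expansion of an input vector."""

    input_dim: int
    degree: int
    terms: tuple[tuple[int, ...], ...] = field(init=False)

    def __post_init__(self):
        if not 1 <= self.degree <= MAX_DEGREE:
            raise ConfigurationError(f"degree must be in 1..{MAX_DEGREE}, got {self.degree}")
        if self.input_dim < 1:
            raise ConfigurationError("input_dim must be >= 1")
        object.__setattr__(self, "terms", tuple(_build_terms(self.input_dim, self.degree)))

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def expand(self, x: np.ndarray) -> np.ndarray:
        """Expand (n, input_dim) or (input_dim,) into polynomial features."""
        x = np.asarray(x, float)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        if x.shape[1] != self.input_dim:
            raise ConfigurationError(
                f"expected {self.input_dim} input features, got {x.shape[1]}")
        out = np.empty((x.shape[0], self.n_terms))
        for j, term in enumerate(self.terms):
            out[:, j] = np.prod(x[:, term], axis=1)
        return out[0] if single else out


def expand_poly_features(x: np.ndarray, feature_map: PolyFeatureMap) -> np.ndarray:
    return feature_map.expand(x)
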