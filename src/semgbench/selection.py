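"""Model selection: RProp minimizer, internal-parameter grid search, and
the sequential complexity-selection statistic.

RProp (resilient backpropagation) adapts one step size per coordinate from
gradient signs alone: the step grows by ``eta_plus`` while the partial
derivative keeps its sign and shrinks by ``eta_minus`` when it flips (the
iRprop- rule: on a flip the coordinate does not move that iteration).
Because only signs matter, the iterate path is invariant to positive
rescaling of the cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, DivergenceError


@dataclass(frozen=True)
class RPropSettings:
    """iRprop- hyperparameters (conventional defaults)."""

    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_min: float = 1e-6
    delta_max: float = 50.0
    max_iterations: int = 500
    cost_tolerance: float = 1e-8

    def __post_init__(self):
        if not (0 < self.eta_minus < 1 < self.eta_plus):
            raise ConfigurationError("require 0 < eta_minus < 1 < eta_plus")
        if not (self.delta_min < self.delta0 < self.delta_max):
            raise ConfigurationError("require delta_min < delta0 < delta_max")


def rprop_minimize(cost_and_gradient: Callable[[np.ndarray], tuple[float, np.ndarray]],
                   theta0: np.ndarray,
                   settings: RPropSettings = RPropSettings()
                   ) -> tuple[np.ndarray, list[float]]:
    """Minimize a differentiable cost with iRprop-.

    Returns the final parameter vector and the cost trace (one entry per
    evaluated iterate, including the initial point).  Raises
    :class:`DivergenceError` if the cost or gradient turns non-finite.
    """
    theta = np.array(theta0, float, copy=True)
    cost, grad = cost_and_gradient(theta)
    if not (np.isfinite(cost) and np.all(np.isfinite(grad))):
        raise DivergenceError("non-finite cost/gradient at theta0", iteration=0)
    trace = [float(cost)]
    delta = np.full_like(theta, settings.delta0)
    prev_grad = np.zeros_like(theta)

    for it in range(settings.max_iterations):
        sign_prod = prev_grad * grad
        grown = sign_prod > 0
        flipped = sign_prod < 0
        delta[grown] = np.minimum(delta[grown] * settings.eta_plus, settings.delta_max)
        delta[flipped] = np.maximum(delta[flipped] * settings.eta_minus, settings.delta_min)
        grad = grad.copy()
        grad[flipped] = 0.0  # iRprop-: skip the move on a sign flip
        theta = theta - np.sign(grad) * delta
        prev_grad = grad
        cost, grad = cost_and_gradient(theta)
        if not (np.isfinite(cost) and np.all(np.isfinite(grad))):
            raise DivergenceError("non-finite cost/gradient during optimization",
                                  iteration=it + 1)
        trace.append(float(cost))
        if abs(trace[-1] - trace[-2]) < settings.cost_tolerance:
            break
    return theta, trace


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------

def svm_c_grid(start: float = 0.01, cap: float = 1e4) -> np.ndarray:
    """Regularization grid: ``start`` doubling while it stays within ``cap``."""
    vals = []
    c = start
    while c <= cap:
        vals.append(c)
        c *= 2.0
    return np.array(vals)


def svm_gamma_grid(upper: float = 50.0, pitch: float = 0.1) -> np.ndarray:
    """RBF width grid (0, upper] with the given pitch; 0 itself is excluded
    because the kernel exponent divides by gamma."""
    n = int(round(upper / pitch))
    return np.round(np.arange(1, n + 1) * pitch, 10)


@dataclass(frozen=True)
class GridSpec:
    """Internal-parameter grids for the three iteratively trained classifiers."""

    nlr_degrees: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    mlp_layers: tuple[int, ...] = tuple(range(1, 11))
    mlp_neurons: tuple[int, ...] = tuple(range(1, 31))
    svm_c: tuple[float, ...] = tuple(svm_c_grid())
    svm_gamma: tuple[float, ...] = tuple(svm_gamma_grid())

    def __post_init__(self):
        if not (self.nlr_degrees and self.mlp_layers and self.mlp_neurons
                and self.svm_c and self.svm_gamma):
            raise ConfigurationError("grids must be non-empty")
        if np.any(np.diff(self.svm_c) <= 0):
            raise ConfigurationError("C grid must be strictly increasing")


@dataclass
class SelectionResult:
    best_model: object
    best_config: dict
    table: list[dict]  # one row per configuration: params, cv_f1, n_parameters

    @property
    def best_cv_f1(self) -> float:
        return max(row["cv_f1"] for row in self.table if row["cv_f1"] is not None)


def _configurations(classifier: str, grid: GridSpec) -> list[dict]:
    if classifier == "nlr":
        return [{"degree": d} for d in grid.nlr_degrees]
    if classifier == "mlp":
        return [{"n_layers": l, "n_neurons": n}
                for l in grid.mlp_layers for n in grid.mlp_neurons]
    if classifier == "svm":
        return [{"C": c, "gamma": g} for c in grid.svm_c for g in grid.svm_gamma]
    raise ConfigurationError(f"unknown classifier '{classifier}'")


def grid_search(classifier: str, split, grid: GridSpec, seed: int,
                rprop: RPropSettings = RPropSettings(),
                th: float = 0.5) -> SelectionResult:
    """Train one model per grid configuration on TR, score F1 on CV, return
    the argmax (ties: fewest parameters, then grid order).

    A configuration whose training raises is recorded with ``cv_f1 = None``
    and skipped.  Per-configuration seeds are derived from (seed, index) so
    results do not depend on evaluation order.
    """
    from . import classifiers as _cls
    from .evaluation import f1score

    configs = _configurations(classifier, grid)
    table: list[dict] = []
    best = None  # (neg_f1, n_params, order) minimised
    for i, cfg in enumerate(configs):
        cfg_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        try:
            if classifier == "nlr":
                model = _cls.train_nlr(split, degree=cfg["degree"], th=th,
                                       settings=rprop, seed=cfg_seed)
                pred = _cls.predict_nlr(model, split.CV.X).labels
            elif classifier == "mlp":
                model = _cls.train_mlp(split, n_layers=cfg["n_layers"],
                                       n_neurons=cfg["n_neurons"], th=th,
                                       settings=rprop, seed=cfg_seed)
                pred = _cls.predict_mlp(model, split.CV.X).labels
            else:
                model = _cls.train_svm_rbf(split, C=cfg["C"], gamma=cfg["gamma"],
                                           seed=cfg_seed)
                pred = _cls.predict_svm_rbf(model, split.CV.X)
        except Exception as exc:  # non-convergence is recorded, not fatal
            warnings.warn(f"configuration {cfg} failed: {exc}", stacklevel=2)
            table.append({**cfg, "cv_f1": None, "n_parameters": None})
            continue
        _, metrics = f1score(split.CV.y, pred)
        n_par = _cls.count_parameters(model)
        table.append({**cfg, "cv_f1": metrics.aggregate_f1, "n_parameters": n_par})
        key = (-metrics.aggregate_f1, n_par, i)
        if best is None or key < best[0]:
            best = (key, model, cfg)
    if best is None:
        raise DivergenceError("every grid configuration failed to train")
    return SelectionResult(best_model=best[1], best_config=best[2], table=table)


def two_stage_svm_search(split, seed: int,
                         coarse_c: Sequence[float] | None = None,
                         coarse_gamma: Sequence[float] | None = None,
                         gamma_pitch: float = 0.1,
                         rprop: RPropSettings = RPropSettings(),
                         th: float = 0.5) -> SelectionResult:
    """Coarse-then-fine search over the (C, gamma) plane.

    Stage 1 scans a thinned C doubling sequence and a log-spread gamma
    subset; stage 2 refines around the stage-1 winner (C halved/doubled,
    gamma at the full grid pitch).  Far cheaper than the exhaustive
    ~20 x 500 grid while honouring the same ranges.
    """
    if coarse_c is None:
        coarse_c = svm_c_grid()[::3]
    if coarse_gamma is None:
        coarse_gamma = np.array([0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 50.0])
    stage1 = grid_search("svm", split,
                         GridSpec(svm_c=tuple(coarse_c),
                                  svm_gamma=tuple(coarse_gamma)),
                         seed=seed, rprop=rprop, th=th)
    c0, g0 = stage1.best_config["C"], stage1.best_config["gamma"]
    fine_c = sorted({min(max(c0 * f, 0.01), 1e4) for f in (0.5, 1.0, 2.0)})
    fine_g = sorted({round(g0 + k * gamma_pitch, 10) for k in (-2, -1, 0, 1, 2)}
                    & set(np.round(np.arange(gamma_pitch, 50.0 + gamma_pitch / 2,
                                             gamma_pitch), 10)))
    fine_g = [g for g in fine_g if g > 0] or [g0]
    stage2 = grid_search("svm", split,
                         GridSpec(svm_c=tuple(fine_c), svm_gamma=tuple(fine_g)),
                         seed=seed, rprop=rprop, th=th)
    # keep whichever stage won on CV F1 (stage 2 includes the stage-1 winner
    # unless it sat off the fine gamma lattice)
    best = stage2 if stage2.best_cv_f1 >= stage1.best_cv_f1 else stage1
    return SelectionResult(best_model=best.best_model,
                           best_config=best.best_config,
                           table=stage1.table + stage2.table)


# ---------------------------------------------------------------------------
# Sequential complexity selection
# ---------------------------------------------------------------------------

def sequential_complexity_selection(scores: np.ndarray, alpha: float = 0.05
                                    ) -> tuple[int, list[dict]]:
    """Select a model-complexity level from a (subjects x levels) score matrix.

    Levels must be ordered simplest to most complex.  Starting from the
    simplest level as benchmark, each subsequent level is compared with the
    benchmark by a paired Wilcoxon signed-rank test; a significant difference
    (p < alpha) promotes that level to the new benchmark.  The procedure
    returns the final benchmark - the last level whose differences with all
    subsequent levels are non-significant - plus the comparison log.
    """
    from .compare import wilcoxon_signed_rank

    scores = np.asarray(scores, float)
    if scores.ndim != 2 or scores.shape[1] < 1:
        raise ConfigurationError("scores must be a (subjects x levels) matrix")
    if scores.shape[0] < 6:
        raise ConfigurationError("need >= 6 subjects for the Wilcoxon comparisons")
    benchmark = 0
    log: list[dict] = []
    for level in range(1, scores.shape[1]):
        _, p = wilcoxon_signed_rank(scores[:, level], scores[:, benchmark])
        significant = p < alpha
        log.append({"benchmark": benchmark, "level": level,
                    "p": p, "significant": bool(significant)})
        if significant:
            benchmark = level
    return benchmark, log
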