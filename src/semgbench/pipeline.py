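"""End-to-end study runner over a cohort of synthetic subjects.

The study has three parts, executed in order by :func:`run_study`:

1. *Complexity-range selection* (at the 100 Hz downsampling step): the
   polynomial degree for NLR and the hidden-layer count, then width, for the
   MLP are selected with the sequential Wilcoxon procedure on per-subject
   test-set F1 scores.
2. *Classifier comparison across sampling rates*: NLR, MLP (at the selected
   complexities) and the grid-searched SVM are trained at every
   downsampling step and scored on TS and GS (F1, parameter count, EOF
   under the memory budget).
3. *Benchmark comparison*: for each subject the per-classifier model with
   the best EOF on GS is compared against the LDA branch (full-rate
   time-domain features, 70/30 split) on F1, parameter count and EOF, with
   pairwise Wilcoxon reports and a summary table (mean +/- std per
   classifier).

Every stage derives its seed from the global seed plus a stable stage key,
so a run is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifiers as cls
from .compare import PairedScores, pairwise_compare
from .errors import ConfigurationError
from .evaluation import EOFConfig, EvaluationResult
from .preprocessing import (FeatureWindowConfig, SplitConfig, downsample_split,
                            extract_td_features, stratified_split_70_30)
from .selection import (RPropSettings, sequential_complexity_selection,
                        svm_c_grid, two_stage_svm_search)
from .synthetic import (AcquisitionConfig, GestureProfile, default_profile,
                        generate_session)

CLASSIFIERS = ("nlr", "mlp", "svm")

# stage keys for seed derivation
_STAGES = {"profile": 0, "session": 1, "split": 2, "train": 3, "lda": 4}


def derive_seed(global_seed: int, *keys: int) -> int:
    """Stable sub-seed (< 2^31) from the global seed and integer keys."""
    return int(np.random.SeedSequence([global_seed, *keys]).generate_state(1)[0]
               % (2**31))


@dataclass(frozen=True)
class StudyConfig:
    """Conditions of the full comparison study.

    Defaults reproduce the protocol scale: a 30-subject cohort, downsampling
    steps {200, 100, 50, 25, 10} (5-100 Hz), degree guesses 1-7, layer
    guesses 1-10 and the compact neuron grid.  Smaller cohorts and grids can
    be configured for desk-scale runs.
    """

    n_subjects: int = 30
    acquisition: AcquisitionConfig = AcquisitionConfig()
    profile: GestureProfile | None = None  # None -> packaged default
    subject_variability: float = 0.15  # sd (volts) of per-subject mean shifts
    steps: tuple[int, ...] = (200, 100, 50, 25, 10)
    selection_step: int = 10  # part-1 downsampling step (100 Hz)
    nlr_degrees: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    mlp_layer_grid: tuple[int, ...] = tuple(range(1, 11))
    mlp_neuron_grid: tuple[int, ...] = (3, 8, 13, 18, 23, 28)
    mlp_neurons_for_layer_sweep: int = 8
    svm_c_grid: tuple[float, ...] = tuple(svm_c_grid()[::3])
    svm_gamma_grid: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 50.0)
    th: float = 0.5
    rprop: RPropSettings = RPropSettings(max_iterations=300)
    eof: EOFConfig = EOFConfig()
    feature_windows: FeatureWindowConfig = FeatureWindowConfig()
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("need at least one subject")
        if not self.steps:
            raise ConfigurationError("need at least one downsampling step")


@dataclass
class StudyResult:
    config: StudyConfig
    part1: dict
    part2: dict
    part3: dict

    def to_dict(self) -> dict:
        return {"part1": self.part1, "part2": self.part2, "part3": self.part3}


def study_config_to_yaml(config: StudyConfig, path: str | Path) -> None:
    """Serialize a StudyConfig (including nested sections) to YAML."""
    import yaml

    def clean(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    doc = clean(asdict(config))
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def study_config_from_yaml(path: str | Path) -> StudyConfig:
    """Load a StudyConfig written by :func:`study_config_to_yaml`."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    sections = {
        "acquisition": lambda d: AcquisitionConfig(
            **{**d, "gesture_names": tuple(d["gesture_names"]),
               "voltage_range": tuple(d["voltage_range"])}),
        "profile": lambda d: None if d is None else GestureProfile(
            **{**d, "mean_activation": np.asarray(d["mean_activation"], float)}),
        "rprop": lambda d: RPropSettings(**d),
        "eof": lambda d: EOFConfig(**d),
        "feature_windows": lambda d: FeatureWindowConfig(**d),
    }
    kwargs = {}
    for key, value in doc.items():
        if key in sections:
            kwargs[key] = sections[key](value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return StudyConfig(**kwargs)


def desk_scale_config(seed: int = 0, n_subjects: int = 8) -> StudyConfig:
    """A reduced operating point that preserves the study structure.

    Eight subjects, trimmed complexity grids and a compact SVM search keep a
    full three-part run in the minutes range on one core while exercising
    every stage at the full acquisition geometry (10^5 x 6 per session).
    """
    return StudyConfig(
        n_subjects=n_subjects,
        nlr_degrees=(1, 2, 3),
        mlp_layer_grid=(1, 2),
        mlp_neuron_grid=(4, 8, 16),
        mlp_neurons_for_layer_sweep=8,
        svm_c_grid=(0.1, 1.0, 10.0, 100.0),
        svm_gamma_grid=(0.3, 1.0, 3.0, 10.0),
        rprop=RPropSettings(max_iterations=200),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort plumbing
# ---------------------------------------------------------------------------

def subject_profile(base: GestureProfile, config: StudyConfig,
                    subject: int) -> GestureProfile:
    """Per-subject activation profile: the base means plus a seeded Gaussian
    shift per (class, channel), clipped to the sensor range."""
    if config.subject_variability == 0:
        return base
    rng = np.random.default_rng(
        derive_seed(config.seed, _STAGES["profile"], subject))
    lo, hi = config.acquisition.voltage_range
    shifted = base.mean_activation + rng.normal(
        0.0, config.subject_variability, base.mean_activation.shape)
    return replace(base, mean_activation=np.clip(shifted, lo, hi))


def subject_session(config: StudyConfig, subject: int):
    base = config.profile if config.profile is not None else default_profile()
    prof = subject_profile(base, config, subject)
    return generate_session(config.acquisition, prof,
                            derive_seed(config.seed, _STAGES["session"], subject))


def subject_split(config: StudyConfig, session, step: int, subject: int):
    return downsample_split(session, SplitConfig(
        downsample_step=step,
        seed=derive_seed(config.seed, _STAGES["split"], subject, step)))


def _train(config: StudyConfig, name: str, split, subject: int, step: int,
           settings: dict):
    seed = derive_seed(config.seed, _STAGES["train"], subject, step,
                       CLASSIFIERS.index(name))
    if name == "nlr":
        model = cls.train_nlr(split, degree=settings["degree"], th=config.th,
                              settings=config.rprop, seed=seed)
        predict = lambda X: cls.predict_nlr(model, X).labels
    elif name == "mlp":
        model = cls.train_mlp(split, n_layers=settings["n_layers"],
                              n_neurons=settings["n_neurons"], th=config.th,
                              settings=config.rprop, seed=seed)
        predict = lambda X: cls.predict_mlp(model, X).labels
    elif name == "svm":
        sel = two_stage_svm_search(split, seed=seed, coarse_c=config.svm_c_grid,
                                   coarse_gamma=config.svm_gamma_grid,
                                   rprop=config.rprop, th=config.th)
        model = sel.best_model
        predict = lambda X: cls.predict_svm_rbf(model, X)
    else:
        raise ConfigurationError(f"unknown classifier '{name}'")
    return model, predict


def _evaluate(config: StudyConfig, model, predict, split) -> dict:
    n_par = cls.count_parameters(model)
    K = config.acquisition.n_classes
    out = {}
    for label, subset in (("TS", split.TS), ("GS", split.GS)):
        if len(subset.y) == 0:
            continue
        res = EvaluationResult.from_predictions(
            label, subset.y, predict(subset.X), n_par, config.eof, n_classes=K)
        out[label] = res.to_dict()
    return out


# ---------------------------------------------------------------------------
# study parts
# ---------------------------------------------------------------------------

def run_part1(config: StudyConfig) -> dict:
    """Complexity-range selection for NLR (degree) and MLP (layers, then
    neurons) at the part-1 downsampling step.

    With fewer than 6 subjects the Wilcoxon comparisons are infeasible; the
    level with the best mean F1 is selected instead (simplest on ties) and
    the fallback is recorded.
    """
    step = config.selection_step

    def sweep(train_settings: list[dict], name: str) -> np.ndarray:
        scores = np.zeros((config.n_subjects, len(train_settings)))
        for s in range(config.n_subjects):
            session = subject_session(config, s)
            split = subject_split(config, session, step, s)
            for j, settings in enumerate(train_settings):
                model, predict = _train(config, name, split, s, step, settings)
                res = EvaluationResult.from_predictions(
                    "TS", split.TS.y, predict(split.TS.X),
                    cls.count_parameters(model), config.eof,
                    n_classes=config.acquisition.n_classes)
                scores[s, j] = res.metrics.aggregate_f1
        return scores

    def select(scores: np.ndarray) -> tuple[int, list[dict] | None, bool]:
        if config.n_subjects >= 6:
            level, log = sequential_complexity_selection(scores, config.alpha)
            return level, log, False
        return int(np.argmax(np.round(scores.mean(axis=0), 12))), None, True

    d_scores = sweep([{"degree": d} for d in config.nlr_degrees], "nlr")
    d_idx, d_log, d_fb = select(d_scores)

    layer_settings = [{"n_layers": l, "n_neurons": config.mlp_neurons_for_layer_sweep}
                      for l in config.mlp_layer_grid]
    l_scores = sweep(layer_settings, "mlp")
    l_idx, l_log, l_fb = select(l_scores)
    n_layers = config.mlp_layer_grid[l_idx]

    neuron_settings = [{"n_layers": n_layers, "n_neurons": n}
                       for n in config.mlp_neuron_grid]
    n_scores = sweep(neuron_settings, "mlp")
    n_idx, n_log, n_fb = select(n_scores)

    return {
        "step": step,
        "nlr": {"grid": list(config.nlr_degrees), "scores": d_scores.tolist(),
                "selected_degree": int(config.nlr_degrees[d_idx]),
                "log": d_log, "mean_fallback": d_fb},
        "mlp_layers": {"grid": list(config.mlp_layer_grid),
                       "scores": l_scores.tolist(),
                       "selected_layers": int(n_layers),
                       "log": l_log, "mean_fallback": l_fb},
        "mlp_neurons": {"grid": list(config.mlp_neuron_grid),
                        "scores": n_scores.tolist(),
                        "selected_neurons": int(config.mlp_neuron_grid[n_idx]),
                        "log": n_log, "mean_fallback": n_fb},
    }


def run_part2(config: StudyConfig, part1: dict) -> dict:
    """Sweep NLR/MLP/SVM over the downsampling steps; evaluate TS and GS."""
    settings = {
        "nlr": {"degree": part1["nlr"]["selected_degree"]},
        "mlp": {"n_layers": part1["mlp_layers"]["selected_layers"],
                "n_neurons": part1["mlp_neurons"]["selected_neurons"]},
        "svm": {},
    }
    results: dict = {name: {int(step): [] for step in config.steps}
                     for name in CLASSIFIERS}
    for s in range(config.n_subjects):
        session = subject_session(config, s)
        for step in config.steps:
            split = subject_split(config, session, step, s)
            for name in CLASSIFIERS:
                model, predict = _train(config, name, split, s, step, settings[name])
                results[name][int(step)].append(_evaluate(config, model, predict, split))
    return {"settings": settings, "results": results}


def run_part3(config: StudyConfig, part2: dict) -> dict:
    """Best-EOF-on-GS models vs the LDA benchmark branch."""
    n = config.n_subjects
    picks: dict = {name: [] for name in CLASSIFIERS}
    table: dict = {name: {"f1": [], "n_parameters": [], "eof": []}
                   for name in (*CLASSIFIERS, "lda")}
    for name in CLASSIFIERS:
        for s in range(n):
            best = max(config.steps,
                       key=lambda st: part2["results"][name][int(st)][s]["GS"]["eof"])
            cell = part2["results"][name][int(best)][s]["GS"]
            picks[name].append(int(best))
            table[name]["f1"].append(cell["f1"])
            table[name]["n_parameters"].append(cell["n_parameters"])
            table[name]["eof"].append(cell["eof"])

    lda_results = []
    for s in range(n):
        session = subject_session(config, s)
        feats, labels = extract_td_features(session, config.feature_windows)
        tr, ts = stratified_split_70_30(
            feats, labels, derive_seed(config.seed, _STAGES["lda"], s))
        model = cls.train_lda(tr.X, tr.y)
        res = EvaluationResult.from_predictions(
            "TS30", ts.y, cls.predict_lda(model, ts.X),
            cls.count_parameters(model), config.eof,
            n_classes=config.acquisition.n_classes)
        lda_results.append(res.to_dict())
        table["lda"]["f1"].append(res.metrics.aggregate_f1)
        table["lda"]["n_parameters"].append(res.n_parameters)
        table["lda"]["eof"].append(res.eof)

    labels = list(table.keys())
    reports = {}
    if n >= 2:
        for metric in ("f1", "n_parameters", "eof"):
            scores = PairedScores(
                condition_labels=labels,
                scores=np.column_stack([table[c][metric] for c in labels]))
            reports[metric] = pairwise_compare(scores, config.alpha).to_dict()

    summary = [{
        "classifier": c,
        "f1_mean": float(np.mean(table[c]["f1"])),
        "f1_std": float(np.std(table[c]["f1"], ddof=1)) if n > 1 else 0.0,
        "n_parameters_mean": float(np.mean(table[c]["n_parameters"])),
        "n_parameters_std": (float(np.std(table[c]["n_parameters"], ddof=1))
                             if n > 1 else 0.0),
        "eof_mean": float(np.mean(table[c]["eof"])),
        "eof_std": float(np.std(table[c]["eof"], ddof=1)) if n > 1 else 0.0,
    } for c in labels]

    return {"best_step_on_gs": picks, "per_subject": table,
            "lda_results": lda_results, "comparisons": reports,
            "summary": summary}


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Run the full three-part study; optionally write the report files."""
    part1 = run_part1(config)
    part2 = run_part2(config, part1)
    part3 = run_part3(config, part2)
    result = StudyResult(config=config, part1=part1, part2=part2, part3=part3)
    if out_dir is not None:
        write_report(result, out_dir)
    return result


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def summary_markdown(summary: list[dict]) -> str:
    lines = ["| Classifier | F1Score | nθ | EOF |",
             "|---|---|---|---|"]
    for row in summary:
        lines.append(
            f"| {row['classifier'].upper()} "
            f"| {row['f1_mean']:.1f} ({row['f1_std']:.1f} s) "
            f"| {row['n_parameters_mean']:.0f} ({row['n_parameters_std']:.0f} s) "
            f"| {row['eof_mean']:.1f} ({row['eof_std']:.1f} s) |")
    return "\n".join(lines) + "\n"


def write_report(result: StudyResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for part in ("part1", "part2", "part3"):
        with open(out / f"{part}.json", "w") as fh:
            json.dump(getattr(result, part), fh, indent=1)
    pd.DataFrame(result.part3["summary"]).to_csv(out / "summary.csv", index=False)
    (out / "summary.md").write_text(summary_markdown(result.part3["summary"]))
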