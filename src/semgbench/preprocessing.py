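"""Scaling, the downsample/generalization-set protocol, and TD features.

The raw-signal branch of the study feeds scaled samples straight to the
classifiers: each channel has its mean subtracted and is divided by its
range.  Downsampling by a step ``s`` keeps every s-th sample as the working
pool, split 60/20/20 into training (TR), cross-validation (CV) and test
(TS); the discarded samples become the Generalization Set (GS), a second
test set standing in for full-rate operation.

The LDA benchmark branch instead extracts five time-domain features per
channel (MAV, RMS, SSC, WL, variance) on 250 ms windows with 200 ms overlap
and uses a stratified 70/30 split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateChannelError, StratificationError
from .synthetic import RecordingSession

TD_FEATURE_NAMES = ("MAV", "RMS", "SSC", "WL", "VAR")


@dataclass(frozen=True)
class ScalingParams:
    """Per-channel mean and range (max - min) used for min-max-style scaling."""

    mean: np.ndarray
    range: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, float))
        object.__setattr__(self, "range", np.asarray(self.range, float))
        if np.any(self.range <= 0):
            bad = int(np.argmax(self.range <= 0))
            raise DegenerateChannelError(f"channel {bad} has zero range; scaling undefined")


def scale_channels(signal: np.ndarray | RecordingSession,
                   params: ScalingParams | None = None) -> tuple[np.ndarray, ScalingParams]:
    """Scale each channel: (x - mean) / range.

    With ``params`` omitted the statistics are fitted on the given data;
    otherwise the provided parameters are applied unchanged (e.g. pool-fitted
    parameters applied to GS).
    """
    x = signal.signal if isinstance(signal, RecordingSession) else np.asarray(signal, float)
    if params is None:
        rng = x.max(axis=0) - x.min(axis=0)
        params = ScalingParams(mean=x.mean(axis=0), range=rng)
    return (x - params.mean) / params.range, params


@dataclass(frozen=True)
class SplitConfig:
    downsample_step: int = 10
    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)  # TR, CV, TS
    seed: int = 0
    balance_tolerance: int = 1

    def __post_init__(self):
        if self.downsample_step < 1:
            raise ConfigurationError("downsample_step must be >= 1")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigurationError("TR/CV/TS fractions must sum to 1")


@dataclass
class Subset:
    X: np.ndarray
    y: np.ndarray
    indices: np.ndarray  # source-row indices into the originating session


@dataclass
class DatasetSplit:
    """TR/CV/TS/GS partition of one session, with the scaling used."""

    TR: Subset
    CV: Subset
    TS: Subset
    GS: Subset
    scaling: ScalingParams
    provenance: dict = field(default_factory=dict)


def _proportional_allocation(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Split ``n`` into integer parts proportional to ``fractions``.

    Floors plus largest-remainder so parts sum exactly to n; deviation from
    exact proportionality is below 1 sample per part.
    """
    raw = [n * f for f in fractions]
    parts = [int(np.floor(r)) for r in raw]
    rem = n - sum(parts)
    order = np.argsort([p - r for p, r in zip(parts, raw)])  # most under-served first
    for i in range(rem):
        parts[order[i]] += 1
    return parts


def _stratified_partition(labels: np.ndarray, fractions: tuple[float, ...],
                          rng: np.random.Generator,
                          min_per_class: int = 1) -> list[np.ndarray]:
    """Seeded per-class shuffle + proportional allocation.

    Subset sizes match the fractions exactly (largest remainder on the
    totals) while every subset's per-class count stays within one sample of
    exact proportionality (the protocol's "proportionated class number"):
    per-class floors are topped up sample by sample into the subset with the
    largest remaining fractional claim that still has capacity.
    """
    classes = np.unique(labels)
    totals = _proportional_allocation(len(labels), fractions)
    per_class: dict = {}
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) < min_per_class:
            raise StratificationError(
                f"class {cls} has only {len(idx)} sample(s) in the pool")
        counts = [int(np.floor(len(idx) * f)) for f in fractions]
        per_class[int(cls)] = [rng.permutation(idx), counts]
    capacity = [t - sum(per_class[int(c)][1][k] for c in classes)
                for k, t in enumerate(totals)]
    for cls in rng.permutation(classes):
        idx, counts = per_class[int(cls)]
        for _ in range(len(idx) - sum(counts)):
            claims = [len(idx) * f - cnt for f, cnt in zip(fractions, counts)]
            k = max(range(len(fractions)),
                    key=lambda k: (capacity[k] > 0, claims[k], capacity[k], -k))
            counts[k] += 1
            capacity[k] -= 1
    buckets: list[list[np.ndarray]] = [[] for _ in fractions]
    for cls in classes:
        idx, counts = per_class[int(cls)]
        start = 0
        for b, p in zip(buckets, counts):
            b.append(idx[start:start + p])
            start += p
    return [np.sort(np.concatenate(b)) if b else np.array([], int) for b in buckets]


def downsample_split(session: RecordingSession, config: SplitConfig) -> DatasetSplit:
    """Downsample + 60/20/20 stratified split; discarded rows form GS.

    Rows at indices = 0 (mod step) form the downsampled pool. Scaling is
    fitted on the pool and applied unchanged to every subset including GS.
    """
    n = session.n_samples
    pool = np.arange(0, n, config.downsample_step)
    gs_mask = np.ones(n, bool)
    gs_mask[pool] = False
    gs_idx = np.flatnonzero(gs_mask)

    pool_labels = session.labels[pool]
    present = np.unique(pool_labels)
    if len(present) < session.n_classes:
        missing = sorted(set(range(session.n_classes)) - set(present.tolist()))
        raise StratificationError(f"class(es) {missing} absent from the downsampled pool")

    rng = np.random.default_rng(config.seed)
    tr_p, cv_p, ts_p = _stratified_partition(pool_labels, config.fractions, rng)
    tr_idx, cv_idx, ts_idx = pool[tr_p], pool[cv_p], pool[ts_p]

    _, scaling = scale_channels(session.signal[pool])

    def subset(idx: np.ndarray) -> Subset:
        x, _ = scale_channels(session.signal[idx], scaling) if len(idx) else (
            np.empty((0, session.n_channels)), scaling)
        return Subset(X=x, y=session.labels[idx], indices=idx)

    return DatasetSplit(
        TR=subset(tr_idx), CV=subset(cv_idx), TS=subset(ts_idx), GS=subset(gs_idx),
        scaling=scaling,
        provenance={"downsample_step": config.downsample_step, "seed": config.seed},
    )


def stratified_split_70_30(X: np.ndarray, labels: np.ndarray,
                           seed: int) -> tuple[Subset, Subset]:
    """Stratified 70/30 train/test split (the LDA-branch protocol)."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    try:
        tr_p, ts_p = _stratified_partition(labels, (0.70, 0.30), rng, min_per_class=2)
    except StratificationError:
        raise
    return (Subset(X=X[tr_p], y=labels[tr_p], indices=tr_p),
            Subset(X=X[ts_p], y=labels[ts_p], indices=ts_p))


# ---------------------------------------------------------------------------
# Time-domain feature extraction (LDA branch)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureWindowConfig:
    window_length_ms: float = 250.0
    overlap_ms: float = 200.0
    ssc_threshold: float = 0.010  # volts; dead-zone for slope-sign changes

    def __post_init__(self):
        if not 0 <= self.overlap_ms < self.window_length_ms:
            raise ConfigurationError("require 0 <= overlap < window_length")


def _window_features(w: np.ndarray, ssc_threshold: float) -> np.ndarray:
    """MAV, RMS, SSC, WL, VAR for one (samples,) window."""
    mav = np.mean(np.abs(w))
    rms = np.sqrt(np.mean(w * w))
    d = np.diff(w)
    # Hudgins-style SSC: interior samples where the slope changes sign and
    # both adjacent increments exceed the dead-zone threshold.
    ssc = float(np.sum((d[:-1] * d[1:] < 0)
                       & (np.abs(d[:-1]) > ssc_threshold)
                       & (np.abs(d[1:]) > ssc_threshold)))
    wl = np.sum(np.abs(d))
    var = np.var(w, ddof=1) if len(w) > 1 else 0.0
    return np.array([mav, rms, ssc, wl, var])


def td_feature_columns(n_channels: int) -> list[str]:
    """Header names in channel-major order: ch1_MAV ... ch1_VAR, ch2_MAV ..."""
    return [f"ch{c + 1}_{name}" for c in range(n_channels) for name in TD_FEATURE_NAMES]


def extract_td_features(session: RecordingSession,
                        config: FeatureWindowConfig = FeatureWindowConfig()
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Windowed TD features per channel; windows never straddle label boundaries.

    Windowing restarts at every contiguous (label, rep) segment; a segment
    shorter than one window is skipped with a warning.  Returns the feature
    matrix (windows x 5*n_channels, channel-major) and per-window labels.
    """
    fs = session.sampling_rate
    win = int(round(config.window_length_ms * fs / 1000.0))
    step = win - int(round(config.overlap_ms * fs / 1000.0))
    if win < 2 or step < 1:
        raise ConfigurationError("window too short for the sampling rate")

    # contiguous segments of constant (label, rep)
    key = session.labels.astype(np.int64) * (session.rep_index.max() + 2) + session.rep_index
    boundaries = np.flatnonzero(np.diff(key) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [session.n_samples]])

    rows, labels = [], []
    for s, e in zip(starts, ends):
        if e - s < win:
            warnings.warn(f"segment [{s}:{e}] shorter than one window; skipped",
                          stacklevel=2)
            continue
        for w0 in range(s, e - win + 1, step):
            seg = session.signal[w0:w0 + win]
            feats = [_window_features(seg[:, c], config.ssc_threshold)
                     for c in range(session.n_channels)]
            rows.append(np.concatenate(feats))
            labels.append(session.labels[s])
    if not rows:
        return np.empty((0, 5 * session.n_channels)), np.empty(0, np.int64)
    return np.vstack(rows), np.asarray(labels, np.int64)
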