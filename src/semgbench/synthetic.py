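"""Synthetic multi-channel surface-EMG session generator.

Emulates the acquisition protocol assumed throughout the study: six
envelope-type sEMG sensors (0-5 V), sampled at 1 kHz, five steady-state
gesture classes ("Rest", "Spherical", "Tip", "Platform", "Point"), ten
repetitions of 2 s per gesture.  Only the sampled steady-state windows are
generated; inter-stimulus gaps and returns to rest were never recorded in
the protocol and are not emulated.

The signal model per (gesture, repetition) block is

    x[t, c] = mean_activation[g, c] + drift[t] + noise[t, c]

where ``drift`` is a slow sinusoid with per-repetition random phase
(amplitude ``within_rep_jitter``) and ``noise`` is Gaussian white noise
shaped by a single-pole low-pass at ``noise_bandwidth`` and rescaled to
standard deviation ``noise_sd``.  Samples are finally clipped to the sensor
voltage range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SessionParseError

DEFAULT_GESTURES = ("Rest", "Spherical", "Tip", "Platform", "Point")

#: Frequency (Hz) of the slow within-repetition drift sinusoid. One cycle
#: every 2 s keeps the drift slow relative to a 250 ms analysis window.
DRIFT_FREQUENCY_HZ = 0.5


@dataclass(frozen=True)
class AcquisitionConfig:
    """Geometry and timing of one recording session."""

    n_channels: int = 6
    sampling_rate: float = 1000.0
    duration_per_rep: float = 2.0
    reps_per_gesture: int = 10
    gesture_names: tuple[str, ...] = DEFAULT_GESTURES
    voltage_range: tuple[float, float] = (0.0, 5.0)

    def __post_init__(self):
        if self.n_channels < 1 or self.reps_per_gesture < 1 or len(self.gesture_names) < 1:
            raise ConfigurationError("all counts must be >= 1")
        if self.sampling_rate <= 0 or self.duration_per_rep <= 0:
            raise ConfigurationError("sampling_rate and duration_per_rep must be > 0")
        lo, hi = self.voltage_range
        if not lo < hi:
            raise ConfigurationError("voltage_range lower bound must be below upper bound")

    @property
    def n_classes(self) -> int:
        return len(self.gesture_names)

    @property
    def samples_per_rep(self) -> int:
        return int(round(self.duration_per_rep * self.sampling_rate))

    @property
    def total_samples(self) -> int:
        return self.n_classes * self.reps_per_gesture * self.samples_per_rep


@dataclass(frozen=True)
class GestureProfile:
    """Statistical profile of the gesture-dependent channel activations.

    ``separability`` scales the between-class differences of the mean
    activation pattern about the grand mean, so larger values spread the
    class centroids apart without moving their centre of mass.
    """

    mean_activation: np.ndarray  # (n_classes, n_channels), volts
    within_rep_jitter: float = 0.10
    noise_sd: float = 0.25
    noise_bandwidth: float = 10.0
    separability: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "mean_activation", np.asarray(self.mean_activation, float))
        if self.mean_activation.ndim != 2:
            raise ConfigurationError("mean_activation must be a (classes x channels) matrix")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.separability < 0:
            raise ConfigurationError("separability must be >= 0")
        if self.noise_bandwidth <= 0:
            raise ConfigurationError("noise_bandwidth must be > 0")

    def effective_means(self) -> np.ndarray:
        """Class means after applying the separability scaling."""
        grand = self.mean_activation.mean(axis=0, keepdims=True)
        return grand + self.separability * (self.mean_activation - grand)


def default_profile(**overrides) -> GestureProfile:
    """The packaged default activation profile (reproducible fixture)."""
    with resources.files("semgbench.data").joinpath("default_profile.json").open() as fh:
        raw = json.load(fh)
    fields = dict(
        mean_activation=np.array(raw["mean_activation"], float),
        within_rep_jitter=raw["within_rep_jitter"],
        noise_sd=raw["noise_sd"],
        noise_bandwidth=raw["noise_bandwidth"],
        separability=raw["separability"],
    )
    fields.update(overrides)
    return GestureProfile(**fields)


@dataclass
class RecordingSession:
    """One labelled acquisition session: samples x channels, volts."""

    signal: np.ndarray          # (n_samples, n_channels)
    labels: np.ndarray          # (n_samples,) integer class index
    rep_index: np.ndarray       # (n_samples,) repetition id within class
    sampling_rate: float
    gesture_names: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.gesture_names)


def _shaped_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sd: float, bandwidth: float, fs: float) -> np.ndarray:
    """White Gaussian noise through a single-pole low-pass, renormalised to ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    a = np.exp(-2.0 * np.pi * bandwidth / fs)
    if a <= 0:  # bandwidth at/above Nyquist-ish: effectively unfiltered
        return sd * white
    from scipy.signal import lfilter

    shaped = lfilter([1.0 - a], [1.0, -a], white, axis=0)
    # Steady-state std of the filtered process, so noise_sd keeps its meaning.
    gain = (1.0 - a) / np.sqrt(1.0 - a * a)
    return sd * shaped / gain


def generate_session(config: AcquisitionConfig, profile: GestureProfile,
                     seed: int) -> RecordingSession:
    """Generate one seeded synthetic session.

    Blocks are laid out class-major, repetitions in order within each class;
    every (class, repetition) block has ``samples_per_rep`` rows.
    """
    means = profile.effective_means()
    if means.shape != (config.n_classes, config.n_channels):
        raise ConfigurationError(
            f"profile mean_activation shape {means.shape} does not match "
            f"config ({config.n_classes} classes x {config.n_channels} channels)"
        )
    rng = np.random.default_rng(seed)
    n_rep = config.samples_per_rep
    t = np.arange(n_rep) / config.sampling_rate
    lo, hi = config.voltage_range

    blocks, labels, reps = [], [], []
    for g in range(config.n_classes):
        for r in range(config.reps_per_gesture):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            drift = profile.within_rep_jitter * np.sin(
                2.0 * np.pi * DRIFT_FREQUENCY_HZ * t + phase
            )
            noise = _shaped_noise(
                rng, (n_rep, config.n_channels), profile.noise_sd,
                profile.noise_bandwidth, config.sampling_rate,
            )
            block = means[g][None, :] + drift[:, None] + noise
            blocks.append(np.clip(block, lo, hi))
            labels.append(np.full(n_rep, g, dtype=np.int64))
            reps.append(np.full(n_rep, r, dtype=np.int64))

    return RecordingSession(
        signal=np.concatenate(blocks, axis=0),
        labels=np.concatenate(labels),
        rep_index=np.concatenate(reps),
        sampling_rate=config.sampling_rate,
        gesture_names=tuple(config.gesture_names),
    )


# ---------------------------------------------------------------------------
# Session file I/O (CSV: ch1..chN float columns, label, rep)
# ---------------------------------------------------------------------------

def write_session(path: str | Path, session: RecordingSession) -> None:
    """Write a session as CSV: ch1..chN (6 decimal places), label, rep."""
    cols = {f"ch{c + 1}": session.signal[:, c] for c in range(session.n_channels)}
    cols["label"] = session.labels
    cols["rep"] = session.rep_index
    df = pd.DataFrame(cols)
    header = f"# sampling_rate={session.sampling_rate} gestures={','.join(session.gesture_names)}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.6f")


def read_session(path: str | Path) -> RecordingSession:
    """Read a session written by :func:`write_session`.

    Raises :class:`SessionParseError` naming the offending column or row on
    malformed input.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sampling_rate, gestures = 1000.0, DEFAULT_GESTURES
    skip = 0
    if first.startswith("#"):
        skip = 1
        for tok in first[1:].split():
            if tok.startswith("sampling_rate="):
                sampling_rate = float(tok.split("=", 1)[1])
            elif tok.startswith("gestures="):
                gestures = tuple(tok.split("=", 1)[1].split(","))
    df = pd.read_csv(path, skiprows=skip)
    if "label" not in df.columns:
        raise SessionParseError(f"{path.name}: missing required column 'label'")
    chan_cols = [c for c in df.columns if c.startswith("ch")]
    if not chan_cols:
        raise SessionParseError(f"{path.name}: no channel columns 'ch*' found")
    for col in chan_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise SessionParseError(f"{path.name}: non-numeric value in column '{col}' at row {row}")
        df[col] = vals
    rep = df["rep"].to_numpy(np.int64) if "rep" in df.columns else np.zeros(len(df), np.int64)
    return RecordingSession(
        signal=df[chan_cols].to_numpy(float),
        labels=df["label"].to_numpy(np.int64),
        rep_index=rep,
        sampling_rate=sampling_rate,
        gesture_names=gestures,
    )
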