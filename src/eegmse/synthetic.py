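"""DEAP-shaped synthetic EEG with class-dependent band irregularity.

Real affect-rated EEG is access-restricted, so this module generates
recordings with the same layout — subjects x trials x channels x
samples at 128 Hz, 3 s of pre-trial baseline followed by 60 s of trial
signal, ratings in [1, 9] per emotional dimension — and a *controllable*
class signal: within a targeted rhythm band, low-class trials contain a
narrowband sinusoid (plus 10% Gaussian noise) while high-class trials
contain band-passed white noise of matched variance.  Sample entropy
provably separates these two regimes, so the generator carries exactly
the kind of signal the entropy features are designed to detect, at a
strength set by ``contrast``.

Each emotional dimension is tied to its own band (default: arousal ->
beta, valence -> alpha, dominance -> gamma), so the three binary
classifications are independent by construction.  Baseline portions
and untargeted bands always use the class-independent low regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .bands import BANDS, FilterSpec, design_butterworth
from .montage import DEAP_CHANNELS, DEAP_GRID

__all__ = [
    "DIMENSIONS",
    "DEFAULT_CLASS_EFFECT",
    "RawRecording",
    "RatingTable",
    "generate_recording",
]

#: Emotional rating dimensions, in storage order.
DIMENSIONS: tuple[str, ...] = ("arousal", "valence", "dominance")

#: Which band carries each dimension's class contrast by default.
DEFAULT_CLASS_EFFECT: dict[str, str] = {
    "arousal": "beta",
    "valence": "alpha",
    "dominance": "gamma",
}

#: Per-band signal standard deviation (arbitrary microvolt-scale units).
#: Lower bands carry more power, as in resting EEG.
_BAND_STD: dict[str, float] = {
    "theta": 8.0,
    "alpha": 8.0,
    "beta": 6.0,
    "gamma": 4.0,
}


@dataclass
class RawRecording:
    """Multi-subject EEG block: (subjects, trials, channels, samples)."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    baseline_seconds: float = 3.0
    trial_seconds: float = 60.0

    def __post_init__(self) -> None:
        expected = round(self.fs * (self.baseline_seconds + self.trial_seconds))
        if self.data.ndim != 4:
            raise ValueError(
                f"data must be 4-D (subjects, trials, channels, samples); "
                f"got {self.data.shape}"
            )
        if self.data.shape[-1] != expected:
            raise ValueError(
                f"samples axis has {self.data.shape[-1]} entries; expected "
                f"fs x (baseline + trial) = {expected}"
            )
        if self.data.shape[2] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]


@dataclass
class RatingTable:
    """Self-assessment ratings, (subjects, trials, dimensions) in [1, 9]."""

    ratings: np.ndarray
    dimensions: tuple[str, ...] = DIMENSIONS

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.ratings.ndim != 3 or self.ratings.shape[2] != len(self.dimensions):
            raise ValueError(
                f"ratings must be (subjects, trials, {len(self.dimensions)})"
            )
        if np.any(self.ratings < 1) or np.any(self.ratings > 9):
            raise ValueError("ratings must lie in [1, 9]")

    def dimension(self, name: str) -> np.ndarray:
        """Ratings of one dimension, (subjects, trials)."""
        return self.ratings[..., self.dimensions.index(name)]


def _band_center(band: tuple[float, float]) -> float:
    return 0.5 * (band[0] + band[1])


def _low_regime(rng, n, freq, fs, std):
    """Sinusoid at the band center plus 10%-amplitude white noise."""
    amp = std * np.sqrt(2.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) / fs
    return amp * np.sin(2.0 * np.pi * freq * t + phase) + rng.normal(
        0.0, 0.1 * amp, size=n
    )


def _high_regime(rng, n, sos, std):
    """Band-passed white noise rescaled to the target std."""
    white = rng.standard_normal(n + 256)  # pad to wash out filter edges
    shaped = _sig.sosfiltfilt(sos, white)[128 : 128 + n]
    s = shaped.std()
    return shaped * (std / s) if s > 0 else shaped


def generate_recording(
    n_subjects: int = 32,
    n_trials: int = 40,
    channels: tuple[str, ...] | list[str] = DEAP_CHANNELS,
    fs: float = 128.0,
    seed: int = 0,
    class_effect: dict[str, str] | None = None,
    contrast: float = 1.0,
    baseline_seconds: float = 3.0,
    trial_seconds: float = 60.0,
    bands: dict[str, tuple[float, float]] | None = None,
) -> tuple[RawRecording, RatingTable]:
    """Generate a synthetic affect-rated EEG block.

    Parameters
    ----------
    n_subjects, n_trials, channels, fs
        Layout; defaults mirror the DEAP preprocessed data (32 x 40 x
        32 channels at 128 Hz, 8064 samples per trial).
    seed
        Seeds all randomness; identical seeds give bit-identical output.
    class_effect
        ``{dimension: band}`` mapping; defaults to
        :data:`DEFAULT_CLASS_EFFECT`.  For each listed dimension a class
        is drawn per (subject, trial) and the trial portion of the
        mapped band follows the class regime; the emitted rating is
        uniform on {1..5} for low, {6..9} for high, so threshold-5
        labeling recovers the generative class exactly.
    contrast
        Strength of the class signal in [0, 1].  1 gives the full
        sinusoid-vs-noise contrast; 0 makes high-class trials follow
        the low regime (labels carry no signal).

    Returns
    -------
    (RawRecording, RatingTable)
    """
    if fs < 90.0:
        raise ValueError(
            f"fs = {fs} Hz violates the Nyquist requirement for the gamma "
            "band (45 Hz needs fs >= 90 Hz)"
        )
    if not 0.0 <= contrast <= 1.0:
        raise ValueError(f"contrast must lie in [0, 1], got {contrast}")
    channels = tuple(channels)
    for ch in channels:
        if ch not in DEAP_GRID:
            raise ValueError(
                f"unknown channel label {ch!r}; known labels: "
                f"{sorted(DEAP_GRID)}"
            )
    if class_effect is None:
        class_effect = DEFAULT_CLASS_EFFECT
    band_defs = bands if bands is not None else BANDS
    for dim, band in class_effect.items():
        if dim not in DIMENSIONS:
            raise ValueError(f"unknown emotional dimension {dim!r}")
        if band not in band_defs:
            raise ValueError(f"unknown band {band!r} in class_effect")

    rng = np.random.default_rng(seed)
    n_base = round(fs * baseline_seconds)
    n_trial = round(fs * trial_seconds)
    n_samples = n_base + n_trial
    band_to_dim = {b: d for d, b in class_effect.items()}

    sos = {
        name: design_butterworth(FilterSpec(order=5, band=edges, fs=fs))
        for name, edges in band_defs.items()
    }
    centers = {name: _band_center(edges) for name, edges in band_defs.items()}

    data = np.zeros((n_subjects, n_trials, len(channels), n_samples),
                    dtype=np.float32)
    ratings = np.zeros((n_subjects, n_trials, len(DIMENSIONS)))

    for s in range(n_subjects):
        for tr in range(n_trials):
            is_high = {}
            for d_idx, dim in enumerate(DIMENSIONS):
                hi = bool(rng.integers(0, 2))
                is_high[dim] = hi
                ratings[s, tr, d_idx] = (
                    rng.integers(6, 10) if hi else rng.integers(1, 6)
                )
            for ch in range(len(channels)):
                x = np.zeros(n_samples)
                for bname in band_defs:
                    std = _BAND_STD.get(bname, 5.0)
                    # baseline: class-independent low regime
                    x[:n_base] += _low_regime(
                        rng, n_base, centers[bname], fs, std
                    )
                    dim = band_to_dim.get(bname)
                    high = dim is not None and is_high[dim]
                    low_part = _low_regime(rng, n_trial, centers[bname], fs, std)
                    if high and contrast > 0.0:
                        noise_part = _high_regime(rng, n_trial, sos[bname], std)
                        x[n_base:] += (
                            np.sqrt(1.0 - contrast) * low_part
                            + np.sqrt(contrast) * noise_part
                        )
                    else:
                        x[n_base:] += low_part
                data[s, tr, ch] = x

    rec = RawRecording(
        data=data,
        fs=fs,
        channel_names=channels,
        baseline_seconds=baseline_seconds,
        trial_seconds=trial_seconds,
    )
    return rec, RatingTable(ratings=ratings)
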