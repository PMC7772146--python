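"""Segmentation, baseline correction and spatial feature tensors.

A 63-s trial is tiled into 63 non-overlapping 1-s windows: the first 3
are pre-trial baseline, the remaining 60 are trial segments that all
inherit the trial's labels.  Per segment, band and channel an MSE value
is computed; the mean MSE vector of the 3 baseline segments is
subtracted from every trial segment (baseline correction); the
corrected per-channel values are then scattered into a 10 x 10 grid per
band (montage embedding with a zero border ring) and the four band
planes are stacked into a 10 x 10 x 4 tensor — the CNN input.

Self-assessment ratings in [1, 9] are binarized at 5 per emotional
dimension: a rating <= 5 is "low", > 5 is "high".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bands import BANDS, BAND_ORDER, decompose
from .entropy import mse
from .montage import MontageGrid

__all__ = [
    "SegmentationPlan",
    "segment",
    "remove_baseline",
    "build_tensor",
    "binarize_labels",
    "EntropyTensorizer",
    "LOW",
    "HIGH",
]

logger = logging.getLogger(__name__)

#: Integer class codes for binarized ratings.
LOW, HIGH = 0, 1


@dataclass(frozen=True)
class SegmentationPlan:
    """Non-overlapping 1-s tiling of a recording."""

    window_seconds: float = 1.0
    n_baseline_segments: int = 3
    n_trial_segments: int = 60

    @property
    def total_seconds(self) -> float:
        return self.window_seconds * (
            self.n_baseline_segments + self.n_trial_segments
        )


def segment(
    trial_data: np.ndarray,
    fs: float,
    plan: SegmentationPlan | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tile a trial into baseline and trial windows.

    Parameters
    ----------
    trial_data
        Array with time on the last axis; its length must equal
        ``fs * plan.total_seconds`` exactly.
    fs
        Sampling rate (Hz).

    Returns
    -------
    (baseline, trial)
        Arrays of shape ``(..., n_baseline_segments, win)`` and
        ``(..., n_trial_segments, win)`` where ``win = fs *
        window_seconds`` samples.
    """
    if plan is None:
        plan = SegmentationPlan()
    trial_data = np.asarray(trial_data)
    win = fs * plan.window_seconds
    if win != int(win) or win < 1:
        raise ValueError(
            f"window of {plan.window_seconds} s at fs={fs} Hz is not an "
            "integer number of samples"
        )
    win = int(win)
    n_seg = plan.n_baseline_segments + plan.n_trial_segments
    expected = n_seg * win
    if trial_data.shape[-1] != expected:
        raise ValueError(
            f"trial has {trial_data.shape[-1]} samples; expected "
            f"{expected} (= {n_seg} windows x {win} samples) — the data "
            "does not tile into 1-s windows"
        )
    tiled = trial_data.reshape(trial_data.shape[:-1] + (n_seg, win))
    nb = plan.n_baseline_segments
    return tiled[..., :nb, :], tiled[..., nb:, :]


def remove_baseline(
    trial_mse: np.ndarray, baseline_mse: np.ndarray
) -> np.ndarray:
    """Subtract the mean baseline MSE vector from every trial segment.

    ``corrected(i) = trial(i) - mean_over_baseline_segments(baseline)``,
    elementwise over whatever trailing feature axes (channels, bands)
    the vectors carry.
    """
    trial_mse = np.asarray(trial_mse, dtype=float)
    baseline_mse = np.asarray(baseline_mse, dtype=float)
    if trial_mse.shape[1:] != baseline_mse.shape[1:]:
        raise ValueError(
            f"trial segments have feature shape {trial_mse.shape[1:]} but "
            f"baseline segments have {baseline_mse.shape[1:]}"
        )
    return trial_mse - baseline_mse.mean(axis=0)


def build_tensor(
    values: np.ndarray,
    channel_names: list[str] | tuple[str, ...],
    grid: MontageGrid | None = None,
    n_bands: int | None = None,
) -> np.ndarray:
    """Scatter per-(channel, band) values into a bordered spatial tensor.

    Parameters
    ----------
    values
        Array of shape ``(n_channels, n_bands)``.
    channel_names
        Channel label per row of ``values``; every label must have a
        grid coordinate.
    grid
        Montage embedding; defaults to the DEAP 32-channel grid.

    Returns
    -------
    ndarray
        ``(rows, cols, n_bands)`` tensor (10 x 10 x 4 by default);
        cells not mapped to a channel are exactly zero.
    """
    if grid is None:
        grid = MontageGrid()
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != len(channel_names):
        raise ValueError(
            f"values must be (n_channels, n_bands); got {values.shape} for "
            f"{len(channel_names)} channels"
        )
    if n_bands is not None and values.shape[1] != n_bands:
        raise ValueError(
            f"expected {n_bands} bands, got {values.shape[1]}"
        )
    rows, cols = grid.grid_shape
    out = np.zeros((rows, cols, values.shape[1]), dtype=float)
    for ch_idx, name in enumerate(channel_names):
        r, c = grid.cell(name)  # raises KeyError naming the channel
        out[r, c, :] = values[ch_idx]
    return out


def binarize_labels(ratings: np.ndarray, threshold: float = 5.0) -> np.ndarray:
    """Binarize self-assessment ratings at the threshold.

    A rating less than or equal to ``threshold`` maps to :data:`LOW`
    (0), a rating above it to :data:`HIGH` (1).  Applied elementwise,
    so per-dimension rating arrays are handled independently.
    """
    ratings = np.asarray(ratings, dtype=float)
    if np.any(ratings < 1.0) or np.any(ratings > 9.0):
        bad = ratings[(ratings < 1.0) | (ratings > 9.0)].ravel()[0]
        raise ValueError(f"rating {bad} outside the valid range [1, 9]")
    return np.where(ratings > threshold, HIGH, LOW)


class EntropyTensorizer:
    """Raw trials -> per-segment baseline-corrected MSE tensors.

    A stateless transformer composing the full feature-extraction
    front end: band decomposition, 1-s segmentation, per-segment MSE,
    baseline correction, and montage embedding.

    ``transform`` maps an array of trials ``(n_trials, n_channels,
    n_samples)`` to tensors ``(n_trials, n_trial_segments, rows, cols,
    n_bands)``.  Degenerate MSE segments (``nan``) are imputed with 0
    after baseline correction, with a logged warning.
    """

    def __init__(
        self,
        fs: float = 128.0,
        channel_names: tuple[str, ...] | list[str] | None = None,
        bands: dict[str, tuple[float, float]] | None = None,
        filter_order: int = 5,
        zero_phase: bool = True,
        m: int = 2,
        r_factor: float = 0.2,
        tau: int = 2,
        coarse_grain_mode: str = "moving_average",
        grid: MontageGrid | None = None,
        plan: SegmentationPlan | None = None,
    ):
        self.fs = fs
        self.channel_names = channel_names
        self.bands = bands
        self.filter_order = filter_order
        self.zero_phase = zero_phase
        self.m = m
        self.r_factor = r_factor
        self.tau = tau
        self.coarse_grain_mode = coarse_grain_mode
        self.grid = grid
        self.plan = plan

    def fit(self, X=None, y=None):
        return self

    def _band_items(self):
        bands = self.bands if self.bands is not None else BANDS
        order = [k for k in BAND_ORDER if k in bands]
        order += [k for k in bands if k not in order]
        return [(k, bands[k]) for k in order]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(
                f"expected (n_trials, n_channels, n_samples), got {X.shape}"
            )
        names = self.channel_names
        if names is None:
            from .montage import DEAP_CHANNELS

            names = DEAP_CHANNELS
        if X.shape[1] != len(names):
            raise ValueError(
                f"{X.shape[1]} channels in data but {len(names)} channel names"
            )
        grid = self.grid if self.grid is not None else MontageGrid()
        plan = self.plan if self.plan is not None else SegmentationPlan()
        band_items = self._band_items()
        band_dict = dict(band_items)
        n_trials, n_ch = X.shape[:2]
        nb, nt = plan.n_baseline_segments, plan.n_trial_segments
        n_bands = len(band_items)
        rows, cols = grid.grid_shape

        out = np.empty((n_trials, nt, rows, cols, n_bands), dtype=float)
        n_degenerate = 0
        for tr in range(n_trials):
            per_band = decompose(
                X[tr], self.fs, bands=band_dict,
                order=self.filter_order, zero_phase=self.zero_phase,
            )
            # (segments, channels, bands) MSE values
            base_vals = np.empty((nb, n_ch, n_bands))
            trial_vals = np.empty((nt, n_ch, n_bands))
            for b_idx, (b_name, _) in enumerate(band_items):
                base_seg, trial_seg = segment(per_band[b_name], self.fs, plan)
                for ch in range(n_ch):
                    for s in range(nb):
                        base_vals[s, ch, b_idx] = mse(
                            base_seg[ch, s], m=self.m,
                            r_factor=self.r_factor, tau=self.tau,
                            coarse_grain_mode=self.coarse_grain_mode,
                        )
                    for s in range(nt):
                        trial_vals[s, ch, b_idx] = mse(
                            trial_seg[ch, s], m=self.m,
                            r_factor=self.r_factor, tau=self.tau,
                            coarse_grain_mode=self.coarse_grain_mode,
                        )
            corrected = remove_baseline(trial_vals, base_vals)
            bad = ~np.isfinite(corrected)
            if bad.any():
                n_degenerate += int(bad.sum())
                corrected = np.where(bad, 0.0, corrected)
            for s in range(nt):
                out[tr, s] = build_tensor(corrected[s], list(names), grid)
        if n_degenerate:
            logger.warning(
                "%d degenerate MSE values imputed with 0", n_degenerate
            )
        return out

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "fs", "channel_names", "bands", "filter_order", "zero_phase",
                "m", "r_factor", "tau", "coarse_grain_mode", "grid", "plan",
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
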