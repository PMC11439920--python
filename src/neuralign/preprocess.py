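"""Deterministic sensor-space preprocessing.

The stages applied before multiset CCA: zero-phase band-pass filtering,
resampling to a common rate, zero-padding of rejected segments (so all
subjects keep equal length), and per-subject PCA dimensionality reduction.
All operations here are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "PcaReduction",
    "bandpass",
    "resample_to",
    "zero_pad",
    "fit_pca",
    "apply_pca",
]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification for a zero-phase forward-backward FIR filter.

    Parameters
    ----------
    low, high : float
        Pass-band edges in Hz. Must satisfy ``0 < low < high < fs / 2``.
    transition : float
        Transition-band width in Hz (default 0.5, the width used for the
        0.5-10 Hz analysis band).
    """

    low: float = 0.5
    high: float = 10.0
    transition: float = 0.5

    def validate(self, fs: float) -> None:
        if not (0.0 < self.low < self.high < fs / 2.0):
            raise ValueError(
                f"band ({self.low}, {self.high}) Hz invalid for fs={fs} Hz: "
                "need 0 < low < high < fs/2"
            )
        if self.transition <= 0:
            raise ValueError("transition width must be positive")


def _bandpass_taps(fs: float, spec: FilterSpec) -> np.ndarray:
    # Hamming-window FIR: ~3.3 / (transition / fs) taps gives the designed
    # transition width; filtfilt squares the magnitude response, so the
    # single-pass 53 dB stop-band becomes >100 dB.
    numtaps = int(np.ceil(3.3 * fs / spec.transition))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(
        numtaps, [spec.low, spec.high], pass_zero=False, window="hamming", fs=fs
    )


def bandpass(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase forward-backward band-pass filter along the last axis.

    Accepts 1-D (time,) or 2-D (channels, time) input. Pass-band gain is ~1
    and, because the filter is applied forward and backward, there is no
    phase shift.
    """
    spec = spec or FilterSpec()
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    taps = _bandpass_taps(fs, spec)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("input too short to filter")
    padlen = min(3 * len(taps), n - 1)
    return signal.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)


def resample_to(x: np.ndarray, fs_in: float, fs_out: float = 400.0) -> np.ndarray:
    """Polyphase resampling along the last axis (down-sampling only).

    Output length is ``round(n * fs_out / fs_in)``. Upsampling is refused:
    the pipeline only ever reduces the acquisition rate (e.g. 1,017 Hz
    recordings brought to the common 400 Hz analysis rate).
    """
    if fs_out > fs_in:
        raise ValueError(f"upsampling {fs_in} -> {fs_out} Hz is not supported")
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    n_out = int(round(n * fs_out / fs_in))
    if fs_out == fs_in:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10**6)
    y = signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    return y[..., :n_out]


def _normalize_intervals(
    intervals: Sequence[tuple[int, int]], n: int
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for start, end in sorted((int(s), int(e)) for s, e in intervals):
        if not (0 <= start < end <= n):
            raise ValueError(f"interval [{start}, {end}) outside [0, {n})")
        if out and start < out[-1][1]:
            raise ValueError(f"interval [{start}, {end}) overlaps a previous one")
        out.append((start, end))
    return out


def zero_pad(x: np.ndarray, intervals: Sequence[tuple[int, int]]) -> np.ndarray:
    """Zero out the masked sample ranges, keeping the length unchanged.

    ``intervals`` are half-open ``[start, end)`` sample ranges. Unmasked
    samples are copied bit-identically.
    """
    x = np.asarray(x)
    n = x.shape[-1]
    y = x.copy()
    for start, end in _normalize_intervals(intervals, n):
        y[..., start:end] = 0
    return y


@dataclass
class PcaReduction:
    """Fitted per-subject PCA: channel mean, orthonormal components, and
    explained-variance ratios, retaining ``d`` dimensions."""

    mean: np.ndarray                      # (channels,)
    components: np.ndarray                # (d, channels), orthonormal rows
    explained_variance_ratio: np.ndarray  # (d,), non-increasing
    explained_variance: np.ndarray        # (d,) eigenvalues

    @property
    def d(self) -> int:
        return self.components.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.components @ (x - self.mean[:, None])


def fit_pca(x: np.ndarray, d: int = 50) -> PcaReduction:
    """Fit channel-space PCA on a (channels, time) matrix.

    Channels are mean-centered; ``d`` is truncated to the numerical rank of
    the data (with a logged warning) if it exceeds it.
    """
    x = np.asarray(x, dtype=float)
    n_ch, n_t = x.shape
    if d < 1 or d > min(n_ch, n_t):
        raise ValueError(f"d={d} must be in [1, min(channels, time)={min(n_ch, n_t)}]")
    p = PCA(n_components=min(d, n_ch, n_t), svd_solver="full").fit(x.T)
    ev = p.explained_variance_
    rank = int(np.sum(ev > ev[0] * 1e-12)) if ev[0] > 0 else 1
    if rank < d:
        logger.warning("requested d=%d exceeds data rank %d; truncating", d, rank)
        d = rank
    return PcaReduction(
        mean=p.mean_.copy(),
        components=p.components_[:d].copy(),
        explained_variance_ratio=p.explained_variance_ratio_[:d].copy(),
        explained_variance=ev[:d].copy(),
    )


def apply_pca(reduction: PcaReduction, x: np.ndarray) -> np.ndarray:
    """Project a (channels, time) matrix onto the fitted principal axes."""
    if x.shape[0] != reduction.mean.shape[0]:
        raise ValueError(
            f"matrix has {x.shape[0]} channels, PCA was fit on {reduction.mean.shape[0]}"
        )
    return reduction.transform(x)
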