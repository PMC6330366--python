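"""Amplitude envelope estimation and the voiced/silent gate.

The envelope is the magnitude of the analytic signal (Hilbert transform),
smoothed by a short centered moving average. A threshold on the per-bin
envelope level separates song from silence/background: bins below it carry no
f0 estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

from .audio_io import AudioSignal
from .errors import ConfigurationError, ConsistencyError, InsufficientDataError
from .spectral import SpectrogramGrid


@dataclass(frozen=True)
class EnvelopeTrace:
    """Smoothed amplitude envelope, one value per signal sample."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ConsistencyError("envelope times and values differ in length")


@dataclass(frozen=True)
class Threshold:
    """Silence-gate threshold: relative fraction of the peak envelope, or absolute.

    Relative mode (default r = 0.05 of the recording's peak) is robust across
    recording gains; absolute mode suits calibrated pipelines.
    """

    mode: str
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("relative", "absolute"):
            raise ConfigurationError(f"threshold mode must be relative/absolute, got {self.mode!r}")
        if self.mode == "relative" and not 0.0 <= self.value <= 1.0:
            raise ConfigurationError(f"relative threshold must be in [0, 1], got {self.value}")
        if self.value < 0:
            raise ConfigurationError(f"threshold must be >= 0, got {self.value}")

    @classmethod
    def relative(cls, r: float) -> "Threshold":
        return cls("relative", r)

    @classmethod
    def absolute(cls, a: float) -> "Threshold":
        return cls("absolute", a)


def compute_envelope(signal: AudioSignal, smooth_ms: float = 5.0) -> EnvelopeTrace:
    """Analytic-signal magnitude smoothed by a centered moving average.

    ``smooth_ms`` is the averaging width in milliseconds (rounded to samples,
    minimum 1, i.e. ``smooth_ms=0`` disables smoothing); edges are handled by
    nearest-value extension.
    """
    x = signal.samples
    if x.ndim != 1:
        raise ConfigurationError("envelope requires a mono signal")
    if x.size == 0:
        raise InsufficientDataError("empty signal")
    if smooth_ms < 0:
        raise ConfigurationError(f"smooth_ms must be >= 0, got {smooth_ms}")
    magnitude = np.abs(hilbert(x))
    width = max(1, int(round(smooth_ms * signal.sample_rate / 1000.0)))
    values = uniform_filter1d(magnitude, size=width, mode="nearest") if width > 1 else magnitude
    times = np.arange(len(x)) / signal.sample_rate
    return EnvelopeTrace(times=times, values=values)


def envelope_at_bins(env: EnvelopeTrace, grid: SpectrogramGrid) -> np.ndarray:
    """Reduce the envelope to one level per spectrogram time bin.

    Bin k takes the *maximum* envelope value over its window extent
    ``[k*hop, k*hop + window)`` — a bin containing any part of a syllable
    onset counts as sound.
    """
    needed = (grid.n_times - 1) * grid.hop + grid.window
    if needed > len(env.values):
        raise ConsistencyError(
            f"grid needs {needed} envelope samples but trace has {len(env.values)}"
        )
    windows = sliding_window_view(env.values[:needed], grid.window)[:: grid.hop]
    return windows.max(axis=1)


def voiced_mask(bin_levels: np.ndarray, threshold: Threshold) -> np.ndarray:
    """Gate time bins: ``mask[k] = bin_levels[k] >= T``.

    T is ``r * max(bin_levels)`` in relative mode or the absolute value ``a``.
    Threshold-attaining bins count as voiced (deterministic tie behavior); an
    all-zero input under relative mode with r > 0 yields an all-silent mask.
    """
    levels = np.asarray(bin_levels, dtype=np.float64)
    if levels.size and levels.min() < 0:
        raise ConfigurationError("bin levels must be non-negative")
    if threshold.mode == "relative":
        peak = levels.max() if levels.size else 0.0
        cut = threshold.value * peak
        if peak == 0.0 and threshold.value > 0:
            return np.zeros(levels.shape, dtype=bool)
    else:
        cut = threshold.value
    return levels >= cut
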