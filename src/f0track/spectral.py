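"""Short-time spectrogram (the sonogram) and frequency-band restriction.

The signal is decomposed into consecutive windowed segments advancing by
``hop = window - overlap``; each segment's spectrum is the squared magnitude
of its discrete Fourier transform over the non-negative frequencies. No
zero-padding, detrending or inter-segment averaging is applied: unlike
Welch-style power estimation, each column stays statistically independent so
that per-column peak picking reflects the instantaneous spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .errors import ConfigurationError, InsufficientDataError
from .audio_io import AudioSignal

if TYPE_CHECKING:  # pragma: no cover
    from .tracker import TrackerConfig


@dataclass(frozen=True)
class SpectrogramGrid:
    """Time-frequency intensity matrix.

    ``power`` is indexed ``(frequency, time)`` and holds linear power (squared
    DFT magnitude) — per-bin argmax is invariant under any monotone rescaling,
    so dB conversion is deferred to plotting. ``times`` are window centers,
    ``t_k = (k*hop + window/2) / sample_rate``.
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    window: int
    hop: int
    window_function: str
    sample_rate: float

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freqs), len(self.times)):
            raise ConfigurationError(
                f"power shape {self.power.shape} does not match "
                f"({len(self.freqs)} freqs, {len(self.times)} times)"
            )

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_freqs(self) -> int:
        return len(self.freqs)

    @property
    def freq_resolution(self) -> float:
        """Frequency-bin width in Hz: sample_rate / window."""
        return self.sample_rate / self.window


def compute_spectrogram(signal: AudioSignal, config: "TrackerConfig") -> SpectrogramGrid:
    """Compute the spectrogram of a mono signal.

    Segments start at sample 0 and advance by ``hop``; trailing samples that
    do not fill a window are discarded, so the column count is
    ``floor((n_samples - window) / hop) + 1``. Each segment is tapered by the
    configured window function and transformed with a length-``window`` DFT
    (no zero-padding).
    """
    x = signal.samples
    if x.ndim != 1:
        raise ConfigurationError("spectrogram requires a mono signal (use to_mono first)")
    window, overlap = config.window, config.overlap
    if overlap >= window:
        raise ConfigurationError(f"overlap ({overlap}) must be < window ({window})")
    if len(x) < window:
        raise InsufficientDataError(
            f"signal has {len(x)} samples, shorter than one window ({window})"
        )
    hop = window - overlap
    taper = get_window(config.window_function, window, fftbins=True)
    segments = sliding_window_view(x, window)[::hop]  # (n_times, window)
    spectrum = np.fft.rfft(segments * taper, axis=1)
    power = (spectrum.real**2 + spectrum.imag**2).T  # (n_freqs, n_times)
    freqs = np.fft.rfftfreq(window, 1.0 / signal.sample_rate)
    times = (np.arange(segments.shape[0]) * hop + window / 2.0) / signal.sample_rate
    return SpectrogramGrid(
        times=times,
        freqs=freqs,
        power=power,
        window=window,
        hop=hop,
        window_function=config.window_function,
        sample_rate=signal.sample_rate,
    )


def restrict_band(grid: SpectrogramGrid, f_min: float, f_max: float) -> SpectrogramGrid:
    """Keep only frequency rows with ``f_min <= f <= f_max`` (time axis unchanged)."""
    if not 0 <= f_min < f_max:
        raise ConfigurationError(f"need 0 <= f_min < f_max, got [{f_min}, {f_max}]")
    keep = (grid.freqs >= f_min) & (grid.freqs <= f_max)
    if not keep.any():
        raise ConfigurationError(
            f"band [{f_min}, {f_max}] Hz contains no frequency bins "
            f"(grid spans 0..{grid.freqs[-1]:g} Hz, step {grid.freq_resolution:g})"
        )
    return replace(grid, freqs=grid.freqs[keep], power=grid.power[keep, :])


def time_resolution_bound(max_syllabic_rate: float) -> float:
    """Upper bound (seconds) a window duration must stay strictly below to
    resolve syllables produced at ``max_syllabic_rate`` Hz: ``1 / rate``.

    Canaries sing at 3-30 Hz syllabic rate, so the default 30 Hz gives 33 ms.
    """
    if max_syllabic_rate <= 0:
        raise ConfigurationError(f"syllabic rate must be > 0, got {max_syllabic_rate}")
    return 1.0 / max_syllabic_rate
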