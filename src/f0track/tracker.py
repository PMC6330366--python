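"""The core tracker: per-time-bin maximum-intensity frequency extraction.

For a tonal sound the spectral peak of each short-time spectrum *is* the
fundamental, so the f0 trajectory is the per-column argmax of the
band-restricted spectrogram:

    f0(t_k) = argmax_{f in [f_min, f_max]} S(f, t_k)

gated by an amplitude-envelope threshold that marks silent bins. Accuracy is
+-1 frequency bin (sample_rate / window); no peak interpolation is applied —
the estimator is the raw bin frequency. When a harmonic carries more power
inside the band than the fundamental, the tracker reports the harmonic: the
band filter is the only mitigation offered for that regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioSignal, ChannelPolicy, to_mono
from .envelope import Threshold, compute_envelope, envelope_at_bins, voiced_mask
from .errors import ConfigurationError, ConsistencyError, InsufficientDataError, TrackerWarning
from .spectral import SpectrogramGrid, compute_spectrogram, restrict_band, time_resolution_bound


@dataclass(frozen=True)
class TrackerConfig:
    """All tunable parameters of the tracker.

    Parameters
    ----------
    window, overlap : int
        Analysis window length and inter-segment overlap, in samples
        (hop = window - overlap). Defaults 1024/512: 23.2 ms at 44.1 kHz,
        inside the < 33 ms bound set by the fastest canary syllabic rate.
    window_function : str
        Taper name understood by :func:`scipy.signal.get_window` (default
        Hann, a standard low-leakage choice).
    f_min, f_max : float
        Search band in Hz; default 800-8000, the canary singing range.
        f_max above Nyquist is clipped (with a warning), not an error.
    threshold : Threshold
        Silence gate; default relative 5% of the peak envelope.
    smooth_ms : float
        Envelope moving-average width, milliseconds.
    channel_policy : str | int
        How stereo input is collapsed; see :func:`f0track.audio_io.to_mono`.
    max_syllabic_rate : float
        Fastest syllable rate (Hz) the analysis must resolve; used only to
        validate the window duration (warning, never an error).
    """

    window: int = 1024
    overlap: int = 512
    window_function: str = "hann"
    f_min: float = 800.0
    f_max: float = 8000.0
    threshold: Threshold = field(default=Threshold("relative", 0.05))
    smooth_ms: float = 5.0
    channel_policy: ChannelPolicy = "average"
    max_syllabic_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ConfigurationError(f"window must be >= 1 sample, got {self.window}")
        if not 0 <= self.overlap < self.window:
            raise ConfigurationError(
                f"need 0 <= overlap < window, got overlap={self.overlap}, window={self.window}"
            )
        if not 0 <= self.f_min < self.f_max:
            raise ConfigurationError(
                f"need 0 <= f_min < f_max, got [{self.f_min}, {self.f_max}]"
            )
        if self.smooth_ms < 0:
            raise ConfigurationError(f"smooth_ms must be >= 0, got {self.smooth_ms}")
        if self.max_syllabic_rate <= 0:
            raise ConfigurationError(
                f"max_syllabic_rate must be > 0, got {self.max_syllabic_rate}"
            )

    @property
    def hop(self) -> int:
        return self.window - self.overlap


@dataclass(frozen=True)
class F0Track:
    """Per-time-bin fundamental-frequency estimates.

    ``f0_hz`` is NaN exactly where ``voiced`` is False — silent bins carry NaN
    rather than 0 Hz because 0 Hz is a legal spectrogram frequency and would
    corrupt downstream statistics. ``peak_power`` keeps the intensity of the
    selected frequency in every bin as a diagnostic.
    """

    times: np.ndarray
    f0_hz: np.ndarray
    voiced: np.ndarray
    peak_power: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.f0_hz) == len(self.voiced) == len(self.peak_power) == n):
            raise ConsistencyError("track fields differ in length")
        if not np.array_equal(np.isnan(self.f0_hz), ~np.asarray(self.voiced, dtype=bool)):
            raise ConsistencyError("f0_hz must be NaN exactly where voiced is False")

    @property
    def n_bins(self) -> int:
        return len(self.times)

    @property
    def voiced_count(self) -> int:
        return int(np.count_nonzero(self.voiced))


def peak_frequency_per_bin(grid: SpectrogramGrid) -> tuple[np.ndarray, np.ndarray]:
    """For each time column, the frequency of maximum intensity and that intensity.

    Ties are broken toward the lowest frequency, which biases toward the
    fundamental; an all-zero column therefore yields the grid's lowest
    frequency (such bins are subsequently gated off as silent).
    """
    if grid.power.size == 0:
        raise InsufficientDataError("empty spectrogram grid")
    idx = np.argmax(grid.power, axis=0)  # first maximum = lowest frequency
    cols = np.arange(grid.n_times)
    return grid.freqs[idx], grid.power[idx, cols]


def validate_config(config: TrackerConfig, sample_rate: float) -> list[str]:
    """Soft checks that return advice strings, never raise.

    Warns when the window outlasts the syllabic-rate bound, when f_max
    exceeds Nyquist (it will be clipped), and when the frequency bins are too
    coarse to be meaningful within the band.
    """
    messages: list[str] = []
    duration = config.window / sample_rate
    bound = time_resolution_bound(config.max_syllabic_rate)
    if duration >= bound:
        messages.append(
            f"window duration {duration * 1e3:.1f} ms is not below the "
            f"{bound * 1e3:.1f} ms needed to resolve {config.max_syllabic_rate:g} Hz syllables"
        )
    nyquist = sample_rate / 2.0
    f_max = config.f_max
    if f_max > nyquist:
        messages.append(f"f_max {f_max:g} Hz exceeds Nyquist ({nyquist:g} Hz); clipping")
        f_max = nyquist
    bin_width = sample_rate / config.window
    if bin_width > (f_max - config.f_min) / 4.0:
        messages.append(
            f"frequency bin width {bin_width:g} Hz is coarse for band "
            f"[{config.f_min:g}, {f_max:g}] Hz (fewer than 4 bins)"
        )
    return messages


def track_f0(signal: AudioSignal, config: TrackerConfig = TrackerConfig()) -> F0Track:
    """Run the full pipeline and return the f0 track.

    Steps: collapse to mono, compute the spectrogram, restrict it to
    [f_min, f_max], take the per-column intensity maximum; in parallel,
    compute the amplitude envelope, reduce it per bin, and threshold it into
    a voiced mask. Voiced bins carry the peak frequency; silent bins NaN.
    Configuration advice from :func:`validate_config` is emitted as
    :class:`TrackerWarning`.
    """
    mono = to_mono(signal, config.channel_policy)
    for message in validate_config(config, mono.sample_rate):
        warnings.warn(message, TrackerWarning, stacklevel=2)
    grid = compute_spectrogram(mono, config)
    f_max = min(config.f_max, float(grid.freqs[-1]))
    band = restrict_band(grid, config.f_min, f_max)
    peak_freq, peak_power = peak_frequency_per_bin(band)
    env = compute_envelope(mono, config.smooth_ms)
    levels = envelope_at_bins(env, grid)
    mask = voiced_mask(levels, config.threshold)
    f0 = np.where(mask, peak_freq, np.nan)
    return F0Track(times=grid.times, f0_hz=f0, voiced=mask, peak_power=peak_power)
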