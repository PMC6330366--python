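"""Synthetic canary-like fixtures with exact ground truth.

Generates pure tones, linear frequency sweeps and syllable trains (tone
bursts separated by silences, optional harmonic partials, optional white
Gaussian background noise) in the 800 Hz - 8 kHz singing range, so every
pipeline stage can be tested against known answers without real recordings.
All generators are deterministic given their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import AudioSignal
from .errors import ConfigurationError


def _check_audible(freq: float, sample_rate: float, what: str = "frequency") -> None:
    if not 0 < freq < sample_rate / 2.0:
        raise ConfigurationError(
            f"{what} {freq:g} Hz must lie in (0, Nyquist={sample_rate / 2:g}) Hz"
        )


def make_tone(f0: float, duration: float, sample_rate: float, amplitude: float = 1.0) -> AudioSignal:
    """Pure sinusoid ``amplitude * sin(2*pi*f0*t)``."""
    _check_audible(f0, sample_rate)
    n = int(round(duration * sample_rate))
    if n < 1:
        raise ConfigurationError(f"duration {duration:g} s yields no samples at {sample_rate:g} Hz")
    t = np.arange(n) / sample_rate
    return AudioSignal(samples=amplitude * np.sin(2.0 * np.pi * f0 * t), sample_rate=sample_rate)


def make_chirp(
    f_start: float, f_end: float, duration: float, sample_rate: float, amplitude: float = 1.0
) -> AudioSignal:
    """Linear sweep with instantaneous frequency ``f_start + (f_end-f_start)*t/duration``.

    The phase is the integral of the instantaneous frequency, so
    ``f_start == f_end`` degenerates exactly to :func:`make_tone`.
    """
    _check_audible(f_start, sample_rate, "start frequency")
    _check_audible(f_end, sample_rate, "end frequency")
    n = int(round(duration * sample_rate))
    if n < 1:
        raise ConfigurationError(f"duration {duration:g} s yields no samples at {sample_rate:g} Hz")
    t = np.arange(n) / sample_rate
    phase = 2.0 * np.pi * f_start * t + np.pi * (f_end - f_start) * t * t / duration
    return AudioSignal(samples=amplitude * np.sin(phase), sample_rate=sample_rate)


@dataclass(frozen=True)
class SyllableSpec:
    """One syllable: a tone (scalar ``f0``) or linear sweep (``(start, end)`` pair).

    ``harmonics`` lists ``(integer multiple >= 2, relative amplitude)``
    partials added on top of the fundamental. ``onset_ramp`` is a
    raised-cosine fade applied at both ends to avoid spectral splatter at
    syllable edges that would otherwise leak across the envelope gate.
    """

    f0: float | tuple[float, float]
    duration: float
    amplitude: float = 1.0
    harmonics: tuple[tuple[int, float], ...] = ()
    onset_ramp: float = 0.005

    def __post_init__(self) -> None:
        start, end = self.f0_pair
        if start <= 0 or end <= 0:
            raise ConfigurationError(f"f0 must be > 0, got {self.f0}")
        if self.duration <= 0:
            raise ConfigurationError(f"duration must be > 0, got {self.duration}")
        if self.amplitude <= 0:
            raise ConfigurationError(f"amplitude must be > 0, got {self.amplitude}")
        for multiple, _rel in self.harmonics:
            if int(multiple) != multiple or multiple < 2:
                raise ConfigurationError(f"harmonic multiples must be integers >= 2, got {multiple}")
        if self.onset_ramp < 0 or 2.0 * self.onset_ramp > self.duration:
            raise ConfigurationError(
                f"need 0 <= 2*onset_ramp <= duration, got ramp {self.onset_ramp}, "
                f"duration {self.duration}"
            )

    @property
    def f0_pair(self) -> tuple[float, float]:
        if isinstance(self.f0, tuple):
            return float(self.f0[0]), float(self.f0[1])
        return float(self.f0), float(self.f0)


@dataclass(frozen=True)
class SyllableTruth:
    """Ground truth for one rendered syllable: extent and linear f0 trajectory."""

    onset: float
    offset: float
    f0_start: float
    f0_end: float

    def f0_at(self, times: np.ndarray) -> np.ndarray:
        """True fundamental at absolute times; NaN outside the syllable."""
        t = np.asarray(times, dtype=np.float64)
        frac = (t - self.onset) / (self.offset - self.onset)
        f0 = self.f0_start + (self.f0_end - self.f0_start) * frac
        return np.where((t >= self.onset) & (t <= self.offset), f0, np.nan)


def render_syllable(spec: SyllableSpec, sample_rate: float) -> np.ndarray:
    """Waveform of one syllable: fundamental + harmonic partials, ramped."""
    f_start, f_end = spec.f0_pair
    wave = make_chirp(f_start, f_end, spec.duration, sample_rate).samples.copy()
    for multiple, rel_amp in spec.harmonics:
        _check_audible(multiple * max(f_start, f_end), sample_rate, f"harmonic {multiple}x")
        wave += rel_amp * make_chirp(
            multiple * f_start, multiple * f_end, spec.duration, sample_rate
        ).samples
    wave *= spec.amplitude
    n_ramp = int(round(spec.onset_ramp * sample_rate))
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        wave[:n_ramp] *= ramp
        wave[-n_ramp:] *= ramp[::-1]
    return wave


def make_syllable_train(
    specs: list[SyllableSpec] | tuple[SyllableSpec, ...],
    gap: float,
    sample_rate: float,
    noise_rms: float = 0.0,
    seed: int = 0,
) -> tuple[AudioSignal, list[SyllableTruth]]:
    """Concatenate ``silence(gap) + syllable + ... + silence(gap)``.

    With ``noise_rms > 0``, zero-mean white Gaussian noise of that RMS is
    added over the whole signal (seeded; same seed gives bit-identical
    output). With ``noise_rms = 0`` the gaps are exactly zero, enabling exact
    silence-gating tests. Returns the signal and per-syllable ground truth
    with onsets/offsets taken from the actual rendered sample indices.
    """
    if not specs:
        raise ConfigurationError("at least one syllable spec is required")
    if gap < 0:
        raise ConfigurationError(f"gap must be >= 0, got {gap}")
    if noise_rms < 0:
        raise ConfigurationError(f"noise_rms must be >= 0, got {noise_rms}")
    gap_n = int(round(gap * sample_rate))
    pieces: list[np.ndarray] = [np.zeros(gap_n)]
    truths: list[SyllableTruth] = []
    cursor = gap_n
    for spec in specs:
        wave = render_syllable(spec, sample_rate)
        f_start, f_end = spec.f0_pair
        truths.append(
            SyllableTruth(
                onset=cursor / sample_rate,
                offset=(cursor + len(wave)) / sample_rate,
                f0_start=f_start,
                f0_end=f_end,
            )
        )
        pieces.append(wave)
        pieces.append(np.zeros(gap_n))
        cursor += len(wave) + gap_n
    samples = np.concatenate(pieces)
    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        samples = samples + noise_rms * rng.standard_normal(len(samples))
    return AudioSignal(samples=samples, sample_rate=sample_rate), truths
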