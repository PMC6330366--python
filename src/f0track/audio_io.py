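"""WAV reading/writing, channel layout handling, and table/figure output.

All audio enters the pipeline as an :class:`AudioSignal`: a float64 array
scaled to [-1, 1] (integer PCM is divided by its type's maximum magnitude so
that envelope thresholds are comparable across encodings) plus a sample rate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import TYPE_CHECKING, Union

import numpy as np
from scipy.io import wavfile

from .errors import (
    ConfigurationError,
    ConsistencyError,
    InputError,
    InsufficientDataError,
    UnsupportedFormatError,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from .spectral import SpectrogramGrid
    from .tracker import F0Track

ChannelPolicy = Union[str, int]

# full-scale magnitude per integer PCM dtype (uint8 is offset-binary)
_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


@dataclass(frozen=True)
class AudioSignal:
    """A sampled waveform.

    Parameters
    ----------
    samples : ndarray
        Shape ``(n,)`` for mono or ``(n, n_channels)`` for multichannel,
        dimensionless amplitude, nominally within [-1, 1].
    sample_rate : float
        Samples per second (Hz).
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise ConfigurationError(f"sample_rate must be > 0, got {self.sample_rate}")
        if samples.size == 0:
            raise InsufficientDataError("signal contains no samples")
        if samples.ndim not in (1, 2):
            raise ConfigurationError("samples must be 1-D (mono) or 2-D (frames, channels)")
        if not np.all(np.isfinite(samples)):
            raise InputError("signal contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return self.n_frames / self.sample_rate


def read_wav(path: str | os.PathLike) -> AudioSignal:
    """Read a PCM or IEEE-float WAV file, rescaling integer encodings to [-1, 1].

    8/16/24/32-bit integer PCM and 32/64-bit float are supported (24-bit is
    delivered by the decoder as left-justified int32, so the int32 scale
    applies). Raises :class:`InputError` for a missing file,
    :class:`UnsupportedFormatError` for non-WAV/compressed input and
    :class:`InsufficientDataError` for a zero-frame file.
    """
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise UnsupportedFormatError(f"{path}: {exc}") from exc
    if data.size == 0:
        raise InsufficientDataError(f"{path}: WAV file contains zero frames")
    if data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:  # pragma: no cover - decoder yields only the dtypes above
        raise UnsupportedFormatError(f"{path}: unsupported sample dtype {data.dtype}")
    return AudioSignal(samples=samples, sample_rate=float(rate))


def write_wav(signal: AudioSignal, path: str | os.PathLike, encoding: str = "pcm16") -> None:
    """Write an :class:`AudioSignal` as WAV.

    ``encoding="pcm16"`` scales by 32768 and clips to the int16 range
    (quantization error <= 2**-15 for in-range input); ``"float32"`` stores
    samples losslessly up to single precision.
    """
    if encoding == "pcm16":
        data = np.clip(np.rint(signal.samples * 32768.0), -32768, 32767).astype(np.int16)
    elif encoding == "float32":
        data = signal.samples.astype(np.float32)
    else:
        raise ConfigurationError(f"unknown encoding {encoding!r} (use 'pcm16' or 'float32')")
    wavfile.write(os.fspath(path), int(round(signal.sample_rate)), data)


def to_mono(signal: AudioSignal, policy: ChannelPolicy = "average") -> AudioSignal:
    """Collapse a signal to one channel.

    ``policy`` is ``"average"`` (per-frame arithmetic mean), ``"left"``,
    ``"right"``, or an integer channel index. Mono input is returned unchanged
    whatever the policy.
    """
    if signal.samples.ndim == 1:
        return signal
    n_ch = signal.n_channels
    if policy == "average":
        mono = signal.samples.mean(axis=1)
    else:
        if policy == "left":
            index = 0
        elif policy == "right":
            index = 1
        elif isinstance(policy, (int, np.integer)):
            index = int(policy)
        else:
            raise ConfigurationError(f"unknown channel policy {policy!r}")
        if not 0 <= index < n_ch:
            raise ConfigurationError(
                f"channel index {index} out of range for {n_ch}-channel signal"
            )
        mono = signal.samples[:, index]
    return AudioSignal(samples=mono, sample_rate=signal.sample_rate)


def write_track_table(track: "F0Track", path: str | os.PathLike, drop_silent: bool = False) -> None:
    """Write a track as a tab-separated text table: time (s) vs f0 (Hz).

    One '#'-prefixed header line names the columns and units. Silent bins are
    written with the literal token ``nan`` unless ``drop_silent``, in which
    case their rows are omitted. Values carry 6 significant digits.
    """
    with open(path, "w", encoding="ascii") as fh:
        fh.write("# time_s\tf0_hz\n")
        for t, f, v in zip(track.times, track.f0_hz, track.voiced):
            if drop_silent and not v:
                continue
            fh.write(f"{t:.6g}\t{f:.6g}\n")


def read_track_table(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Parse a table written by :func:`write_track_table` back into arrays."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0:
        return np.empty(0), np.empty(0)
    return data[:, 0], data[:, 1]


def render_track_figure(
    signal: AudioSignal,
    grid: "SpectrogramGrid",
    track: "F0Track",
    path: str | os.PathLike,
):
    """Render the four diagnostic panels and save them as a raster image.

    Panels: waveform; spectrogram (dB); f0 overlaid on the spectrogram; f0 vs
    time. The output format follows the file extension (jpg, png, ...).
    Returns the matplotlib Figure so callers/tests can inspect the plotted
    data; the caller is responsible for closing it.
    """
    import matplotlib.pyplot as plt

    if len(grid.times) != len(track.times) or not np.allclose(grid.times, track.times):
        raise ConsistencyError("spectrogram and track do not share time bins")

    mono = to_mono(signal)
    t_sig = np.arange(mono.n_frames) / mono.sample_rate
    floor = max(float(grid.power.max()), 1e-30) * 1e-10
    power_db = 10.0 * np.log10(grid.power + floor)

    fig, axes = plt.subplots(4, 1, figsize=(8, 9), sharex=True)
    axes[0].plot(t_sig, mono.samples, lw=0.4, color="k")
    axes[0].set_ylabel("amplitude")
    for ax in (axes[1], axes[2]):
        ax.pcolormesh(grid.times, grid.freqs, power_db, shading="auto", cmap="magma")
        ax.set_ylabel("frequency (Hz)")
    axes[2].plot(track.times, track.f0_hz, ".", ms=3, color="cyan")
    axes[3].plot(track.times, track.f0_hz, ".", ms=3, color="tab:red")
    axes[3].set_ylabel("f0 (Hz)")
    axes[3].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(os.fspath(path), dpi=100)
    return fig
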