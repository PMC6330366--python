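"""Exception and warning types shared across the package."""


class F0TrackError(Exception):
    """Base class for all errors raised by f0track."""


class InputError(F0TrackError):
    """A required input (file, channel, ...) is missing or unreadable."""


class UnsupportedFormatError(InputError):
    """The input file is not a WAV file this package can decode."""


class ConfigurationError(F0TrackError, ValueError):
    """A parameter violates a hard invariant (bad band, overlap >= window, ...)."""


class InsufficientDataError(F0TrackError, ValueError):
    """The signal is too short (or empty) for the requested analysis."""


class ConsistencyError(F0TrackError, ValueError):
    """Two objects that must share an axis (time bins, coverage) do not."""


class TrackerWarning(UserWarning):
    """Non-fatal configuration advice (e.g. window too long for the syllabic rate)."""
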