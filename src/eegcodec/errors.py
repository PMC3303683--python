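"""Exception hierarchy for the codec.

All codec-raised errors derive from :class:`EEGCodecError` so callers can
catch the whole family; argument/contract violations additionally derive
from :class:`ValueError` to behave like ordinary Python APIs.
"""


class EEGCodecError(Exception):
    """Base class for all errors raised by eegcodec."""


class InvalidArgumentError(EEGCodecError, ValueError):
    """An argument violates an operation's precondition."""


class EmptyInputError(InvalidArgumentError):
    """An input signal/stream that must be non-empty is empty."""


class ParseError(EEGCodecError, ValueError):
    """A text input could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class RangeError(EEGCodecError, ValueError):
    """A sample value lies outside the declared bit-depth range."""


class TrainingFailureError(EEGCodecError, RuntimeError):
    """Predictor training diverged (non-finite loss)."""


class UnsupportedModeError(EEGCodecError):
    """A benchmark-only mode was requested on the decodable codec path."""


class ContainerCorruptionError(EEGCodecError):
    """The compressed container failed validation (magic/length/checksum)."""


class VersionError(ContainerCorruptionError):
    """The container was written by an incompatible format version."""
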