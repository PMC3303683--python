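"""Single-channel EEG signals and the one-integer-per-line ASCII dialect.

Signals are sequences of signed integer samples (LSB counts) with a
sampling rate and a bit depth; the default matches clinical scalp/depth
recordings digitised at 173.61 Hz with 12-bit accuracy.  The on-disk text
dialect is one decimal integer per line (LF written; LF or CRLF read),
the format the public Bonn epilepsy recordings are distributed in.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInputError, InvalidArgumentError, ParseError, RangeError

DEFAULT_FS = 173.61
DEFAULT_BIT_DEPTH = 12


def bit_depth_range(bit_depth: int) -> tuple[int, int]:
    """Inclusive signed sample range for an ``n``-bit signal."""
    return -(1 << (bit_depth - 1)), (1 << (bit_depth - 1)) - 1


@dataclass
class EEGSignal:
    """An integer-sampled single-channel EEG trace.

    Parameters
    ----------
    samples
        Signed integer samples, in LSB counts of the ADC.
    fs
        Sampling rate in Hz.
    bit_depth
        ADC resolution ``n``; every sample must lie in
        ``[-2**(n-1), 2**(n-1) - 1]``.
    label
        Free-text profile tag (e.g. the generator profile name).
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    bit_depth: int = DEFAULT_BIT_DEPTH
    label: str = field(default="")

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.int64)
        if self.samples.ndim != 1:
            raise InvalidArgumentError("samples must be one-dimensional")
        if self.fs <= 0:
            raise InvalidArgumentError("sampling rate must be positive")
        if not (2 <= int(self.bit_depth) <= 32):
            raise InvalidArgumentError("bit_depth out of supported range")
        lo, hi = bit_depth_range(self.bit_depth)
        if self.samples.size and (
            self.samples.min() < lo or self.samples.max() > hi
        ):
            raise RangeError(
                f"samples exceed the {self.bit_depth}-bit range [{lo}, {hi}]"
            )

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def require_nonempty(self) -> None:
        if len(self) == 0:
            raise EmptyInputError("signal is empty")


def read_ascii_signal(
    path: str | os.PathLike,
    fs: float = DEFAULT_FS,
    bit_depth: int = DEFAULT_BIT_DEPTH,
) -> EEGSignal:
    """Read a one-integer-per-line ASCII signal file.

    Blank lines are ignored; leading/trailing whitespace around a token is
    accepted.  Raises :class:`ParseError` (with the offending 1-based line
    number) on a non-integer token, :class:`EmptyInputError` on a file with
    no samples, and :class:`RangeError` if a value exceeds ``bit_depth``.
    """
    values: list[int] = []
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                values.append(int(token))
            except ValueError:
                raise ParseError(
                    f"line {lineno}: not an integer: {token!r}", line=lineno
                ) from None
    if not values:
        raise EmptyInputError(f"no samples in {os.fspath(path)!r}")
    lo, hi = bit_depth_range(bit_depth)
    arr = np.asarray(values, dtype=np.int64)
    if arr.min() < lo or arr.max() > hi:
        raise RangeError(
            f"value outside the {bit_depth}-bit range [{lo}, {hi}] in "
            f"{os.fspath(path)!r}"
        )
    return EEGSignal(arr, fs=fs, bit_depth=bit_depth)


def write_ascii_signal(signal: EEGSignal, path: str | os.PathLike) -> None:
    """Write ``signal`` in the ASCII dialect (LF line endings).

    ``read_ascii_signal(write_ascii_signal(s))`` reproduces ``s.samples``
    exactly.  Empty signals are rejected.
    """
    signal.require_nonempty()
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.writelines(f"{int(v)}\n" for v in signal.samples)
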