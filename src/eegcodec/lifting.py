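"""Reversible integer 5/3 (LeGall) lifting wavelet transform.

The 5/3 biorthogonal wavelet factors into one predict and one update
lifting step; with floor rounding both steps map integers to integers and
are exactly invertible, which is what makes the preprocessing stage
lossless:

    d[k] = x[2k+1] - floor((x[2k] + x[2k+2]) / 2)
    a[k] = x[2k]   + floor((d[k-1] + d[k] + 2) / 4)

Boundaries use whole-sample symmetric extension (``x[-1] = x[1]``,
``x[N] = x[N-2]``; mirrored detail indices in the update step), and an
odd-length input gives the approximation the extra sample - the reversible
convention of JPEG-2000.  Multi-level analysis recurses on the
approximation, four levels by default.

A worst-case coefficient growth of two bits over the filter plus rounding
gives the ``n+4``-bit alphabet bound used when packing raw coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, InvalidArgumentError

DEFAULT_LEVELS = 4


def coefficient_bound(bit_depth: int) -> int:
    """Hard magnitude bound for coefficients of an ``n``-bit signal.

    Coefficients of a signal in ``[-2**(n-1), 2**(n-1)-1]`` fit in ``n+4``
    signed bits after four decomposition levels; the bound is used for the
    predictor clamp and for packing raw (unpredicted) coefficients.
    """
    return 1 << (bit_depth + 3)


@dataclass
class SubbandSet:
    """Integer wavelet coefficients of one signal block.

    ``details[0]`` is the finest level d^(1); ``approx`` is the coarsest
    approximation a^(L).  ``levels`` is the effective decomposition depth
    (it may be smaller than requested for short inputs).
    """

    levels: int
    details: list[np.ndarray]
    approx: np.ndarray
    original_length: int

    def validate(self) -> None:
        if self.levels != len(self.details):
            raise InvalidArgumentError("levels does not match detail count")
        n = self.original_length
        for d in self.details:  # finest first
            if len(d) != n // 2:
                raise InvalidArgumentError("inconsistent subband lengths")
            n = (n + 1) // 2
        if len(self.approx) != n:
            raise InvalidArgumentError("inconsistent approximation length")

    def segments(self) -> list[np.ndarray]:
        """Coding order: approximation first, then details coarse-to-fine."""
        return [self.approx] + list(reversed(self.details))


def subband_lengths(original_length: int, levels: int) -> list[int]:
    """Lengths of the coding-order segments for a given input length."""
    n = original_length
    det = []
    for _ in range(levels):
        det.append(n // 2)
        n = (n + 1) // 2
    return [n] + list(reversed(det))


def _neighbors(even: np.ndarray, n_odd: int, n: int) -> np.ndarray:
    """x[2k+2] for each detail index k, with symmetric right extension."""
    if n % 2 == 0:
        # last odd sample's right neighbour mirrors to x[N-2] = even[-1]
        return np.concatenate([even[1:], even[-1:]])
    return even[1 : n_odd + 1]


def lift_forward_53(x) -> tuple[np.ndarray, np.ndarray]:
    """One analysis level: split ``x`` into (approximation, detail)."""
    x = np.asarray(x, dtype=np.int64)
    n = len(x)
    if n < 2:
        raise InvalidArgumentError("lifting requires at least 2 samples")
    even = x[0::2]
    odd = x[1::2]
    right = _neighbors(even, len(odd), n)
    detail = odd - ((even[: len(odd)] + right) >> 1)

    # update step operands: d[k-1] and d[k] with mirrored detail indices
    d_prev = np.concatenate([detail[:1], detail[: len(even) - 1]])
    if len(even) > len(detail):  # odd n: d[K] mirrors to d[K-1]
        d_curr = np.concatenate([detail, detail[-1:]])
    else:
        d_curr = detail
    approx = even + ((d_prev + d_curr + 2) >> 2)
    return approx, detail


def lift_inverse_53(approx, detail, out_length: int) -> np.ndarray:
    """Exact inverse of :func:`lift_forward_53`."""
    approx = np.asarray(approx, dtype=np.int64)
    detail = np.asarray(detail, dtype=np.int64)
    if out_length < 2:
        raise InvalidArgumentError("out_length must be >= 2")
    if len(approx) != (out_length + 1) // 2 or len(detail) != out_length // 2:
        raise InvalidArgumentError("subband lengths do not match out_length")

    d_prev = np.concatenate([detail[:1], detail[: len(approx) - 1]])
    if len(approx) > len(detail):
        d_curr = np.concatenate([detail, detail[-1:]])
    else:
        d_curr = detail
    even = approx - ((d_prev + d_curr + 2) >> 2)
    right = _neighbors(even, len(detail), out_length)
    odd = detail + ((even[: len(detail)] + right) >> 1)

    x = np.empty(out_length, dtype=np.int64)
    x[0::2] = even
    x[1::2] = odd
    return x


def dwt_multilevel(x, levels: int = DEFAULT_LEVELS) -> SubbandSet:
    """Multi-level analysis; recurses on the approximation.

    For inputs too short for the requested depth the effective number of
    levels is reduced (a one-sample input bypasses the transform with
    ``levels = 0``).  Empty input is an error.
    """
    x = np.asarray(x, dtype=np.int64)
    if len(x) == 0:
        raise EmptyInputError("cannot transform an empty signal")
    if levels < 1:
        raise InvalidArgumentError("levels must be >= 1")
    details: list[np.ndarray] = []
    cur = x
    while len(details) < levels and len(cur) >= 2:
        cur, d = lift_forward_53(cur)
        details.append(d)
    return SubbandSet(
        levels=len(details),
        details=details,
        approx=cur,
        original_length=len(x),
    )


def idwt_multilevel(sb: SubbandSet) -> np.ndarray:
    """Exact inverse of :func:`dwt_multilevel`."""
    sb.validate()
    cur = np.asarray(sb.approx, dtype=np.int64)
    for d in reversed(sb.details):  # coarsest reconstruction first
        cur = lift_inverse_53(cur, d, len(cur) + len(d))
    if len(cur) != sb.original_length:
        raise InvalidArgumentError("reconstructed length mismatch")
    return cur
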