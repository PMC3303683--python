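"""Deterministic fixed-point arithmetic for predictor inference.

Lossless prediction coding only works if the decoder reproduces the
encoder's predictions bit for bit.  Floating point cannot guarantee that
across platforms, so every inference-time operation here is defined over
Python integers: weights are ``j``-bit integers with a per-layer
power-of-two scale, activations carry :data:`ACT_FRAC_BITS` fractional
bits, and every rescale rounds half away from zero.

The hidden-layer tanh is evaluated through a fixed 2048-entry table over
[-4, 4) with integer linear interpolation; outside that range tanh is
saturated to +/-1 in fixed point.
"""

from __future__ import annotations

import math

#: fractional bits carried by activations / intermediate values
ACT_FRAC_BITS = 16
ACT_ONE = 1 << ACT_FRAC_BITS

#: default width of transmitted weight integers ("j" bits of side info)
DEFAULT_WEIGHT_BITS = 16

_TANH_SPAN = 4          # tanh treated as saturated beyond |z| = 4
_TANH_ENTRIES = 2048
_TANH_STEP = (2 * _TANH_SPAN * ACT_ONE) // _TANH_ENTRIES  # fp units per entry

_TANH_TABLE = tuple(
    int(round(math.tanh(-_TANH_SPAN + (2 * _TANH_SPAN) * i / _TANH_ENTRIES) * ACT_ONE))
    for i in range(_TANH_ENTRIES + 1)
)


def rshift_round(value: int, shift: int) -> int:
    """Arithmetic right shift by ``shift`` bits, rounding half away from zero.

    ``shift <= 0`` degenerates to a left shift.  Defined for arbitrary
    Python integers, hence exact for any operand width.
    """
    if shift <= 0:
        return value << (-shift)
    half = 1 << (shift - 1)
    if value >= 0:
        return (value + half) >> shift
    return -((-value + half) >> shift)


def div_round(num: int, den: int) -> int:
    """Integer division rounding half away from zero; ``den`` must be > 0."""
    if den <= 0:
        raise ValueError("denominator must be positive")
    if num >= 0:
        return (num + den // 2) // den
    return -((-num + den // 2) // den)


def quantize_weight(w: float, scale_exp: int) -> int:
    """Round ``w * 2**scale_exp`` half away from zero to an integer."""
    scaled = w * (1 << scale_exp) if scale_exp >= 0 else w / (1 << -scale_exp)
    return int(math.floor(abs(scaled) + 0.5)) * (1 if scaled >= 0 else -1)


def choose_scale_exp(max_abs: float, weight_bits: int = DEFAULT_WEIGHT_BITS) -> int:
    """Largest power-of-two exponent keeping ``max_abs`` inside ``weight_bits``.

    Returns the biggest ``s`` with ``round(max_abs * 2**s) <= 2**(bits-1)-1``,
    clamped to [-8, 40] so degenerate all-zero layers get a sane default.
    """
    limit = (1 << (weight_bits - 1)) - 1
    if max_abs <= 0:
        return weight_bits - 1
    s = int(math.floor(math.log2(limit / max_abs)))
    # floating-point log can be off by one; correct by direct check
    while abs(quantize_weight(max_abs, s + 1)) <= limit and s < 40:
        s += 1
    while abs(quantize_weight(max_abs, s)) > limit and s > -8:
        s -= 1
    return s


def to_fixed(x: int, input_scale_exp: int) -> int:
    """Map an integer coefficient to a fixed-point activation.

    The real-valued input to the network is ``x * 2**-b`` (``b`` the input
    scale exponent); its fixed-point image is that value times ``ACT_ONE``.
    """
    return rshift_round(x << ACT_FRAC_BITS, input_scale_exp)


def from_fixed(y_fp: int, input_scale_exp: int) -> int:
    """Inverse of :func:`to_fixed`: rescale a network output to an integer."""
    return rshift_round(y_fp << input_scale_exp, ACT_FRAC_BITS)


def tanh_fixed(z_fp: int) -> int:
    """tanh on a fixed-point value, via table lookup + linear interpolation."""
    lo = -_TANH_SPAN * ACT_ONE
    hi = _TANH_SPAN * ACT_ONE
    if z_fp <= lo:
        return -ACT_ONE
    if z_fp >= hi:
        return ACT_ONE
    pos = z_fp - lo
    idx, frac = divmod(pos, _TANH_STEP)
    base = _TANH_TABLE[idx]
    delta = _TANH_TABLE[idx + 1] - base
    return base + div_round(delta * frac, _TANH_STEP)
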