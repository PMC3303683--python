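"""Context-based bias cancellation of prediction residues.

The residue sequence left by a predictor is a mixture of sources with
different local means.  Classifying each position by a small context --
the signs of ``m`` local signal differences, two-level quantised as
``Q(d) = 0 if d < 0 else 1`` -- and subtracting the per-context mean
residue recentres every mixture component on zero, which sharpens the
Laplacian the entropy coder sees.

Two context definitions are provided:

``symmetric``
    d_i = x[k+i] - x[k-i].  This variant uses the *future* sample and is
    therefore measurable only at the encoder; the decodable codec path
    refuses it (benchmark/analysis use only).
``causal``
    d_i = x[k-i] - x[k-i-1]: adjacent past differences, computable from
    already-reconstructed coefficients, hence exactly invertible at the
    decoder given the transmitted bias table.

Positions too close to a segment edge for the full difference window map
to the reserved context 0.  Ties d_i = 0 quantise to bit 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, UnsupportedModeError
from .fixedpoint import div_round
from .predictors import ResidualStream, SegmentResiduals

MODES = ("symmetric", "causal")

#: context counts swept by the evaluation harness (2**m)
CONTEXT_COUNT_SWEEP = (4, 8, 16, 32, 256)


@dataclass(frozen=True)
class ContextConfig:
    """Context depth ``m`` (2**m contexts) and causality mode."""

    m: int = 5
    mode: str = "causal"

    def __post_init__(self):
        if self.m < 1 or self.m > 8:
            raise InvalidArgumentError("context depth m must lie in [1, 8]")
        if self.mode not in MODES:
            raise InvalidArgumentError(f"unknown context mode {self.mode!r}")

    @property
    def context_count(self) -> int:
        return 1 << self.m


@dataclass
class BiasTable:
    """Per-context integer offsets (rounded mean residues) and counts."""

    config: ContextConfig
    bias: np.ndarray    # int64, length 2**m
    counts: np.ndarray  # int64, length 2**m

    def validate_against(self, cfg: ContextConfig) -> None:
        if self.config != cfg or len(self.bias) != cfg.context_count:
            raise InvalidArgumentError("bias table does not match context config")


def context_index(coeff_stream, k: int, cfg: ContextConfig) -> int:
    """Context of position ``k`` within one coefficient segment.

    Returns an integer in ``[0, 2**m)``; positions whose difference window
    would leave the segment map to the reserved context 0.
    """
    x = np.asarray(coeff_stream, dtype=np.int64)
    if not (0 <= k < len(x)):
        raise InvalidArgumentError(f"position {k} out of range")
    m = cfg.m
    if cfg.mode == "symmetric":
        if k - m < 0 or k + m >= len(x):
            return 0
        diffs = [int(x[k + i]) - int(x[k - i]) for i in range(1, m + 1)]
    else:
        if k < m + 1:
            return 0
        diffs = [int(x[k - i]) - int(x[k - i - 1]) for i in range(1, m + 1)]
    idx = 0
    for i, d in enumerate(diffs):  # bit_i = Q(d_i), weight 2**(i-1)
        if d >= 0:
            idx |= 1 << i
    return idx


def _segment_context_indices(x: np.ndarray, cfg: ContextConfig,
                             start: int) -> np.ndarray:
    """Vectorised contexts for positions start..len(x)-1 of one segment."""
    n = len(x)
    ks = np.arange(start, n)
    idx = np.zeros(len(ks), dtype=np.int64)
    m = cfg.m
    if cfg.mode == "symmetric":
        valid = (ks - m >= 0) & (ks + m < n)
    else:
        valid = ks >= m + 1
    kv = ks[valid]
    acc = np.zeros(len(kv), dtype=np.int64)
    for i in range(1, m + 1):
        if cfg.mode == "symmetric":
            d = x[kv + i] - x[kv - i]
        else:
            d = x[kv - i] - x[kv - i - 1]
        acc |= (d >= 0).astype(np.int64) << (i - 1)
    idx[valid] = acc
    return idx


def _stream_segments(coeff_stream, res: ResidualStream) -> list[np.ndarray]:
    """Coefficient segments aligned with ``res.segments``."""
    if isinstance(coeff_stream, (list, tuple)):
        segs = [np.asarray(s, dtype=np.int64) for s in coeff_stream]
    else:
        segs = [np.asarray(coeff_stream, dtype=np.int64)]
    if len(segs) != len(res.segments):
        raise InvalidArgumentError(
            "coefficient segments do not align with residual segments"
        )
    for x, seg in zip(segs, res.segments):
        if len(x) != len(seg.raw) + len(seg.residues):
            raise InvalidArgumentError(
                "coefficient segment length does not match residuals"
            )
    return segs


def residual_contexts(coeff_stream, res: ResidualStream,
                      cfg: ContextConfig) -> np.ndarray:
    """Context index for every residue position, concatenated."""
    segs = _stream_segments(coeff_stream, res)
    parts = [
        _segment_context_indices(x, cfg, len(seg.raw))
        for x, seg in zip(segs, res.segments)
    ]
    return np.concatenate(parts) if parts else np.zeros(0, dtype=np.int64)


def build_bias_table(coeff_stream, res: ResidualStream,
                     cfg: ContextConfig) -> BiasTable:
    """Estimate per-context offsets: rounded (half away from zero) means.

    Contexts never observed get bias 0.
    """
    ctx = residual_contexts(coeff_stream, res, cfg)
    e = res.all_residues()
    nc = cfg.context_count
    sums = np.bincount(ctx, weights=e.astype(np.float64), minlength=nc)
    counts = np.bincount(ctx, minlength=nc).astype(np.int64)
    bias = np.zeros(nc, dtype=np.int64)
    for c in range(nc):
        if counts[c]:
            bias[c] = div_round(int(round(sums[c])), int(counts[c]))
    return BiasTable(config=cfg, bias=bias, counts=counts)


def _shift_residues(res: ResidualStream, table: BiasTable, coeff_stream,
                    sign: int) -> ResidualStream:
    segs = _stream_segments(coeff_stream, res)
    out = []
    for x, seg in zip(segs, res.segments):
        ctx = _segment_context_indices(x, table.config, len(seg.raw))
        shifted = seg.residues + sign * table.bias[ctx]
        out.append(SegmentResiduals(raw=seg.raw.copy(),
                                    residues=shifted.astype(np.int64)))
    return ResidualStream(order=res.order, segments=out)


def apply_bias_cancellation(res: ResidualStream, table: BiasTable,
                            coeff_stream) -> ResidualStream:
    """e'_k = e_k - bias[context(k)]; raw leading samples untouched."""
    return _shift_residues(res, table, coeff_stream, sign=-1)


def remove_bias_cancellation(res_corrected: ResidualStream, table: BiasTable,
                             decoded_stream) -> ResidualStream:
    """Exact inverse of :func:`apply_bias_cancellation`.

    Requires causal contexts: at decode time the context of position k
    must be computable from already-reconstructed coefficients, which the
    symmetric (future-sample) definition cannot guarantee.
    """
    if table.config.mode != "causal":
        raise UnsupportedModeError(
            "symmetric contexts are benchmark-only; the decodable codec "
            "requires causal mode"
        )
    return _shift_residues(res_corrected, table, decoded_stream, sign=+1)
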