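"""End-to-end codec: blocks -> wavelet -> prediction -> bias -> entropy.

The encoder segments the signal (single-block SB, or block-adaptive BA
with 90-second blocks), applies the four-level integer 5/3 wavelet per
block, trains/fits the configured predictor on the block's coefficient
stream, computes residues, optionally cancels per-context bias (causal
contexts only on the decodable path), entropy codes the corrected
residues with LZARIC and assembles a self-describing container.  The
decoder inverts every stage exactly; a CRC-32 of the original samples
guards against silent corruption.

``benchmark_bps`` runs the encoder only and reports the size breakdown;
it additionally accepts the symmetric (future-sample) context definition
for measurement studies, which the decodable path refuses.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .container import (
    BIAS_MODES,
    SCHEMES,
    BlockData,
    CompressedContainer,
    crc32_samples,
)
from .context import (
    BiasTable,
    ContextConfig,
    apply_bias_cancellation,
    build_bias_table,
)
from .entropy import decode_residues, encode_residues
from .errors import (
    ContainerCorruptionError,
    EmptyInputError,
    InvalidArgumentError,
    UnsupportedModeError,
)
from .lifting import SubbandSet, coefficient_bound, dwt_multilevel, idwt_multilevel, subband_lengths
from .metrics import SizeBreakdown
from .predictors import (
    NLMSFilter,
    PredictorSpec,
    QuantizedPredictor,
    ResidualStream,
    SegmentResiduals,
    predict_next_with_state,
    segment_residuals,
    train_predictor,
)
from .signal_io import EEGSignal


@dataclass
class CodecConfig:
    """Full encoder configuration."""

    predictor: PredictorSpec = field(default_factory=PredictorSpec)
    levels: int = 4
    scheme: str = "SB"
    block_seconds: float = 90.0
    context: ContextConfig = field(default_factory=ContextConfig)
    bias: str = "IBC"

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise InvalidArgumentError(f"unknown scheme {self.scheme!r}")
        if self.bias not in BIAS_MODES:
            raise InvalidArgumentError(f"unknown bias mode {self.bias!r}")
        if self.block_seconds <= 0:
            raise InvalidArgumentError("block_seconds must be positive")
        if self.levels < 1:
            raise InvalidArgumentError("levels must be >= 1")

    def bias_context(self) -> ContextConfig | None:
        """Context configuration implied by the bias mode.

        The original bias-cancellation scheme (BC) conditions on a single
        adjacent-sample difference; the improved scheme (IBC) uses the
        configured depth ``m``.
        """
        if self.bias == "WBC":
            return None
        if self.bias == "BC":
            return ContextConfig(m=1, mode="causal")
        return self.context


def split_blocks(signal: EEGSignal, cfg: CodecConfig) -> list[tuple[int, int]]:
    """Sample ranges of the processing blocks.

    SB: one full-length range.  BA: consecutive ranges of
    ``floor(block_seconds * fs)`` samples; the final remainder is merged
    into the preceding block (a remainder shorter than ``2**levels``
    would starve the wavelet).
    """
    signal.require_nonempty()
    n = len(signal)
    if cfg.scheme == "SB":
        return [(0, n)]
    size = int(cfg.block_seconds * signal.fs)
    if size < 1 or size >= n:
        return [(0, n)]
    ranges = [(s, min(s + size, n)) for s in range(0, n, size)]
    if len(ranges) > 1 and ranges[-1][1] - ranges[-1][0] < (1 << cfg.levels):
        last = ranges.pop()
        prev = ranges.pop()
        ranges.append((prev[0], last[1]))
    return ranges


def _transform_block(x: np.ndarray, levels: int) -> SubbandSet:
    if len(x) < 2:
        # single-sample blocks bypass the transform
        return SubbandSet(levels=0, details=[], approx=x.astype(np.int64),
                          original_length=len(x))
    return dwt_multilevel(x, levels)


def _encode_block(
    x: np.ndarray,
    cfg: CodecConfig,
    bit_depth: int,
    allow_symmetric: bool,
) -> tuple[BlockData, dict]:
    clamp = coefficient_bound(bit_depth)
    sb = _transform_block(x, cfg.levels)
    # one predictor per subband segment: the segments are distinct
    # stochastic processes with very different scales
    models = []
    res_segments = []
    for seg in sb.segments():
        if len(seg) <= cfg.predictor.order:
            models.append(None)
            res_segments.append(SegmentResiduals(
                raw=np.asarray(seg, dtype=np.int64).copy(),
                residues=np.zeros(0, dtype=np.int64)))
            continue
        model = train_predictor(seg, cfg.predictor, clamp_abs=clamp)
        models.append(model)
        res_segments.append(segment_residuals(model, seg))
    res = ResidualStream(order=cfg.predictor.order, segments=res_segments)

    ctx_cfg = cfg.bias_context()
    table: BiasTable | None = None
    if ctx_cfg is not None:
        if ctx_cfg.mode == "symmetric" and not allow_symmetric:
            raise UnsupportedModeError(
                "symmetric contexts cannot be decoded; use causal mode or "
                "benchmark_bps for measurement"
            )
        table = build_bias_table(sb.segments(), res, ctx_cfg)
        res_coded = apply_bias_cancellation(res, table, sb.segments())
    else:
        res_coded = res

    payload = encode_residues(res_coded.all_residues())
    raw_values = (
        np.concatenate([seg.raw for seg in res.segments])
        if res.segments else np.zeros(0, dtype=np.int64)
    )
    blk = BlockData(length=len(x), eff_levels=sb.levels, models=models,
                    bias_table=table, raw_values=raw_values, payload=payload)
    width = bit_depth + 4
    sizes = {
        "raw_header_bits": len(raw_values) * width,
        "side_info_bits": sum(m.side_info_bits() for m in models if m),
        "bias_table_bits": (16 + 16 * table.config.context_count) if table else 0,
        "payload_bits": 8 * len(payload),
        "r": res.residue_count(),
    }
    return blk, sizes


def _run_encoder(signal: EEGSignal, cfg: CodecConfig,
                 allow_symmetric: bool) -> CompressedContainer:
    signal.require_nonempty()
    t0 = time.perf_counter()
    ranges = split_blocks(signal, cfg)
    blocks = []
    totals = {"raw_header_bits": 0, "side_info_bits": 0, "bias_table_bits": 0,
              "payload_bits": 0, "r": 0}
    for start, stop in ranges:
        blk, sizes = _encode_block(signal.samples[start:stop], cfg,
                                   signal.bit_depth, allow_symmetric)
        blocks.append(blk)
        for k in totals:
            totals[k] += sizes[k]
    fs_num, fs_den = CompressedContainer.fs_to_rational(signal.fs)
    container = CompressedContainer(
        fs_num=fs_num, fs_den=fs_den, bit_depth=signal.bit_depth,
        levels=cfg.levels, scheme=cfg.scheme, bias_mode=cfg.bias,
        context_mode=cfg.context.mode if cfg.bias == "IBC" else "causal",
        context_m=cfg.context.m, original_length=len(signal),
        crc32=crc32_samples(signal.samples), blocks=blocks,
    )
    n_bytes = len(container.to_bytes())
    component_bits = sum(totals[k] for k in
                         ("raw_header_bits", "side_info_bits",
                          "bias_table_bits", "payload_bits"))
    container.breakdown = SizeBreakdown(
        v=len(signal), n=signal.bit_depth, p=cfg.predictor.order,
        raw_header_bits=totals["raw_header_bits"],
        side_info_bits=totals["side_info_bits"],
        bias_table_bits=totals["bias_table_bits"],
        payload_bits=totals["payload_bits"],
        overhead_bits=8 * n_bytes - component_bits,
        r=totals["r"],
        processing_time_s=time.perf_counter() - t0,
    )
    return container


def compress(signal: EEGSignal, cfg: CodecConfig | None = None) -> CompressedContainer:
    """Losslessly compress a signal; ``decompress`` inverts it bit-exactly.

    The decodable path requires causal contexts whenever bias cancellation
    is enabled; a symmetric-context request raises
    :class:`UnsupportedModeError` pointing at :func:`benchmark_bps`.
    """
    cfg = cfg or CodecConfig()
    return _run_encoder(signal, cfg, allow_symmetric=False)


def benchmark_bps(signal: EEGSignal, cfg: CodecConfig | None = None) -> SizeBreakdown:
    """Encoder-only measurement run (symmetric Eq-style contexts allowed)."""
    cfg = cfg or CodecConfig()
    return _run_encoder(signal, cfg, allow_symmetric=True).breakdown


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _ctx_index_prefix(x: np.ndarray, k: int, m: int) -> int:
    """Causal context of position k from the reconstructed prefix."""
    if k < m + 1:
        return 0
    idx = 0
    for i in range(1, m + 1):
        if x[k - i] - x[k - i - 1] >= 0:
            idx |= 1 << (i - 1)
    return idx


def _decode_segment(model: QuantizedPredictor | None, raw: np.ndarray,
                    res_corr: np.ndarray, table: BiasTable | None) -> np.ndarray:
    if model is None:
        if len(res_corr):
            raise ContainerCorruptionError(
                "residues present for a model-free segment"
            )
        return np.asarray(raw, dtype=np.int64)
    p = model.order
    n = len(raw) + len(res_corr)
    x = np.empty(n, dtype=np.int64)
    x[: len(raw)] = raw
    m = table.config.m if table is not None else 0
    bias = table.bias if table is not None else None
    if model.kind == "nlms":
        filt = NLMSFilter(model.order, model.mu_num, model.mu_den, model.eps,
                          model.clamp_abs)
        for k in range(len(raw), n):
            e = int(res_corr[k - len(raw)])
            if bias is not None:
                e += int(bias[_ctx_index_prefix(x, k, m)])
            window = x[k - p : k]
            pred = filt.predict(window)
            x[k] = pred + e
            filt.update(window, e)
    else:
        state = model.init_state()
        for k in range(len(raw), n):
            e = int(res_corr[k - len(raw)])
            if bias is not None:
                e += int(bias[_ctx_index_prefix(x, k, m)])
            pred, state = predict_next_with_state(model, x[k - p : k], state)
            x[k] = pred + e
    return x


def _decode_block(blk: BlockData) -> np.ndarray:
    if blk.bias_table is not None and blk.bias_table.config.mode != "causal":
        raise UnsupportedModeError(
            "container holds symmetric (benchmark-only) contexts; not decodable"
        )
    seg_lengths = subband_lengths(blk.length, blk.eff_levels)
    if len(blk.models) != len(seg_lengths):
        raise ContainerCorruptionError("model count does not match segment count")
    residues = decode_residues(blk.payload)
    raw_pos = 0
    res_pos = 0
    rebuilt = []
    for seg_len, model in zip(seg_lengths, blk.models):
        raw_n = seg_len if model is None else min(model.order, seg_len)
        raw = blk.raw_values[raw_pos : raw_pos + raw_n]
        raw_pos += raw_n
        n_res = seg_len - raw_n
        seg_res = residues[res_pos : res_pos + n_res]
        res_pos += n_res
        if len(raw) != raw_n or len(seg_res) != n_res:
            raise ContainerCorruptionError("block sections shorter than declared")
        rebuilt.append(_decode_segment(model, raw, seg_res, blk.bias_table))
    if res_pos != len(residues):
        raise ContainerCorruptionError("residue payload longer than declared")
    approx = rebuilt[0]
    details = list(reversed(rebuilt[1:]))
    sb = SubbandSet(levels=blk.eff_levels, details=details, approx=approx,
                    original_length=blk.length)
    if blk.eff_levels == 0:
        return approx
    return idwt_multilevel(sb)


def decompress(container: CompressedContainer | bytes) -> EEGSignal:
    """Exact inverse of :func:`compress`; verifies the sample CRC-32."""
    if isinstance(container, (bytes, bytearray)):
        container = CompressedContainer.from_bytes(bytes(container))
    parts = [_decode_block(blk) for blk in container.blocks]
    samples = np.concatenate(parts) if parts else np.zeros(0, dtype=np.int64)
    if len(samples) != container.original_length:
        raise ContainerCorruptionError(
            f"decoded length {len(samples)} != declared "
            f"{container.original_length}"
        )
    if crc32_samples(samples) != container.crc32:
        raise ContainerCorruptionError("checksum mismatch on decoded samples")
    return EEGSignal(samples, fs=container.fs, bit_depth=container.bit_depth)


# ---------------------------------------------------------------------------
# evaluation sweeps
# ---------------------------------------------------------------------------

def sweep_orders(signal: EEGSignal, base: CodecConfig,
                 orders=(2, 5, 10, 20)) -> list[SizeBreakdown]:
    """One benchmark row per predictor order (hidden sizes re-paired)."""
    rows = []
    for p in orders:
        spec = replace(base.predictor, order=p, hidden=None)
        cfg = replace(base, predictor=spec)
        rows.append(benchmark_bps(signal, cfg))
    return rows
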