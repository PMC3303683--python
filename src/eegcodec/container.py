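"""Self-describing binary container for compressed EEG blocks.

Layout (all multi-byte integers little-endian): a fixed header with magic
``EWNZ``, format version, the sampling rate as a rational (so no float
drift), bit depth, decomposition levels, block scheme, bias mode and
context configuration, the original sample count and a CRC-32 of the
original samples; then one section per block holding the serialised
predictor (absent for NLMS, which re-adapts symmetrically), the bias
table, the raw leading coefficients bit-packed at ``n+4`` bits each, and
the entropy-coded residue payload.  Decoding uses header bytes only.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .context import BiasTable, ContextConfig
from .errors import ContainerCorruptionError, VersionError
from .predictors import PREDICTOR_KINDS, LayerQ, QuantizedPredictor

MAGIC = b"EWNZ"
FORMAT_VERSION = 1

SCHEMES = ("SB", "BA")
BIAS_MODES = ("WBC", "BC", "IBC")
_CTX_MODES = ("causal", "symmetric")


def crc32_samples(samples: np.ndarray) -> int:
    return zlib.crc32(np.asarray(samples, dtype="<i4").tobytes()) & 0xFFFFFFFF


# ---------------------------------------------------------------------------
# bit-packing of raw coefficients (n+4 bits each, two's complement)
# ---------------------------------------------------------------------------

def pack_signed(values: np.ndarray, width: int) -> bytes:
    acc = 0
    nbits = 0
    out = bytearray()
    mask = (1 << width) - 1
    for v in values:
        acc = (acc << width) | (int(v) & mask)
        nbits += width
        while nbits >= 8:
            nbits -= 8
            out.append((acc >> nbits) & 0xFF)
    if nbits:
        out.append((acc << (8 - nbits)) & 0xFF)
    return bytes(out)


def unpack_signed(data: bytes, count: int, width: int) -> np.ndarray:
    out = np.empty(count, dtype=np.int64)
    acc = 0
    nbits = 0
    pos = 0
    sign_bit = 1 << (width - 1)
    full = 1 << width
    for i in range(count):
        while nbits < width:
            if pos >= len(data):
                raise ContainerCorruptionError("truncated raw coefficient block")
            acc = (acc << 8) | data[pos]
            pos += 1
            nbits += 8
        nbits -= width
        u = (acc >> nbits) & (full - 1)
        out[i] = u - full if u & sign_bit else u
    return out


# ---------------------------------------------------------------------------
# predictor serialisation (the "nsi" side information)
# ---------------------------------------------------------------------------

def serialize_predictor(model: QuantizedPredictor) -> bytes:
    out = bytearray()
    out.append(PREDICTOR_KINDS.index(model.kind))
    out.append(model.order)
    out += struct.pack("<H", model.hidden)
    out += struct.pack("<b", model.input_scale_exp)
    out.append(model.weight_bits)
    out += struct.pack("<i", model.mean_offset)
    if model.kind == "nlms":
        out += struct.pack("<HHI", model.mu_num, model.mu_den, model.eps)
        return bytes(out)
    out.append(len(model.layers))
    for layer in model.layers:
        rows, cols = layer.weights.shape
        out += struct.pack("<HHbB", rows, cols, layer.scale_exp,
                           1 if layer.recurrent is not None else 0)
        out += layer.weights.astype("<i2").tobytes()
        out += layer.bias.astype("<i2").tobytes()
        if layer.recurrent is not None:
            out += layer.recurrent.astype("<i2").tobytes()
    return bytes(out)


def deserialize_predictor(data: bytes, clamp_abs: int) -> QuantizedPredictor:
    try:
        kind = PREDICTOR_KINDS[data[0]]
        order = data[1]
        (hidden,) = struct.unpack_from("<H", data, 2)
        (b,) = struct.unpack_from("<b", data, 4)
        j = data[5]
        (mean_offset,) = struct.unpack_from("<i", data, 6)
        pos = 10
        if kind == "nlms":
            mu_num, mu_den, eps = struct.unpack_from("<HHI", data, pos)
            return QuantizedPredictor(
                kind=kind, order=order, hidden=0, input_scale_exp=b,
                weight_bits=j, layers=[], clamp_abs=clamp_abs,
                mu_num=mu_num, mu_den=mu_den, eps=eps,
            )
        n_layers = data[pos]
        pos += 1
        layers = []
        for _ in range(n_layers):
            rows, cols, scale, has_rec = struct.unpack_from("<HHbB", data, pos)
            pos += 6
            W = np.frombuffer(data, dtype="<i2", count=rows * cols,
                              offset=pos).reshape(rows, cols).astype(np.int64)
            pos += 2 * rows * cols
            bias = np.frombuffer(data, dtype="<i2", count=rows,
                                 offset=pos).astype(np.int64)
            pos += 2 * rows
            rec = None
            if has_rec:
                rec = np.frombuffer(data, dtype="<i2", count=rows * rows,
                                    offset=pos).reshape(rows, rows).astype(np.int64)
                pos += 2 * rows * rows
            layers.append(LayerQ(weights=W, bias=bias, scale_exp=scale,
                                 recurrent=rec))
    except (IndexError, struct.error) as exc:
        raise ContainerCorruptionError(f"bad predictor section: {exc}") from exc
    return QuantizedPredictor(
        kind=kind, order=order, hidden=hidden, input_scale_exp=b,
        weight_bits=j, layers=layers, clamp_abs=clamp_abs,
        mean_offset=mean_offset,
    )


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class BlockData:
    """One compressed block: per-segment models, bias table, raw data, payload."""

    length: int
    eff_levels: int
    models: list                 # QuantizedPredictor | None per coding segment
    bias_table: BiasTable | None
    raw_values: np.ndarray       # concatenated raw prefixes, coding order
    payload: bytes


@dataclass
class CompressedContainer:
    fs_num: int
    fs_den: int
    bit_depth: int
    levels: int
    scheme: str
    bias_mode: str
    context_mode: str
    context_m: int
    original_length: int
    crc32: int
    blocks: list[BlockData]
    version: int = FORMAT_VERSION
    breakdown: object = field(default=None, compare=False, repr=False)

    @property
    def fs(self) -> float:
        return self.fs_num / self.fs_den

    @classmethod
    def fs_to_rational(cls, fs: float) -> tuple[int, int]:
        frac = Fraction(fs).limit_denominator(1_000_000)
        return frac.numerator, frac.denominator

    def to_bytes(self) -> bytes:
        out = bytearray(MAGIC)
        out.append(self.version)
        out += struct.pack(
            "<IIBBBBBBQI",
            self.fs_num, self.fs_den, self.bit_depth, self.levels,
            SCHEMES.index(self.scheme), BIAS_MODES.index(self.bias_mode),
            _CTX_MODES.index(self.context_mode), self.context_m,
            self.original_length, self.crc32,
        )
        out += struct.pack("<I", len(self.blocks))
        width = self.bit_depth + 4
        for blk in self.blocks:
            out += struct.pack("<IB", blk.length, blk.eff_levels)
            out.append(len(blk.models))
            for model in blk.models:
                if model is None:
                    out += struct.pack("<I", 0)
                    continue
                pred = serialize_predictor(model)
                out += struct.pack("<I", len(pred))
                out += pred
            if blk.bias_table is not None:
                tb = blk.bias_table
                out.append(1)
                out.append(_CTX_MODES.index(tb.config.mode))
                out.append(tb.config.m)
                out += np.asarray(tb.bias, dtype="<i2").tobytes()
            else:
                out.append(0)
            raw = pack_signed(blk.raw_values, width)
            out += struct.pack("<II", len(blk.raw_values), len(raw))
            out += raw
            out += struct.pack("<I", len(blk.payload))
            out += blk.payload
        return bytes(out)

    @classmethod
    def from_bytes(cls, data: bytes) -> "CompressedContainer":
        if len(data) < 5 or data[:4] != MAGIC:
            raise ContainerCorruptionError("bad magic: not an EWNZ container")
        if data[4] != FORMAT_VERSION:
            raise VersionError(
                f"unsupported format version {data[4]} (expected {FORMAT_VERSION})"
            )
        try:
            (fs_num, fs_den, bit_depth, levels, scheme_i, bias_i, ctx_mode_i,
             ctx_m, original_length, crc) = struct.unpack_from("<IIBBBBBBQI", data, 5)
            pos = 5 + struct.calcsize("<IIBBBBBBQI")
            (n_blocks,) = struct.unpack_from("<I", data, pos)
            pos += 4
            width = bit_depth + 4
            from .lifting import coefficient_bound  # avoid cycle at import
            clamp = coefficient_bound(bit_depth)
            blocks = []
            for _ in range(n_blocks):
                length, eff_levels = struct.unpack_from("<IB", data, pos)
                pos += 5
                n_models = data[pos]
                pos += 1
                models = []
                for _ in range(n_models):
                    (pred_len,) = struct.unpack_from("<I", data, pos)
                    pos += 4
                    if pred_len == 0:
                        models.append(None)
                        continue
                    models.append(
                        deserialize_predictor(data[pos : pos + pred_len], clamp)
                    )
                    pos += pred_len
                has_bias = data[pos]
                pos += 1
                table = None
                if has_bias:
                    mode = _CTX_MODES[data[pos]]
                    m = data[pos + 1]
                    pos += 2
                    nb = 1 << m
                    bias = np.frombuffer(data, dtype="<i2", count=nb,
                                         offset=pos).astype(np.int64)
                    pos += 2 * nb
                    cfgb = ContextConfig(m=m, mode=mode)
                    table = BiasTable(config=cfgb, bias=bias,
                                      counts=np.zeros(nb, dtype=np.int64))
                raw_count, raw_len = struct.unpack_from("<II", data, pos)
                pos += 8
                raw = unpack_signed(data[pos : pos + raw_len], raw_count, width)
                pos += raw_len
                (pl_len,) = struct.unpack_from("<I", data, pos)
                pos += 4
                payload = data[pos : pos + pl_len]
                if len(payload) != pl_len:
                    raise ContainerCorruptionError("truncated residue payload")
                pos += pl_len
                blocks.append(BlockData(length=length, eff_levels=eff_levels,
                                        models=models, bias_table=table,
                                        raw_values=raw, payload=payload))
        except (struct.error, IndexError) as exc:
            raise ContainerCorruptionError(f"truncated container: {exc}") from exc
        return cls(
            fs_num=fs_num, fs_den=fs_den, bit_depth=bit_depth, levels=levels,
            scheme=SCHEMES[scheme_i], bias_mode=BIAS_MODES[bias_i],
            context_mode=_CTX_MODES[ctx_mode_i], context_m=ctx_m,
            original_length=original_length, crc32=crc, blocks=blocks,
        )
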