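"""Combinational Lempel-Ziv + arithmetic entropy coding of residues.

The bias-corrected residues are serialised to bytes (zigzag map then
7-bit variable-length split), the byte stream is passed through an LZW
dictionary stage (initial alphabet 0..255, dictionary frozen at 2**16
entries), and the LZW code indices are entropy coded with an adaptive
order-0 arithmetic coder.  Every stage is bit-exact invertible and fully
specified in integer arithmetic, so payloads are portable.

Arithmetic coder format constants (fixed so payloads are portable):
32-bit range with E3 underflow handling, symbol frequencies start at 1,
increment by 32 per occurrence, and are halved (rounding up, so never
below 1) when the total exceeds 2**15.  A terminator symbol closes the
stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContainerCorruptionError, EmptyInputError, InvalidArgumentError
from .predictors import ResidualStream, SegmentResiduals

LZW_MAX_ENTRIES = 1 << 16
FREQ_INCREMENT = 32
FREQ_TOTAL_CAP = 1 << 15

_TOP = 1 << 32
_HALF = 1 << 31
_QUARTER = 1 << 30
_THREE_QUARTER = 3 << 30
_MASK = _TOP - 1


@dataclass
class SymbolStream:
    """Byte-alphabet symbols produced by residue serialisation."""

    symbols: list[int]
    alphabet_size: int = 256


@dataclass
class CodedPayload:
    """Entropy-coded bytes plus the counts needed for size accounting."""

    data: bytes
    bit_length: int
    symbol_count: int


# ---------------------------------------------------------------------------
# residue <-> byte symbols
# ---------------------------------------------------------------------------

def zigzag(v: int) -> int:
    """Fold signed integers onto non-negatives: 0,-1,1,-2,... -> 0,1,2,3,..."""
    return 2 * v if v >= 0 else -2 * v - 1


def unzigzag(u: int) -> int:
    return u // 2 if u % 2 == 0 else -(u + 1) // 2


def map_residues_to_symbols(residues) -> SymbolStream:
    """Zigzag + 7-bit continuation split; exactly invertible."""
    if isinstance(residues, ResidualStream):
        residues = residues.all_residues()
    out: list[int] = []
    for v in residues:
        u = zigzag(int(v))
        while u >= 0x80:
            out.append((u & 0x7F) | 0x80)
            u >>= 7
        out.append(u)
    return SymbolStream(symbols=out)


def map_symbols_to_residues(stream: SymbolStream) -> np.ndarray:
    """Inverse of :func:`map_residues_to_symbols`."""
    res: list[int] = []
    u = 0
    shift = 0
    for b in stream.symbols:
        if b & 0x80:
            u |= (b & 0x7F) << shift
            shift += 7
        else:
            u |= b << shift
            res.append(unzigzag(u))
            u = 0
            shift = 0
    if shift != 0:
        raise ContainerCorruptionError("truncated varint in residue stream")
    return np.asarray(res, dtype=np.int64)


# ---------------------------------------------------------------------------
# LZW dictionary stage
# ---------------------------------------------------------------------------

def lzw_encode(stream: SymbolStream) -> list[int]:
    """Greedy LZW over a 256-symbol alphabet, dictionary frozen at 2**16."""
    if stream.alphabet_size != 256:
        raise InvalidArgumentError("LZW stage expects a byte alphabet")
    syms = stream.symbols
    if not syms:
        return []
    table: dict[tuple[int, int], int] = {}
    next_code = 256
    codes: list[int] = []
    cur = syms[0]
    for s in syms[1:]:
        key = (cur, s)
        code = table.get(key)
        if code is not None:
            cur = code
        else:
            codes.append(cur)
            if next_code < LZW_MAX_ENTRIES:
                table[key] = next_code
                next_code += 1
            cur = s
    codes.append(cur)
    return codes


def lzw_decode(codes: list[int]) -> SymbolStream:
    """Inverse of :func:`lzw_encode`, incl. the self-referential code case."""
    if not codes:
        return SymbolStream(symbols=[])
    entries: list[bytes] = [bytes([i]) for i in range(256)]
    prev = codes[0]
    if prev >= 256:
        raise ContainerCorruptionError("first LZW code must be a literal")
    out = bytearray(entries[prev])
    for code in codes[1:]:
        if code < len(entries):
            entry = entries[code]
        elif code == len(entries) and code < LZW_MAX_ENTRIES:
            entry = entries[prev] + entries[prev][:1]
        else:
            raise ContainerCorruptionError(f"LZW code {code} beyond dictionary")
        out += entry
        if len(entries) < LZW_MAX_ENTRIES:
            entries.append(entries[prev] + entry[:1])
        prev = code
    return SymbolStream(symbols=list(out))


# ---------------------------------------------------------------------------
# adaptive order-0 arithmetic coder
# ---------------------------------------------------------------------------

class _Fenwick:
    """Cumulative frequency tree for the adaptive model."""

    def __init__(self, n: int):
        self.n = n
        self.tree = [0] * (n + 1)

    def add(self, i: int, delta: int) -> None:
        i += 1
        while i <= self.n:
            self.tree[i] += delta
            i += i & (-i)

    def cumsum(self, i: int) -> int:
        """Sum of frequencies of symbols < i."""
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return s

    def find(self, target: int) -> int:
        """Largest index with cumsum(index) <= target."""
        idx = 0
        bit = 1 << (self.n.bit_length())
        while bit:
            nxt = idx + bit
            if nxt <= self.n and self.tree[nxt] <= target:
                idx = nxt
                target -= self.tree[nxt]
            bit >>= 1
        return idx


class _AdaptiveModel:
    def __init__(self, alphabet: int):
        self.alphabet = alphabet
        self.freq = [1] * alphabet
        self.total = alphabet
        self.fen = _Fenwick(alphabet)
        for i in range(alphabet):
            self.fen.add(i, 1)

    def interval(self, sym: int) -> tuple[int, int, int]:
        lo = self.fen.cumsum(sym)
        return lo, lo + self.freq[sym], self.total

    def locate(self, scaled: int) -> int:
        return self.fen.find(scaled)

    def update(self, sym: int) -> None:
        self.freq[sym] += FREQ_INCREMENT
        self.total += FREQ_INCREMENT
        self.fen.add(sym, FREQ_INCREMENT)
        if self.total > FREQ_TOTAL_CAP:
            self._rescale()

    def _rescale(self) -> None:
        self.freq = [(f + 1) >> 1 for f in self.freq]
        self.total = sum(self.freq)
        self.fen = _Fenwick(self.alphabet)
        for i, f in enumerate(self.freq):
            self.fen.add(i, f)


class _BitWriter:
    def __init__(self):
        self.buf = bytearray()
        self.acc = 0
        self.nbits = 0
        self.bit_count = 0

    def put(self, bit: int) -> None:
        self.acc = (self.acc << 1) | bit
        self.nbits += 1
        self.bit_count += 1
        if self.nbits == 8:
            self.buf.append(self.acc)
            self.acc = 0
            self.nbits = 0

    def bytes(self) -> bytes:
        if self.nbits:
            return bytes(self.buf) + bytes([self.acc << (8 - self.nbits)])
        return bytes(self.buf)


class _BitReader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def get(self) -> int:
        byte_i, bit_i = divmod(self.pos, 8)
        self.pos += 1
        if byte_i >= len(self.data):
            return 0  # zero padding past the payload end
        return (self.data[byte_i] >> (7 - bit_i)) & 1


def arith_encode(codes, max_code: int) -> CodedPayload:
    """Adaptive order-0 arithmetic coding of integer codes <= max_code."""
    alphabet = max_code + 2       # +1 values, + terminator
    terminator = max_code + 1
    model = _AdaptiveModel(alphabet)
    w = _BitWriter()
    low, high = 0, _MASK
    pending = 0

    def emit(bit: int):
        nonlocal pending
        w.put(bit)
        while pending:
            w.put(1 - bit)
            pending -= 1

    for sym in list(codes) + [terminator]:
        if not (0 <= sym < alphabet):
            raise InvalidArgumentError(f"code {sym} exceeds max_code {max_code}")
        c_lo, c_hi, total = model.interval(sym)
        span = high - low + 1
        high = low + span * c_hi // total - 1
        low = low + span * c_lo // total
        while True:
            if high < _HALF:
                emit(0)
            elif low >= _HALF:
                emit(1)
                low -= _HALF
                high -= _HALF
            elif low >= _QUARTER and high < _THREE_QUARTER:
                pending += 1
                low -= _QUARTER
                high -= _QUARTER
            else:
                break
            low = (low << 1) & _MASK
            high = ((high << 1) | 1) & _MASK
        model.update(sym)

    pending += 1
    emit(0 if low < _QUARTER else 1)
    return CodedPayload(data=w.bytes(), bit_length=w.bit_count,
                        symbol_count=len(codes))


def arith_decode(payload: CodedPayload, max_code: int) -> list[int]:
    """Exact inverse of :func:`arith_encode`."""
    alphabet = max_code + 2
    terminator = max_code + 1
    model = _AdaptiveModel(alphabet)
    r = _BitReader(payload.data)
    value = 0
    for _ in range(32):
        value = (value << 1) | r.get()
    low, high = 0, _MASK
    out: list[int] = []
    while True:
        span = high - low + 1
        total = model.total
        scaled = ((value - low + 1) * total - 1) // span
        sym = model.locate(scaled)
        c_lo, c_hi, total = model.interval(sym)
        high = low + span * c_hi // total - 1
        low = low + span * c_lo // total
        while True:
            if high < _HALF:
                pass
            elif low >= _HALF:
                low -= _HALF
                high -= _HALF
                value -= _HALF
            elif low >= _QUARTER and high < _THREE_QUARTER:
                low -= _QUARTER
                high -= _QUARTER
                value -= _QUARTER
            else:
                break
            low = (low << 1) & _MASK
            high = ((high << 1) | 1) & _MASK
            value = ((value << 1) | r.get()) & _MASK
        model.update(sym)
        if sym == terminator:
            break
        out.append(sym)
        if len(out) > (payload.symbol_count or 1 << 62):
            raise ContainerCorruptionError("arithmetic stream overran")
    if payload.symbol_count and len(out) != payload.symbol_count:
        raise ContainerCorruptionError("arithmetic stream symbol count mismatch")
    return out


# ---------------------------------------------------------------------------
# LZARIC composition
# ---------------------------------------------------------------------------

def _write_varint(out: bytearray, u: int) -> None:
    while u >= 0x80:
        out.append((u & 0x7F) | 0x80)
        u >>= 7
    out.append(u)


def _read_varint(data: bytes, pos: int) -> tuple[int, int]:
    u = 0
    shift = 0
    while True:
        if pos >= len(data):
            raise ContainerCorruptionError("truncated varint")
        b = data[pos]
        pos += 1
        u |= (b & 0x7F) << shift
        shift += 7
        if not (b & 0x80):
            return u, pos


def encode_residues(residues) -> bytes:
    """Full LZARIC pipeline on a flat residue sequence -> payload bytes.

    Layout: [byte_count varint][max_code varint][arith bytes].
    """
    syms = map_residues_to_symbols(residues)
    codes = lzw_encode(syms)
    max_code = max(codes) if codes else 0
    payload = arith_encode(codes, max_code)
    out = bytearray()
    _write_varint(out, len(syms.symbols))
    _write_varint(out, max_code)
    out += payload.data
    return bytes(out)


def decode_residues(data: bytes) -> np.ndarray:
    """Inverse of :func:`encode_residues`."""
    byte_count, pos = _read_varint(data, 0)
    max_code, pos = _read_varint(data, pos)
    if byte_count == 0:
        return np.zeros(0, dtype=np.int64)
    payload = CodedPayload(data=data[pos:], bit_length=8 * (len(data) - pos),
                           symbol_count=0)
    codes = arith_decode(payload, max_code)
    syms = lzw_decode(codes)
    if len(syms.symbols) != byte_count:
        raise ContainerCorruptionError("decoded byte count mismatch")
    return map_symbols_to_residues(syms)


def lzaric(res: ResidualStream) -> CodedPayload:
    """Encode a residual stream; payload bytes include the LZARIC header."""
    data = encode_residues(res)
    return CodedPayload(data=data, bit_length=8 * len(data),
                        symbol_count=res.residue_count())


def lzaric_inverse(payload: CodedPayload) -> ResidualStream:
    """Decode to a flat single-segment residual stream (no raw prefix)."""
    residues = decode_residues(payload.data)
    if payload.symbol_count and len(residues) != payload.symbol_count:
        raise ContainerCorruptionError("residue count mismatch")
    return ResidualStream(order=0, segments=[
        SegmentResiduals(raw=np.zeros(0, dtype=np.int64), residues=residues)
    ])
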