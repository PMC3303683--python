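"""Compression performance measures: CR, BPS, CE, efficiency percentage.

The compression ratio is the original bit count over the transmitted bit
count,

    CR = v*n / (p*n' + w*j + r*k + ...),

where v is the sample count, n the bits per original sample, the p*n'
term the raw (unpredicted) leading coefficients, w*j the transmitted
predictor parameters (w parameters at j bits each), r*k the entropy-coded
residue payload, plus the bias table and container framing, so that CR
cross-checks exactly against the on-disk container size.  BPS is the
compressed bits per original sample (BPS = n/CR), compression efficiency
is 100*(1 - 1/CR), and computational efficiency CE = CR / processing
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidArgumentError


@dataclass
class SizeBreakdown:
    """Bit accounting of one compression run."""

    v: int                       # total samples in the test signal
    n: int                       # bits per original sample
    p: int                       # predictor order
    raw_header_bits: int = 0     # leading raw coefficients, n+4 bits each
    side_info_bits: int = 0      # transmitted parameters x j bits
    bias_table_bits: int = 0     # transmitted context offsets
    payload_bits: int = 0        # entropy-coded residue payload
    overhead_bits: int = 0       # container framing (magic, header, lengths)
    r: int = 0                   # residue count
    processing_time_s: float = 0.0

    def __post_init__(self):
        for name in ("v", "n", "raw_header_bits", "side_info_bits",
                     "bias_table_bits", "payload_bits", "overhead_bits", "r"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.r > self.v:
            raise InvalidArgumentError("residue count cannot exceed sample count")

    @property
    def total_bits(self) -> int:
        return (self.raw_header_bits + self.side_info_bits
                + self.bias_table_bits + self.payload_bits + self.overhead_bits)

    def merged(self, other: "SizeBreakdown") -> "SizeBreakdown":
        """Accumulate a per-block breakdown into a whole-signal one."""
        return SizeBreakdown(
            v=self.v + other.v, n=self.n, p=max(self.p, other.p),
            raw_header_bits=self.raw_header_bits + other.raw_header_bits,
            side_info_bits=self.side_info_bits + other.side_info_bits,
            bias_table_bits=self.bias_table_bits + other.bias_table_bits,
            payload_bits=self.payload_bits + other.payload_bits,
            overhead_bits=self.overhead_bits + other.overhead_bits,
            r=self.r + other.r,
            processing_time_s=self.processing_time_s + other.processing_time_s,
        )


def compression_ratio(sb: SizeBreakdown) -> float:
    """CR = original bits / compressed bits."""
    denom = sb.total_bits
    if denom <= 0:
        raise InvalidArgumentError("compressed size must be positive")
    return sb.v * sb.n / denom


def bits_per_sample(sb: SizeBreakdown) -> float:
    """BPS = compressed bits / sample; satisfies BPS = n / CR."""
    if sb.v <= 0:
        raise InvalidArgumentError("sample count must be positive")
    return sb.total_bits / sb.v


def computational_efficiency(cr: float, pt_seconds: float) -> float:
    """CE = CR / processing time (1/s)."""
    if pt_seconds <= 0:
        raise InvalidArgumentError("processing time must be positive")
    return cr / pt_seconds


def compression_efficiency_pct(cr: float) -> float:
    """Space saving as a percentage: 100 * (1 - 1/CR)."""
    if cr <= 0:
        raise InvalidArgumentError("compression ratio must be positive")
    return 100.0 * (1.0 - 1.0 / cr)


@dataclass
class EvalReport:
    """Rows of per-configuration results plus dataset-mean aggregation."""

    rows: list[dict] = field(default_factory=list)

    def add(self, config: str, sb: SizeBreakdown, **extra) -> dict:
        cr = compression_ratio(sb)
        row = {
            "config": config,
            "v": sb.v,
            "n": sb.n,
            "cr": cr,
            "bps": bits_per_sample(sb),
            "efficiency_pct": compression_efficiency_pct(cr),
            "raw_header_bits": sb.raw_header_bits,
            "side_info_bits": sb.side_info_bits,
            "bias_table_bits": sb.bias_table_bits,
            "payload_bits": sb.payload_bits,
            "overhead_bits": sb.overhead_bits,
            "total_bits": sb.total_bits,
            "processing_time_s": sb.processing_time_s,
        }
        row.update(extra)
        self.rows.append(row)
        return row

    def mean(self, key: str) -> float:
        """Mean of one column over all rows (the DS1-DS5 average)."""
        if not self.rows:
            raise InvalidArgumentError("report is empty")
        return sum(r[key] for r in self.rows) / len(self.rows)

    def to_delimited(self, sep: str = "\t") -> str:
        if not self.rows:
            return ""
        keys = list(self.rows[0].keys())
        lines = [sep.join(keys)]
        for r in self.rows:
            lines.append(sep.join(
                f"{r[k]:.6g}" if isinstance(r[k], float) else str(r[k])
                for k in keys
            ))
        return "\n".join(lines) + "\n"
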