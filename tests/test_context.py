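import numpy as np
import pytest

from eegcodec import (
    BiasTable,
    ContextConfig,
    InvalidArgumentError,
    UnsupportedModeError,
    apply_bias_cancellation,
    build_bias_table,
    context_index,
    remove_bias_cancellation,
)
from eegcodec.predictors import ResidualStream, SegmentResiduals


def make_stream(coeffs, raw_n, residues):
    seg = SegmentResiduals(raw=np.asarray(coeffs[:raw_n], dtype=np.int64),
                           residues=np.asarray(residues, dtype=np.int64))
    return ResidualStream(order=raw_n, segments=[seg])


def entropy(v):
    _, c = np.unique(np.asarray(v), return_counts=True)
    p = c / c.sum()
    return float(-(p * np.log2(p)).sum())


class TestContextIndex:
    def test_symmetric_negative_difference_gives_zero_bit(self):
        # d_1 = x[k+1] - x[k-1] = 4 - 5 < 0 -> bit 0 -> index 0
        x = [0, 5, 9, 4, 0]
        assert context_index(x, 2, ContextConfig(m=1, mode="symmetric")) == 0

    def test_causal_bit_packing(self):
        # past ..., 2, 3, 5 before k: d_1 = 5-3 >= 0, d_2 = 3-2 >= 0 -> index 3
        x = [2, 3, 5, 0]
        assert context_index(x, 3, ContextConfig(m=2, mode="causal")) == 3

    def test_tie_at_zero_quantises_to_one(self):
        x = [5, 5, 0]
        assert context_index(x, 2, ContextConfig(m=1, mode="causal")) == 1

    def test_m5_produces_32_distinct_contexts(self, rng):
        cfg = ContextConfig(m=5, mode="causal")
        x = rng.integers(-100, 100, size=5000)
        seen = {context_index(x, k, cfg) for k in range(6, len(x))}
        assert seen == set(range(32))

    def test_window_violations_map_to_reserved_context(self):
        cfg = ContextConfig(m=3, mode="causal")
        assert context_index([1, 2, 3, 4, 5], 2, cfg) == 0

    def test_out_of_range_position_rejected(self):
        with pytest.raises(InvalidArgumentError):
            context_index([1, 2, 3], 5, ContextConfig(m=1))

    def test_context_count_sweep_mapping(self):
        for m, count in [(2, 4), (3, 8), (4, 16), (5, 32), (8, 256)]:
            assert ContextConfig(m=m).context_count == count


class TestBiasTable:
    def test_constant_residues_fully_cancelled(self):
        coeffs = np.arange(20)  # increasing -> one causal context
        res = make_stream(coeffs, 2, [7] * 18)
        cfg = ContextConfig(m=1, mode="causal")
        table = build_bias_table(coeffs, res, cfg)
        corrected = apply_bias_cancellation(res, table, coeffs)
        assert np.all(corrected.all_residues() == 0)

    def test_symmetric_residues_give_zero_bias(self):
        coeffs = np.arange(22)
        res = make_stream(coeffs, 2, [4, -4] * 10)
        table = build_bias_table(coeffs, res, ContextConfig(m=1, mode="causal"))
        assert np.all(table.bias == 0)

    def test_empty_contexts_get_zero_bias(self):
        coeffs = np.arange(10)
        res = make_stream(coeffs, 2, [1] * 8)
        table = build_bias_table(coeffs, res, ContextConfig(m=2, mode="causal"))
        assert table.bias[table.counts == 0].tolist() == [0] * int(
            (table.counts == 0).sum()
        )

    def test_offset_injection_recovery(self, rng):
        """Per-context offsets are recovered within 1 LSB and cancellation
        zeroes the per-context mean and does not raise entropy."""
        cfg = ContextConfig(m=2, mode="causal")
        offsets = {0: -6, 1: -2, 2: 3, 3: 9}
        n = 40_000
        coeffs = rng.integers(-300, 300, size=n)
        res_vals = np.zeros(n - 5, dtype=np.int64)
        stream = make_stream(coeffs, 5, res_vals)
        from eegcodec.context import residual_contexts

        ctx = residual_contexts(coeffs, stream, cfg)
        lap = np.rint(rng.laplace(0.0, 4.0, size=len(ctx))).astype(np.int64)
        res_vals[:] = lap + np.vectorize(offsets.get)(ctx)
        stream = make_stream(coeffs, 5, res_vals)

        table = build_bias_table(coeffs, stream, cfg)
        for c, mu in offsets.items():
            assert abs(int(table.bias[c]) - mu) <= 1
        corrected = apply_bias_cancellation(stream, table, coeffs)
        e = corrected.all_residues()
        for c in offsets:
            assert abs(float(e[ctx == c].mean())) <= 0.5
        assert entropy(e) <= entropy(res_vals)


class TestInvertibility:
    def test_zero_bias_is_identity(self):
        coeffs = np.arange(30)
        res = make_stream(coeffs, 3, list(range(27)))
        cfg = ContextConfig(m=2, mode="causal")
        table = BiasTable(config=cfg, bias=np.zeros(4, dtype=np.int64),
                          counts=np.zeros(4, dtype=np.int64))
        out = apply_bias_cancellation(res, table, coeffs)
        assert np.array_equal(out.all_residues(), res.all_residues())

    def test_remove_inverts_apply_on_random_data(self, rng):
        coeffs = rng.integers(-500, 500, size=1000)
        res = make_stream(coeffs, 5, rng.integers(-50, 50, size=995))
        cfg = ContextConfig(m=4, mode="causal")
        table = build_bias_table(coeffs, res, cfg)
        corrected = apply_bias_cancellation(res, table, coeffs)
        restored = remove_bias_cancellation(corrected, table, coeffs)
        assert np.array_equal(restored.all_residues(), res.all_residues())

    def test_symmetric_mode_not_decodable(self):
        coeffs = np.arange(30)
        res = make_stream(coeffs, 3, [1] * 27)
        cfg = ContextConfig(m=2, mode="symmetric")
        table = build_bias_table(coeffs, res, cfg)
        with pytest.raises(UnsupportedModeError):
            remove_bias_cancellation(res, table, coeffs)

    def test_zero_length_residual_stream(self):
        coeffs = np.arange(3)
        res = make_stream(coeffs, 3, [])
        cfg = ContextConfig(m=2, mode="causal")
        table = build_bias_table(coeffs, res, cfg)
        out = remove_bias_cancellation(
            apply_bias_cancellation(res, table, coeffs), table, coeffs)
        assert len(out.all_residues()) == 0
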