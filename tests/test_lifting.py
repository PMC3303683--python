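import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eegcodec import (
    EmptyInputError,
    InvalidArgumentError,
    SubbandSet,
    coefficient_bound,
    dwt_multilevel,
    idwt_multilevel,
    lift_forward_53,
    lift_inverse_53,
)


def reference_lift_53(x):
    """Independent oracle: the two lifting equations applied index by index
    with explicit whole-sample symmetric mirroring."""
    n = len(x)

    def xs(i):  # x with mirrored boundaries
        if i < 0:
            return x[-i]
        if i >= n:
            return x[2 * n - 2 - i]
        return x[i]

    n_det = n // 2
    n_app = (n + 1) // 2
    detail = [
        xs(2 * k + 1) - ((xs(2 * k) + xs(2 * k + 2)) // 2) for k in range(n_det)
    ]

    def ds(k):  # detail with mirrored indices
        if k < 0:
            return detail[-k - 1]
        if k >= n_det:
            return detail[2 * n_det - 1 - k]
        return detail[k]

    approx = [xs(2 * k) + ((ds(k - 1) + ds(k) + 2) // 4) for k in range(n_app)]
    return approx, detail


signals = st.lists(st.integers(-2048, 2047), min_size=2, max_size=300)


class TestSingleLevel:
    def test_constant_annihilated(self):
        a, d = lift_forward_53([10] * 5)
        assert d.tolist() == [0, 0] and a.tolist() == [10, 10, 10]

    def test_linear_ramp_annihilated(self):
        _, d = lift_forward_53([0, 1, 2, 3, 4])
        assert d.tolist() == [0, 0]

    def test_matches_index_by_index_oracle(self):
        x = [7, 3, -2, 5, 11, 0]
        a, d = lift_forward_53(x)
        a_ref, d_ref = reference_lift_53(x)
        assert a.tolist() == a_ref and d.tolist() == d_ref

    @given(signals)
    def test_oracle_agreement_on_random_inputs(self, x):
        a, d = lift_forward_53(x)
        a_ref, d_ref = reference_lift_53(x)
        assert a.tolist() == a_ref and d.tolist() == d_ref

    @given(signals)
    def test_perfect_reconstruction(self, x):
        a, d = lift_forward_53(x)
        assert lift_inverse_53(a, d, len(x)).tolist() == x

    def test_too_short_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            lift_forward_53([5])

    def test_inverse_rejects_mismatched_lengths(self):
        with pytest.raises(InvalidArgumentError):
            lift_inverse_53([5], [], 1)


class TestMultiLevel:
    def test_dyadic_bookkeeping_len16(self):
        sb = dwt_multilevel(np.arange(16), levels=4)
        assert [len(d) for d in sb.details] == [8, 4, 2, 1]
        assert len(sb.approx) == 1

    def test_ceil_floor_convention_len21(self):
        sb = dwt_multilevel(np.arange(21), levels=1)
        assert len(sb.approx) == 11 and len(sb.details[0]) == 10

    def test_short_input_reduces_levels_and_inverts(self):
        x = np.array([3, -7, 12, 0, 5, 9])
        sb = dwt_multilevel(x, levels=4)
        assert sb.levels < 4
        assert np.array_equal(idwt_multilevel(sb), x)

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            dwt_multilevel(np.array([], dtype=int), levels=4)

    def test_corrupted_subband_lengths_rejected(self):
        sb = dwt_multilevel(np.arange(32), levels=4)
        bad = SubbandSet(levels=sb.levels, details=sb.details,
                         approx=sb.approx[:-1], original_length=33)
        with pytest.raises(InvalidArgumentError):
            idwt_multilevel(bad)

    def test_identity_on_constant(self):
        x = np.full(100, 42)
        assert np.array_equal(idwt_multilevel(dwt_multilevel(x, 4)), x)

    def test_round_trip_random_batch(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 400))
            x = rng.integers(-2048, 2048, size=n)
            sb = dwt_multilevel(x, 4)
            assert np.array_equal(idwt_multilevel(sb), x)

    def test_coefficient_magnitude_bound(self, rng):
        bound = coefficient_bound(12)
        for _ in range(50):
            x = rng.integers(-2048, 2048, size=int(rng.integers(16, 2000)))
            sb = dwt_multilevel(x, 4)
            worst = max(int(np.abs(s).max()) for s in sb.segments())
            assert worst <= bound
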