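import numpy as np
import pytest

from eegcodec import (
    InvalidArgumentError,
    NLMSFilter,
    PredictorSpec,
    QuantizedPredictor,
    SubbandSet,
    coefficient_bound,
    compute_residuals,
    dwt_multilevel,
    fit_ar_levinson,
    levinson_durbin,
    nlms_residuals,
    predict_next,
    reconstruct_coeffs,
    train_predictor,
)
from eegcodec.fixedpoint import ACT_FRAC_BITS
from eegcodec.predictors import LayerQ


def flat_subbands(x):
    x = np.asarray(x, dtype=np.int64)
    return SubbandSet(levels=0, details=[], approx=x, original_length=len(x))


def copy_predictor(p=2, scale=14):
    """w = (1, 0, ..., 0): prediction equals the previous sample."""
    w = np.zeros((1, p), dtype=np.int64)
    w[0, 0] = 1 << scale
    layer = LayerQ(weights=w, bias=np.zeros(1, dtype=np.int64), scale_exp=scale)
    return QuantizedPredictor(kind="slp", order=p, hidden=0, input_scale_exp=4,
                              weight_bits=16, layers=[layer],
                              clamp_abs=coefficient_bound(12))


def entropy(v):
    _, c = np.unique(np.asarray(v), return_counts=True)
    p = c / c.sum()
    return float(-(p * np.log2(p)).sum())


class TestFixedPointInference:
    def test_copy_predictor_returns_previous_sample(self):
        m = copy_predictor()
        assert predict_next(m, [3, 9]) == 9
        assert predict_next(m, [-7, -12]) == -12

    def test_zero_weights_predict_zero(self):
        m = copy_predictor()
        m.layers[0].weights[:] = 0
        assert predict_next(m, [123, -456]) == 0

    def test_window_length_checked(self):
        with pytest.raises(InvalidArgumentError):
            predict_next(copy_predictor(p=2), [1, 2, 3])

    def test_matches_independent_scalar_evaluation(self, rng):
        """Integer inference equals a from-scratch re-evaluation of the
        fixed-point contract (independent arithmetic path)."""
        for _ in range(25):
            p = int(rng.integers(1, 8))
            s = int(rng.integers(8, 18))
            W = rng.integers(-30000, 30000, size=(1, p))
            bias = rng.integers(-30000, 30000, size=1)
            layer = LayerQ(weights=W, bias=bias, scale_exp=s)
            b = int(rng.integers(0, 12))
            m = QuantizedPredictor(kind="slp", order=p, hidden=0,
                                   input_scale_exp=b, weight_bits=16,
                                   layers=[layer], clamp_abs=1 << 40)
            window = [int(v) for v in rng.integers(-2048, 2048, size=p)]

            def rhalf(v, k):
                if k <= 0:
                    return v << -k
                h = 1 << (k - 1)
                return (v + h) >> k if v >= 0 else -((-v + h) >> k)

            acc = int(bias[0]) << ACT_FRAC_BITS
            for i in range(p):
                u = rhalf(window[-(i + 1)] << ACT_FRAC_BITS, b)
                acc += int(W[0, i]) * u
            expected = rhalf(rhalf(acc, s) << b, ACT_FRAC_BITS)
            assert predict_next(m, window) == expected


class TestTraining:
    def test_constant_stream_slp_residues_are_zero(self):
        const = np.full(500, 1000, dtype=np.int64)
        model = train_predictor(const, PredictorSpec(kind="slp", order=5, seed=0))
        res = compute_residuals(model, flat_subbands(const))
        assert np.all(res.all_residues() == 0)

    def test_training_is_seed_deterministic(self, short_eeg):
        sb = dwt_multilevel(short_eeg.samples, 4)
        spec = PredictorSpec(kind="mlp", order=5, seed=9)
        m1, m2 = train_predictor(sb, spec), train_predictor(sb, spec)
        for l1, l2 in zip(m1.layers, m2.layers):
            assert np.array_equal(l1.weights, l2.weights)
            assert np.array_equal(l1.bias, l2.bias)
            assert l1.scale_exp == l2.scale_exp

    def test_lm_training_log_never_ends_above_start(self, short_eeg):
        sb = dwt_multilevel(short_eeg.samples, 4)
        model = train_predictor(sb.details[0],
                                PredictorSpec(kind="slp", order=5, seed=1))
        assert model.training_log[-1] <= model.training_log[0]

    def test_stream_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            train_predictor(np.arange(4), PredictorSpec(kind="slp", order=5))

    def test_hidden_sizes_paired_with_order(self):
        assert PredictorSpec(kind="mlp", order=10).hidden == 8
        assert PredictorSpec(kind="elman", order=20).hidden == 16


class TestLevinsonDurbin:
    def test_yule_walker_closed_form(self):
        a = levinson_durbin([1.0, 0.5], 1)
        assert a[0] == pytest.approx(0.5, abs=1e-12)

    def test_white_noise_gives_near_zero_coefficients(self, rng):
        x = rng.integers(-500, 500, size=100_000)
        m = fit_ar_levinson(x, 5)
        a = m.layers[0].weights[0] / 2.0 ** m.layers[0].scale_exp
        assert np.abs(a).max() < 0.05

    def test_recovers_ar5_coefficients(self, rng):
        true = np.array([0.5, -0.3, 0.2, -0.1, 0.05])
        n = 100_000
        x = np.zeros(n)
        e = rng.standard_normal(n) * 10
        for t in range(5, n):
            x[t] = true @ x[t - 5 : t][::-1] + e[t]
        m = fit_ar_levinson(np.rint(x).astype(np.int64), 5)
        a = m.layers[0].weights[0] / 2.0 ** m.layers[0].scale_exp
        assert np.abs(a - true).max() < 0.05

    def test_agrees_with_statsmodels_recursion(self, rng):
        from statsmodels.tsa.stattools import levinson_durbin as sm_ld

        x = rng.standard_normal(5000).cumsum()
        r = [float(np.dot(x[: len(x) - k], x[k:]) / len(x)) for k in range(6)]
        ours = levinson_durbin(r, 5)
        _, arcoefs, *_ = sm_ld(np.asarray(r), nlags=5, isacov=True)
        assert np.allclose(ours, arcoefs, atol=1e-10)

    def test_zero_variance_stream_flagged(self):
        m = fit_ar_levinson(np.full(100, 7), 5)
        assert "zero-variance" in m.flags
        assert np.all(m.layers[0].weights == 0)
        assert m.mean_offset == 7


class TestNLMS:
    def test_constant_stream_residues_reach_zero(self):
        res = nlms_residuals(np.full(400, 700), order=5)
        assert np.all(res.all_residues()[-100:] == 0)

    def test_mu_zero_rejected(self):
        with pytest.raises(InvalidArgumentError):
            nlms_residuals(np.arange(100), order=5, mu=0.0)
        with pytest.raises(InvalidArgumentError):
            NLMSFilter(5, 0, 2, 1, 100)

    def test_prediction_gain_on_ar1(self, rng):
        n = 10_000
        x = np.zeros(n)
        e = rng.standard_normal(n) * 20
        for t in range(1, n):
            x[t] = 0.9 * x[t - 1] + e[t]
        xi = np.rint(x).astype(np.int64)
        res = nlms_residuals(xi, order=5).all_residues()
        gain = np.var(xi.astype(float)) / np.var(res.astype(float))
        assert gain > 1.0


class TestLosslessChain:
    @pytest.mark.parametrize("kind", ["slp", "mlp", "elman", "ar", "nlms"])
    def test_reconstruct_inverts_compute_residuals(self, kind, short_eeg):
        sb = dwt_multilevel(short_eeg.samples, 4)
        model = train_predictor(sb, PredictorSpec(kind=kind, order=5, seed=1),
                                clamp_abs=coefficient_bound(12))
        res = compute_residuals(model, sb)
        back = reconstruct_coeffs(res, model, sb_template=sb)
        for a, b in zip(sb.segments(), back.segments()):
            assert np.array_equal(a, b)

    def test_zero_predictor_residues_equal_coefficients(self):
        m = copy_predictor()
        m.layers[0].weights[:] = 0
        x = np.array([5, 7, -3, 11, 2], dtype=np.int64)
        res = compute_residuals(m, flat_subbands(x))
        assert res.segments[0].raw.tolist() == [5, 7]
        assert res.segments[0].residues.tolist() == [-3, 11, 2]

    def test_copy_predictor_on_constant_subband(self):
        m = copy_predictor()
        res = compute_residuals(m, flat_subbands([5, 5, 5, 5]))
        assert res.segments[0].raw.tolist() == [5, 5]
        assert res.segments[0].residues.tolist() == [0, 0]

    def test_copy_predictor_reduces_entropy_of_smooth_stream(self, rng):
        # a slow random walk is first-difference predictable
        steps = rng.integers(-2, 3, size=3000)
        x = np.clip(np.cumsum(steps), -2000, 2000).astype(np.int64)
        res = compute_residuals(copy_predictor(), flat_subbands(x))
        assert entropy(res.all_residues()) <= entropy(x)
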