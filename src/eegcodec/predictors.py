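"""Prediction of wavelet coefficients: neural networks and linear models.

Each coefficient x_k is predicted from its ``p`` predecessors within the
same subband segment,

    x_hat_k = f( sum_{i=1..p} w_i * x_{k-i} ),

and only the residue e_k = x_k - x_hat_k is entropy coded.  Five
predictor kinds are supported:

``slp``
    single-layer perceptron (linear, trained with Levenberg-Marquardt);
``mlp``
    one tanh hidden layer (Levenberg-Marquardt), hidden sizes 1/3/8/12
    paired with orders 2/5/10/20;
``elman``
    recurrent hidden layer with state feedback (gradient descent with
    momentum and adaptive learning rate), hidden sizes 1/5/8/16;
``ar``
    fifth-order autoregressive model fitted by Levinson-Durbin on biased
    autocorrelation estimates;
``nlms``
    fifth-order normalised-LMS adaptive FIR that adapts symmetrically
    from reconstructed samples only, so no weights are transmitted.

Training happens in float on inputs scaled by 2**-b (b the smallest
exponent covering the coefficient range); trained weights are quantised
to ``j``-bit fixed point and *all inference is integer-only*
(:mod:`eegcodec.fixedpoint`), so encoder and decoder predictions are
bit-identical on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from . import fixedpoint as fp
from .errors import InvalidArgumentError, TrainingFailureError
from .lifting import SubbandSet

PREDICTOR_KINDS = ("slp", "mlp", "elman", "ar", "nlms")

#: hidden-layer sizes paired with predictor order
MLP_HIDDEN = {2: 1, 5: 3, 10: 8, 20: 12}
ELMAN_HIDDEN = {2: 1, 5: 5, 10: 8, 20: 16}

_DEFAULT_EPOCHS = {"slp": 50, "mlp": 50, "elman": 30}

#: fractional bits of the NLMS weight accumulator
NLMS_FRAC_BITS = 16


@dataclass
class PredictorSpec:
    """Configuration of one predictor (kind, order, training knobs)."""

    kind: str = "slp"
    order: int = 5
    hidden: int | None = None
    epochs: int | None = None
    seed: int = 0
    weight_bits: int = fp.DEFAULT_WEIGHT_BITS
    # nlms adaptation parameters
    mu: float = 0.5
    eps: int = 1
    # elman gradient-descent parameters
    learning_rate: float = 0.01
    momentum: float = 0.9

    def __post_init__(self):
        if self.kind not in PREDICTOR_KINDS:
            raise InvalidArgumentError(f"unknown predictor kind {self.kind!r}")
        if self.order < 1:
            raise InvalidArgumentError("order must be >= 1")
        if self.hidden is None:
            if self.kind == "mlp":
                self.hidden = MLP_HIDDEN.get(self.order, max(1, self.order // 2))
            elif self.kind == "elman":
                self.hidden = ELMAN_HIDDEN.get(self.order, max(1, self.order // 2))
            else:
                self.hidden = 0
        if self.epochs is None:
            self.epochs = _DEFAULT_EPOCHS.get(self.kind, 1)


@dataclass
class LayerQ:
    """One quantised layer: integer weights with a power-of-two scale."""

    weights: np.ndarray            # (out, in), int64, fits in j bits signed
    bias: np.ndarray               # (out,), int64, same scale
    scale_exp: int
    recurrent: np.ndarray | None = None  # (out, out), elman state feedback

    def param_count(self) -> int:
        n = self.weights.size + self.bias.size
        if self.recurrent is not None:
            n += self.recurrent.size
        return n


@dataclass
class QuantizedPredictor:
    """A trained predictor frozen to deterministic fixed point.

    This is the "network setting information" transmitted to the decoder
    (except for ``nlms``, which transmits nothing and re-adapts
    symmetrically).  Prediction is a pure function of the integer weights
    and the integer window.
    """

    kind: str
    order: int
    hidden: int
    input_scale_exp: int            # b: inputs scaled by 2**-b for the net
    weight_bits: int                # j: bits per transmitted weight
    layers: list[LayerQ]
    clamp_abs: int                  # prediction clamp (wavelet bound)
    mean_offset: int = 0            # AR models predict around this mean
    mu_num: int = 1                 # nlms step size as a fraction
    mu_den: int = 2
    eps: int = 1
    flags: tuple = ()
    training_log: list = field(default_factory=list, compare=False)

    def param_count(self) -> int:
        return sum(layer.param_count() for layer in self.layers)

    def side_info_bits(self) -> int:
        """Transmitted parameter payload: param_count x j bits."""
        return self.param_count() * self.weight_bits

    def init_state(self) -> list[int]:
        """Initial recurrent state (zeros); empty for stateless kinds."""
        return [0] * (self.hidden if self.kind == "elman" else 0)


@dataclass
class SegmentResiduals:
    """Residues of one subband segment: raw prefix + prediction errors."""

    raw: np.ndarray        # first min(p, len) coefficients stored verbatim
    residues: np.ndarray   # e_k for the remaining positions


@dataclass
class ResidualStream:
    """Per-segment residues for one block, in coding order."""

    order: int
    segments: list[SegmentResiduals]

    def all_residues(self) -> np.ndarray:
        if not self.segments:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate([s.residues for s in self.segments])

    def residue_count(self) -> int:
        return int(sum(len(s.residues) for s in self.segments))


# ---------------------------------------------------------------------------
# fixed-point inference
# ---------------------------------------------------------------------------

def _affine_fp(layer: LayerQ, inputs_fp: list[int],
               state_fp: list[int] | None = None) -> list[int]:
    """Integer affine map; output carries ACT_FRAC_BITS fractional bits."""
    out = []
    W = layer.weights
    R = layer.recurrent
    for r in range(W.shape[0]):
        acc = int(layer.bias[r]) << fp.ACT_FRAC_BITS
        row = W[r]
        for c in range(W.shape[1]):
            acc += int(row[c]) * inputs_fp[c]
        if R is not None and state_fp:
            rrow = R[r]
            for c in range(len(state_fp)):
                acc += int(rrow[c]) * state_fp[c]
        out.append(fp.rshift_round(acc, layer.scale_exp))
    return out


def predict_next_with_state(
    model: QuantizedPredictor, window, state: list[int] | None = None
) -> tuple[int, list[int]]:
    """Predict the next coefficient and return the updated recurrent state.

    ``window`` holds the ``p`` previous (reconstructed) coefficients, most
    recent last.  All arithmetic is integer-only; the result is clamped to
    the wavelet coefficient bound.
    """
    if model.kind == "nlms":
        raise InvalidArgumentError(
            "nlms is stateful-adaptive; use NLMSFilter / compute_residuals"
        )
    if len(window) != model.order:
        raise InvalidArgumentError(
            f"window length {len(window)} != predictor order {model.order}"
        )
    b = model.input_scale_exp
    mean = model.mean_offset
    # window order: w_i multiplies x_{k-i}, so feed most-recent-first
    u_fp = [fp.to_fixed(int(window[-(i + 1)]) - mean, b)
            for i in range(model.order)]
    if model.kind in ("slp", "ar"):
        y_fp = _affine_fp(model.layers[0], u_fp)[0]
        new_state = state or []
    elif model.kind == "mlp":
        hidden = [fp.tanh_fixed(z) for z in _affine_fp(model.layers[0], u_fp)]
        y_fp = _affine_fp(model.layers[1], hidden)[0]
        new_state = state or []
    elif model.kind == "elman":
        if state is None:
            state = model.init_state()
        hidden = [fp.tanh_fixed(z)
                  for z in _affine_fp(model.layers[0], u_fp, state)]
        y_fp = _affine_fp(model.layers[1], hidden)[0]
        new_state = hidden
    else:  # pragma: no cover - guarded by PredictorSpec validation
        raise InvalidArgumentError(model.kind)
    pred = mean + fp.from_fixed(y_fp, b)
    pred = max(-model.clamp_abs, min(model.clamp_abs, pred))
    return pred, new_state


def predict_next(model: QuantizedPredictor, window,
                 state: list[int] | None = None) -> int:
    """Stateless convenience wrapper around :func:`predict_next_with_state`."""
    return predict_next_with_state(model, window, state)[0]


class NLMSFilter:
    """Fixed-point normalised-LMS FIR, mirrored exactly by the decoder.

    Weights carry :data:`NLMS_FRAC_BITS` fractional bits and adapt as

        w <- w + mu * e * u / (eps + ||u||^2)

    with the division rounded half away from zero, ``mu`` held as an exact
    fraction.  Updates see reconstructed samples only, so running the same
    filter over decoded data reproduces every prediction.
    """

    def __init__(self, order: int, mu_num: int, mu_den: int, eps: int,
                 clamp_abs: int):
        if order < 1:
            raise InvalidArgumentError("order must be >= 1")
        if mu_num <= 0 or mu_den <= 0 or mu_num > mu_den:
            raise InvalidArgumentError("mu must satisfy 0 < mu <= 1")
        self.order = order
        self.mu_num = mu_num
        self.mu_den = mu_den
        self.eps = max(1, int(eps))
        self.clamp_abs = clamp_abs
        self.w = [0] * order

    def predict(self, window) -> int:
        acc = 0
        for wi, ui in zip(self.w, window):
            acc += wi * int(ui)
        pred = fp.rshift_round(acc, NLMS_FRAC_BITS)
        return max(-self.clamp_abs, min(self.clamp_abs, pred))

    def update(self, window, err: int) -> None:
        norm = self.eps
        for ui in window:
            norm += int(ui) * int(ui)
        den = self.mu_den * norm
        for i, ui in enumerate(window):
            num = self.mu_num * err * int(ui) << NLMS_FRAC_BITS
            self.w[i] += fp.div_round(num, den)


# ---------------------------------------------------------------------------
# residual computation / reconstruction
# ---------------------------------------------------------------------------

def _nlms_from_model(model: QuantizedPredictor) -> NLMSFilter:
    return NLMSFilter(model.order, model.mu_num, model.mu_den, model.eps,
                      model.clamp_abs)


def segment_residuals(model: QuantizedPredictor, x) -> SegmentResiduals:
    """Residues of one segment: raw ``min(p, len)`` prefix + errors.

    Recurrent/adaptive state starts from zero at the segment start.
    """
    p = model.order
    x = np.asarray(x, dtype=np.int64)
    raw_n = min(p, len(x))
    res = np.empty(max(0, len(x) - raw_n), dtype=np.int64)
    if model.kind == "nlms":
        filt = _nlms_from_model(model)
        for k in range(raw_n, len(x)):
            window = x[k - p : k]
            pred = filt.predict(window)
            e = int(x[k]) - pred
            res[k - raw_n] = e
            filt.update(window, e)
    else:
        state = model.init_state()
        for k in range(raw_n, len(x)):
            pred, state = predict_next_with_state(model, x[k - p : k], state)
            res[k - raw_n] = int(x[k]) - pred
    return SegmentResiduals(raw=x[:raw_n].copy(), residues=res)


def segment_reconstruct(model: QuantizedPredictor, seg: SegmentResiduals) -> np.ndarray:
    """Exact inverse of :func:`segment_residuals`."""
    p = model.order
    n = len(seg.raw) + len(seg.residues)
    x = np.empty(n, dtype=np.int64)
    x[: len(seg.raw)] = seg.raw
    raw_n = len(seg.raw)
    if model.kind == "nlms":
        filt = _nlms_from_model(model)
        for k in range(raw_n, n):
            window = x[k - p : k]
            pred = filt.predict(window)
            e = int(seg.residues[k - raw_n])
            x[k] = pred + e
            filt.update(window, e)
    else:
        state = model.init_state()
        for k in range(raw_n, n):
            pred, state = predict_next_with_state(model, x[k - p : k], state)
            x[k] = pred + int(seg.residues[k - raw_n])
    return x


def compute_residuals(model: QuantizedPredictor, sb: SubbandSet) -> ResidualStream:
    """Residues for every segment of ``sb`` (coding order), one shared model.

    The first ``min(p, len)`` coefficients of each segment are kept raw;
    prediction windows never cross segment boundaries; recurrent/adaptive
    state resets at each segment start.
    """
    return ResidualStream(
        order=model.order,
        segments=[segment_residuals(model, x) for x in sb.segments()],
    )


def reconstruct_coeffs(res: ResidualStream, model: QuantizedPredictor,
                       sb_template: SubbandSet | None = None) -> SubbandSet:
    """Exact inverse of :func:`compute_residuals`.

    ``sb_template`` supplies the subband bookkeeping (levels, lengths);
    when omitted a flat single-segment SubbandSet-like reconstruction is
    produced from the segment lengths in ``res``.
    """
    rebuilt = [segment_reconstruct(model, seg) for seg in res.segments]
    if sb_template is not None:
        approx = rebuilt[0]
        details = list(reversed(rebuilt[1:]))
        return SubbandSet(levels=sb_template.levels, details=details,
                          approx=approx,
                          original_length=sb_template.original_length)
    total = int(sum(len(x) for x in rebuilt))
    if len(rebuilt) == 1:
        return SubbandSet(levels=0, details=[], approx=rebuilt[0],
                          original_length=total)
    details = list(reversed(rebuilt[1:]))
    n = total
    for _ in details:
        n = (n + 1) // 2
    return SubbandSet(levels=len(details), details=details, approx=rebuilt[0],
                      original_length=total)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _as_segments(sb_stream) -> list[np.ndarray]:
    if isinstance(sb_stream, SubbandSet):
        return sb_stream.segments()
    if isinstance(sb_stream, (list, tuple)) and sb_stream and not np.isscalar(
        sb_stream[0]
    ) and hasattr(sb_stream[0], "__len__"):
        return [np.asarray(s, dtype=np.int64) for s in sb_stream]
    return [np.asarray(sb_stream, dtype=np.int64)]


def _input_scale_exp(max_abs: int) -> int:
    """Smallest b with max|coeff| <= 2**b."""
    if max_abs <= 1:
        return 0
    return int(math.ceil(math.log2(max_abs)))


def _training_windows(segments: list[np.ndarray], p: int):
    """Sliding windows (most recent first) and targets, per segment."""
    xs, ys = [], []
    for x in segments:
        if len(x) <= p:
            continue
        # column i holds x_{k-(i+1)}: most recent predecessor first
        wins = np.stack([x[p - 1 - i : len(x) - 1 - i] for i in range(p)], axis=1)
        xs.append(wins)
        ys.append(x[p:])
    if not xs:
        raise InvalidArgumentError("stream too short for this predictor order")
    return np.concatenate(xs).astype(np.float64), np.concatenate(ys).astype(
        np.float64
    )


def _nguyen_widrow(rng, fan_in: int, fan_out: int):
    """Nguyen-Widrow layer initialisation (weights + spread biases)."""
    w = rng.uniform(-1.0, 1.0, size=(fan_out, fan_in))
    beta = 0.7 * fan_out ** (1.0 / max(1, fan_in))
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    w = beta * w / norms
    if fan_out == 1:
        b = np.zeros(1)
    else:
        b = beta * np.linspace(-1.0, 1.0, fan_out) * np.sign(w[:, 0])
    return w, b


def _quantize_layers(float_layers, weight_bits: int) -> list[LayerQ]:
    out = []
    limit = (1 << (weight_bits - 1)) - 1
    for parts in float_layers:
        arrays = [a for a in parts.values() if a is not None]
        max_abs = max((float(np.max(np.abs(a))) for a in arrays), default=0.0)
        s = fp.choose_scale_exp(max_abs, weight_bits)

        def q(a):
            if a is None:
                return None
            qa = np.array(
                [[fp.quantize_weight(float(v), s) for v in row] for row in
                 np.atleast_2d(a)],
                dtype=np.int64,
            )
            return np.clip(qa, -limit, limit)

        W = q(parts["weights"])
        bias = q(parts["bias"])[0]
        rec = q(parts.get("recurrent"))
        out.append(LayerQ(weights=W, bias=bias, scale_exp=s, recurrent=rec))
    return out


def _train_lm(X, y, spec: PredictorSpec, rng):
    """Levenberg-Marquardt for slp (linear) and mlp (one tanh hidden layer).

    Damping starts at 1e-3 and moves by factors of 10; an epoch's step is
    retried with more damping until the MSE improves; stops early when the
    relative MSE change falls below 1e-6.
    """
    p = X.shape[1]
    h = spec.hidden if spec.kind == "mlp" else 0

    if spec.kind == "slp":
        theta = np.concatenate([rng.uniform(-0.5, 0.5, size=p) * 0.1, [0.0]])

        def forward(t):
            return X @ t[:p] + t[p]

        def jacobian(t):
            return np.hstack([X, np.ones((len(X), 1))])

    else:
        W1, b1 = _nguyen_widrow(rng, p, h)
        W2 = rng.uniform(-0.5, 0.5, size=h) / math.sqrt(h)
        theta = np.concatenate([W1.ravel(), b1, W2, [0.0]])

        def unpack(t):
            i = 0
            W1 = t[i : i + h * p].reshape(h, p); i += h * p
            b1 = t[i : i + h]; i += h
            W2 = t[i : i + h]; i += h
            b2 = t[i]
            return W1, b1, W2, b2

        def forward(t):
            W1, b1, W2, b2 = unpack(t)
            H = np.tanh(X @ W1.T + b1)
            return H @ W2 + b2

        def jacobian(t):
            W1, b1, W2, b2 = unpack(t)
            H = np.tanh(X @ W1.T + b1)
            G = (1.0 - H**2) * W2          # (N, h)
            JW1 = G[:, :, None] * X[:, None, :]  # dy/dW1
            return np.hstack([
                JW1.reshape(len(X), h * p),
                G,
                H,
                np.ones((len(X), 1)),
            ])

    lam = 1e-3
    r = forward(theta) - y
    mse = float(np.mean(r**2))
    if not np.isfinite(mse):
        raise TrainingFailureError("initial MSE not finite")
    log = [mse]
    for _ in range(spec.epochs):
        J = jacobian(theta)
        A = J.T @ J
        g = J.T @ r
        improved = False
        for _try in range(12):
            try:
                step = np.linalg.solve(A + lam * np.eye(len(theta)), g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            cand = theta - step
            r_new = forward(cand) - y
            mse_new = float(np.mean(r_new**2))
            if not np.isfinite(mse_new):
                lam *= 10
                continue
            if mse_new < mse:
                theta, r = cand, r_new
                prev, mse = mse, mse_new
                lam = max(lam / 10, 1e-12)
                improved = True
                break
            lam *= 10
        log.append(mse)
        if not np.isfinite(mse):
            raise TrainingFailureError(f"training diverged, MSE={mse}")
        if improved and abs(prev - mse) <= 1e-6 * max(prev, 1e-30):
            break
        if not improved:
            break

    if spec.kind == "slp":
        layers = [{"weights": theta[:p].reshape(1, p),
                   "bias": np.array([theta[p]])}]
    else:
        W1, b1, W2, b2 = unpack(theta)
        layers = [
            {"weights": W1, "bias": b1},
            {"weights": W2.reshape(1, h), "bias": np.array([b2])},
        ]
    return layers, log


def _train_elman(segments, spec: PredictorSpec, rng, scale: float):
    """Gradient descent with momentum + adaptive LR for the Elman network.

    The recurrent connection is handled as a one-step-delayed input
    (teacher-forced truncation): hidden states are rolled forward
    sequentially, gradients ignore the dependence of h_{t-1} on the
    parameters.  A step that worsens the MSE by more than 4% is rejected
    and the learning rate reduced (x0.7); improving steps grow it (x1.05).
    """
    p, h = spec.order, spec.hidden
    W1, b1 = _nguyen_widrow(rng, p, h)
    Wr, _ = _nguyen_widrow(rng, h, h)
    Wr *= 0.5
    W2 = rng.uniform(-0.5, 0.5, size=h) / math.sqrt(h)
    b2 = 0.0

    seqs = []
    for x in segments:
        if len(x) <= p:
            continue
        wins = np.stack([x[p - 1 - i : len(x) - 1 - i] for i in range(p)], axis=1)
        seqs.append((wins.astype(np.float64) * scale,
                     x[p:].astype(np.float64) * scale))
    if not seqs:
        raise InvalidArgumentError("stream too short for this predictor order")

    def forward(params):
        W1, b1, Wr, W2, b2 = params
        Hs, Hprevs, Us, Ts = [], [], [], []
        for U, t in seqs:
            hstate = np.zeros(h)
            for j in range(len(U)):
                Hprevs.append(hstate)
                z = W1 @ U[j] + Wr @ hstate + b1
                hstate = np.tanh(z)
                Hs.append(hstate)
                Us.append(U[j])
            Ts.append(t)
        H = np.array(Hs)
        Hp = np.array(Hprevs)
        U = np.array(Us)
        t = np.concatenate(Ts)
        y = H @ W2 + b2
        return H, Hp, U, t, y

    lr = spec.learning_rate
    mom = spec.momentum
    params = [W1, b1, Wr, W2, b2]
    vel = [np.zeros_like(np.atleast_1d(q)) for q in params]
    H, Hp, U, t, y = forward(params)
    mse = float(np.mean((y - t) ** 2))
    log = [mse]
    for _ in range(spec.epochs):
        N = len(t)
        dy = 2.0 * (y - t) / N
        gW2 = H.T @ dy
        gb2 = float(np.sum(dy))
        dH = np.outer(dy, params[3]) * (1.0 - H**2)
        gW1 = dH.T @ U
        gb1 = dH.sum(axis=0)
        gWr = dH.T @ Hp
        grads = [gW1, gb1, gWr, gW2, gb2]
        new_vel = [mom * v - lr * np.atleast_1d(g) for v, g in zip(vel, grads)]
        cand = [
            q + (v if isinstance(q, np.ndarray) else v[0])
            for q, v in zip(params, new_vel)
        ]
        Hc, Hpc, Uc, tc, yc = forward(cand)
        mse_new = float(np.mean((yc - tc) ** 2))
        if not np.isfinite(mse_new):
            raise TrainingFailureError("elman training diverged")
        if mse_new > 1.04 * mse:
            lr *= 0.7
            vel = [np.zeros_like(v) for v in vel]
            log.append(mse)
            continue
        params, vel = cand, new_vel
        H, Hp, U, t, y = Hc, Hpc, Uc, tc, yc
        if mse_new < mse:
            lr *= 1.05
        mse = mse_new
        log.append(mse)
    W1, b1, Wr, W2, b2 = params
    layers = [
        {"weights": W1, "bias": b1, "recurrent": Wr},
        {"weights": np.asarray(W2).reshape(1, h), "bias": np.array([b2])},
    ]
    return layers, log


def train_predictor(sb_stream, spec: PredictorSpec,
                    clamp_abs: int | None = None) -> QuantizedPredictor:
    """Train a predictor on a coefficient stream and freeze it to fixed point.

    ``sb_stream`` may be a flat integer sequence, a list of segment arrays
    (windows never cross segment boundaries), or a :class:`SubbandSet`.
    Deterministic given ``spec.seed``; the per-epoch MSE log is attached
    as ``training_log``.
    """
    segments = _as_segments(sb_stream)
    total = int(sum(len(s) for s in segments))
    if total <= spec.order:
        raise InvalidArgumentError("stream too short for this predictor order")
    if clamp_abs is None:
        clamp_abs = 1 << 62

    if spec.kind == "ar":
        return fit_ar_levinson(np.concatenate(segments), order=spec.order,
                               weight_bits=spec.weight_bits,
                               clamp_abs=clamp_abs)
    if spec.kind == "nlms":
        frac = Fraction(spec.mu).limit_denominator(1 << 16)
        if not (0 < frac <= 1):
            raise InvalidArgumentError("mu must satisfy 0 < mu <= 1")
        return QuantizedPredictor(
            kind="nlms", order=spec.order, hidden=0, input_scale_exp=0,
            weight_bits=spec.weight_bits, layers=[], clamp_abs=clamp_abs,
            mu_num=frac.numerator, mu_den=frac.denominator, eps=spec.eps,
        )

    all_vals = np.concatenate(segments)
    max_abs = int(np.max(np.abs(all_vals))) if len(all_vals) else 0
    b = _input_scale_exp(max_abs)
    scale = 2.0 ** (-b)
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "elman":
        float_layers, log = _train_elman(segments, spec, rng, scale)
    else:
        X, y = _training_windows(segments, spec.order)
        float_layers, log = _train_lm(X * scale, y * scale, spec, rng)

    layers = _quantize_layers(float_layers, spec.weight_bits)
    return QuantizedPredictor(
        kind=spec.kind, order=spec.order, hidden=spec.hidden,
        input_scale_exp=b, weight_bits=spec.weight_bits, layers=layers,
        clamp_abs=clamp_abs, training_log=log,
    )


# ---------------------------------------------------------------------------
# linear predictors
# ---------------------------------------------------------------------------

def levinson_durbin(r, order: int) -> np.ndarray:
    """Solve the Yule-Walker equations by the Levinson-Durbin recursion.

    ``r`` holds autocorrelation lags r_0..r_order.  Returns the forward
    prediction coefficients ``a`` with x_hat_k = sum_i a_i x_{k-i}.
    """
    r = np.asarray(r, dtype=np.float64)
    if len(r) < order + 1:
        raise InvalidArgumentError("need order+1 autocorrelation lags")
    if r[0] <= 0:
        return np.zeros(order)
    a = np.zeros(order)
    err = r[0]
    for m in range(order):
        # r[m:0:-1] = (r_m, ..., r_1): lags pairing a_1..a_m with r_{m+1-i}
        acc = r[m + 1] - (np.dot(a[:m], r[m:0:-1]) if m else 0.0)
        k = acc / err
        a_new = a.copy()
        a_new[m] = k
        a_new[:m] = a[:m] - k * a[:m][::-1]
        a = a_new
        err *= 1.0 - k * k
        if err <= 0:
            break
    return a


def fit_ar_levinson(stream, order: int = 5,
                    weight_bits: int = fp.DEFAULT_WEIGHT_BITS,
                    clamp_abs: int | None = None) -> QuantizedPredictor:
    """Fit an AR(order) model via biased autocorrelation + Levinson-Durbin.

    The integer-rounded stream mean is removed before fitting and stored
    in the model, so a zero-variance stream degenerates to a flagged
    zero-coefficient model that predicts the mean.
    """
    x = np.concatenate(_as_segments(stream)).astype(np.float64)
    if len(x) <= order:
        raise InvalidArgumentError("stream too short for this AR order")
    if clamp_abs is None:
        clamp_abs = 1 << 62
    m0 = int(round(float(np.mean(x))))
    xc = x - np.mean(x)
    n = len(xc)
    r = np.array([np.dot(xc[: n - k], xc[k:]) / n for k in range(order + 1)])
    flags = ()
    if r[0] <= 0:
        a = np.zeros(order)
        flags = ("zero-variance",)
    else:
        a = levinson_durbin(r, order)

    max_abs = int(math.ceil(float(np.max(np.abs(x - m0))))) if len(x) else 0
    b = _input_scale_exp(max_abs)
    layers = _quantize_layers(
        [{"weights": a.reshape(1, order), "bias": np.zeros(1)}], weight_bits
    )
    return QuantizedPredictor(
        kind="ar", order=order, hidden=0, input_scale_exp=b,
        weight_bits=weight_bits, layers=layers, clamp_abs=clamp_abs,
        mean_offset=m0, flags=flags,
    )


def nlms_residuals(stream, order: int = 5, mu: float = 0.5,
                   eps: int = 1, clamp_abs: int | None = None) -> ResidualStream:
    """Residues of the symmetric-adaptation NLMS filter over a flat stream."""
    x = np.asarray(stream, dtype=np.int64)
    if len(x) <= order:
        raise InvalidArgumentError("stream too short for this filter order")
    if mu <= 0 or mu > 1:
        raise InvalidArgumentError("mu must satisfy 0 < mu <= 1")
    if clamp_abs is None:
        clamp_abs = 1 << 62
    frac = Fraction(mu).limit_denominator(1 << 16)
    model = QuantizedPredictor(
        kind="nlms", order=order, hidden=0, input_scale_exp=0,
        weight_bits=fp.DEFAULT_WEIGHT_BITS, layers=[], clamp_abs=clamp_abs,
        mu_num=frac.numerator, mu_den=frac.denominator, eps=eps,
    )
    sb = SubbandSet(levels=0, details=[], approx=x, original_length=len(x))
    return compute_residuals(model, sb)
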