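# Methods

This note documents the models, numerical contracts and design choices
behind `eegcodec`, in the spirit of a codec format specification plus a
statistical methods section.

## Signal model and scope

The codec operates on single-channel EEG digitised to signed integers
(default 12-bit at 173.61 Hz).  Losslessness is defined at the sample
level: `decompress(compress(s))` reproduces the integer samples exactly,
guarded by a CRC-32 in the container.  Multi-channel layouts, streaming
encoding and encryption are out of scope.

## Integer 5/3 lifting wavelet

The 5/3 biorthogonal pair is factored into one predict and one update
lifting step with floor rounding,

    d[k] = x[2k+1] − ⌊(x[2k] + x[2k+2])/2⌋
    a[k] = x[2k]   + ⌊(d[k−1] + d[k] + 2)/4⌋ ,

which maps integers to integers reversibly.  Boundary handling and the
odd-length split follow the reversible JPEG-2000 convention: whole-sample
symmetric extension (x[−1] = x[1], x[N] = x[N−2]; mirrored detail indices
in the update step) and the approximation takes the extra sample.  These
conventions are this package's documented choice — the transform itself
does not dictate them — selected because they are invertible for every
length ≥ 2.  Analysis recurses on the approximation, four levels by
default; inputs too short for the requested depth reduce the effective
level count (recorded in the container), and one-sample blocks bypass the
transform.  Coefficients of an n-bit signal are bounded by n+4 signed
bits; that bound sizes the raw-coefficient packing and the predictor
clamp.

## Prediction

Each coefficient is predicted from its p predecessors within the same
subband segment; windows never cross segment boundaries and
recurrent/adaptive state resets at each segment start.

**One predictor per subband segment.**  The five coding segments
(approximation, then details coarse-to-fine) are distinct stochastic
processes whose scales differ by an order of magnitude.  A single
predictor fitted across their concatenation minimises an objective
dominated by the loudest subbands and measurably *increases* residue
entropy in the others, so the codec fits one predictor per segment per
block.  The extra side information is negligible (≈ 96 bits per segment
for an SLP of order 5).

**Predictor families and training.**
* *SLP* — linear, no hidden layer; trained by Levenberg–Marquardt (for a
  linear model this converges in essentially one damped Gauss–Newton
  step).
* *MLP* — one tanh hidden layer, identity output; hidden sizes 1/3/8/12
  paired with orders 2/5/10/20; Levenberg–Marquardt with analytic
  Jacobian, initial damping 1e−3, ×10/÷10 schedule, at most 50 epochs,
  early stop on relative MSE change < 1e−6; Nguyen–Widrow layer
  initialisation.
* *Elman* — recurrent hidden layer (sizes 1/5/8/16 by order); gradient
  descent with momentum 0.9 and adaptive learning rate (start 0.01,
  ×1.05 on improvement, ×0.7 and momentum reset when the MSE worsens by
  more than 4%), 30 epochs by default.  The recurrent connection is
  trained with one-step truncation (the dependence of the previous hidden
  state on the weights is ignored), the standard simplification for this
  architecture.
* *AR(5)* — biased autocorrelation estimates, Levinson–Durbin recursion;
  the integer-rounded stream mean is removed before fitting and stored,
  so a zero-variance stream degenerates to a flagged model predicting the
  mean.
* *NLMS FIR(5)* — w ← w + µ·e·u/(ε + ‖u‖²) with µ = 1/2 held as an exact
  fraction and ε = 1; adaptation sees reconstructed samples only, so the
  decoder re-runs the identical filter and **no weights are transmitted**.

Training happens in float64 on inputs scaled by 2^−b, where b is the
smallest exponent with max|coefficient| ≤ 2^b, and is deterministic given
the seed.  Epoch counts and damping constants are configurable; the
defaults above were fixed once as reasonable small-problem settings.

**Fixed-point inference contract.**  Cross-platform float differences
would silently break losslessness, so trained weights are frozen to
16-bit integers with a per-layer power-of-two scale (round half away from
zero; the scale is the largest keeping every weight and bias inside 16
signed bits), activations carry 16 fractional bits, tanh is evaluated
through a fixed 2048-entry table over [−4, 4) with integer linear
interpolation, and every rescale rounds half away from zero.  Prediction
is then a pure function of integer weights and the integer window,
clamped to the wavelet coefficient bound.  Sixteen fractional activation
bits keep the worst-case quantisation error of an exactly-fitted SLP
below 0.5 LSB after the 2^b rescale, so e.g. a constant stream yields
exactly zero residues.

## Context-based bias cancellation

Residues are grouped by the two-level-quantised signs of m local
differences, Q(d) = 0 if d < 0 else 1 (ties count as 1), packed as
index = Σ bitᵢ·2^(i−1).  Two context definitions exist:

* *symmetric* — dᵢ = x[k+i] − x[k−i].  It uses future samples, so a
  sequential decoder cannot form it; it is retained for encoder-side
  benchmarking only and the decodable path refuses it.
* *causal* — dᵢ = x[k−i] − x[k−i−1], adjacent past differences, exactly
  invertible at the decoder.

Per-context biases are the rounded (half away from zero) mean residues,
estimated in a second encoder pass and transmitted in the header (2^m
16-bit values; m ≤ 8), the simplest provably encoder/decoder-symmetric
scheme.  Positions whose difference window leaves the segment map to a
reserved context 0.  The codec's three bias modes are: WBC (none), BC
(m = 1, the single adjacent-difference context of the original scheme)
and IBC (the configured depth, default m = 5 / 32 contexts).

On residues whose conditional mean truly varies with the context, the
measured saving is ≈ 0.6 bits/sample (offset-structured test data, m = 5)
and deepening m beyond the structure present yields no significant
further gain.  On the synthetic EEG profiles the predictor residues are
already nearly context-unbiased, so IBC changes CR by roughly the cost of
the table (|ΔCR| ≈ 0.02); the mechanism matters for signals with
context-dependent prediction bias, which the offset-structured
measurement exercises directly.

## Entropy stage (LZARIC)

Residues are folded to non-negative integers (zigzag), split into 7-bit
groups with a continuation bit, LZW-coded over the byte alphabet
(initial dictionary 0..255, frozen at 2^16 entries), and the code indices
are compressed by an adaptive order-0 arithmetic coder.  Coder constants
are part of the format: 32-bit integer range with E3 underflow handling,
frequencies start at 1, increment 32 per occurrence, halve (rounding up)
when the total exceeds 2^15; a terminator symbol closes each stream.  The
arithmetic stage lands within 2% of the order-0 empirical entropy for
iid sources of 10^5 symbols (alphabets 2–256); at a few ×10^4 symbols the
adaptation cost is nearer 3%.  LZW helps on repetitive residue streams
and can expand slightly on incompressible ones; the composition is always
bit-exact either way.  A degenerate all-zero stream of 10^4 residues
costs ≈ 200 bytes: LZW collapses the run to ~140 codes, but each code
index is novel to the adaptive model (~7 bits each).

## Blocks, container, accounting

The single-block scheme (SB) processes the whole signal at once; the
block-adaptive scheme (BA) cuts ⌊90 s · fs⌋-sample blocks with
independent per-block models, merging a final remainder shorter than
2^levels into the preceding block.  The container stores the sampling
rate as a rational (17361/100 by default) to avoid float drift, packs raw
leading coefficients at n+4 bits, serialises predictor weights
little-endian two's-complement, and is fully self-describing.  The size
breakdown reported for every run accounts raw-coefficient bits,
side-information bits (parameters × 16), bias-table bits, payload bits
and container framing separately; their sum equals the on-disk bit count
exactly, and CR is computed over that total (a conservative choice — the
framing and bias table are charged to the codec).  Encode wall-clock time
is recorded for CE but never used in correctness checks.

## Synthetic EEG generator

Profiles ds1–ds5 emulate the five recording conditions of the public Bonn
epilepsy datasets: eyes-open/eyes-closed surface EEG, interictal
intracranial EEG opposite to and within the epileptogenic zone, and ictal
recordings.  Each trace is a sum of three random-phase sinusoids per
rhythm band (delta/theta/alpha/beta, relative powers per profile), a
1/f² Gaussian background band-limited to 0.5–40 Hz — the slope matches
the measured fall-off of scalp/depth EEG above the alpha peak, and the
band matches the acquisition filter of the emulated recordings — plus,
for the ictal profile only, Poisson-timed biphasic spike kernels (~2.5/s,
triple the background amplitude).  RMS amplitudes (60–420 LSB by profile)
were fixed once at plausible microvolt-equivalent levels.  Samples are
zero-mean LSB counts rounded and clipped to the bit-depth range.

What the generator does *not* emulate: nonstationary artefacts (eye
blinks, electrode pops), line interference, true broadband ictal chirps,
or inter-channel structure.  Passing tests therefore demonstrate the
codec's correctness and qualitative behaviour (subband statistics,
predictor and context mechanics) on spectrally realistic data, not the
compression ratio attainable on any particular clinical recording: real
recordings differ in predictability, and published figures on the Bonn
data (CR ≈ 3) also depend on training settings not reproduced here.

## Degenerate inputs and tie-breaks

Empty signals are rejected everywhere; one- and two-sample signals
compress via the transform bypass.  Segments no longer than the predictor
order are stored raw with no model.  All rounding in the inference path
is half-away-from-zero; Q(0) = 1 in the context quantiser; empty contexts
get bias 0.  Corrupted containers fail with the specific field named
(magic, version, section lengths, CRC).

## Known limitations

* Encoder-side training dominates runtime for the MLP/Elman kinds; no
  GPU or online adaptation is provided.
* The tanh table is built from the host libm at import; its values are
  rounded to 2^−16, where a last-ulp libm difference could in principle
  flip one table entry.  A frozen table constant would remove even that
  risk.
* BC/IBC require causal contexts; the symmetric definition is available
  only through the measurement-only benchmark path.
* CR on synthetic profiles (≈ 1.5 mean) characterises these generator
  conditions, not clinical data.
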