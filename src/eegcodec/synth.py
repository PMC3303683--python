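"""Synthetic Bonn-like EEG generator (profiles DS1-DS5).

The generator emulates the five physiological conditions of the public
Bonn epilepsy recordings: surface EEG from healthy volunteers with eyes
open (DS1) and eyes closed (DS2, dominant alpha rhythm), intracranial
interictal EEG from the hippocampal formation opposite the epileptogenic
zone (DS3) and from within it (DS4), and intracranial ictal recordings
(DS5, high-amplitude spiking).

The signal model is a sum of per-band sinusoids with random phases, a
1/f^alpha Gaussian background band-limited to the 0.5-40 Hz acquisition
band (alpha = 2, the spectral slope scalp/depth EEG shows above the
alpha peak), and - for the ictal profile only - Poisson-timed biphasic
spike kernels.  The mixture is scaled to a target RMS in LSB counts, rounded
and clipped to the bit-depth range.  Samples are zero-mean LSB counts;
no physiological realism is claimed beyond spectral shape and amplitude
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .signal_io import DEFAULT_BIT_DEPTH, DEFAULT_FS, EEGSignal, bit_depth_range

#: canonical EEG rhythm bands (Hz); "noise" keys the 1/f background power
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: acquisition band of the emulated recordings (analog filter passband, Hz)
ACQ_BAND = (0.5, 40.0)

_SINES_PER_BAND = 3


@dataclass(frozen=True)
class GeneratorProfile:
    """Spectral recipe for one synthetic recording condition.

    ``band_powers`` maps rhythm-band names (and the special key ``"noise"``
    for the 1/f background) to relative powers; ``amplitude_scale`` is the
    target RMS of the background+oscillation mixture in LSB counts;
    ``spike_rate`` (events/s) is nonzero only for the ictal profile.
    """

    name: str
    band_powers: dict[str, float] = field(default_factory=dict)
    noise_exponent: float = 2.0
    spike_rate: float = 0.0
    amplitude_scale: float = 100.0

    def __post_init__(self):
        if any(v < 0 for v in self.band_powers.values()):
            raise InvalidArgumentError("band powers must be non-negative")
        if self.spike_rate < 0:
            raise InvalidArgumentError("spike_rate must be >= 0")


PROFILES: dict[str, GeneratorProfile] = {
    # surface, eyes open: desynchronised, low-amplitude, broadband
    "ds1_eyes_open": GeneratorProfile(
        name="ds1_eyes_open",
        band_powers={"delta": 0.4, "theta": 0.3, "alpha": 0.6, "beta": 0.35,
                     "noise": 0.8},
        amplitude_scale=60.0,
    ),
    # surface, eyes closed: dominant posterior alpha rhythm
    "ds2_eyes_closed": GeneratorProfile(
        name="ds2_eyes_closed",
        band_powers={"delta": 0.3, "theta": 0.25, "alpha": 1.6, "beta": 0.2,
                     "noise": 0.5},
        amplitude_scale=110.0,
    ),
    # intracranial interictal, hippocampus opposite the epileptogenic zone
    "ds3_interictal_opposite": GeneratorProfile(
        name="ds3_interictal_opposite",
        band_powers={"delta": 0.8, "theta": 0.6, "alpha": 0.35, "beta": 0.25,
                     "noise": 0.7},
        amplitude_scale=90.0,
    ),
    # intracranial interictal, within the epileptogenic zone: slower, larger
    "ds4_interictal_focal": GeneratorProfile(
        name="ds4_interictal_focal",
        band_powers={"delta": 1.0, "theta": 0.7, "alpha": 0.3, "beta": 0.3,
                     "noise": 0.8},
        amplitude_scale=130.0,
    ),
    # ictal: high-amplitude rhythmic slowing with superposed spiking
    "ds5_ictal": GeneratorProfile(
        name="ds5_ictal",
        band_powers={"delta": 1.2, "theta": 0.9, "alpha": 0.4, "beta": 0.5,
                     "noise": 1.0},
        spike_rate=2.5,
        amplitude_scale=420.0,
    ),
}


def _band_oscillation(rng, n, fs, band, k=_SINES_PER_BAND):
    """Unit-RMS sum of ``k`` random-phase sinusoids inside ``band``."""
    t = np.arange(n) / fs
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    freqs = rng.uniform(lo, hi, size=k)
    phases = rng.uniform(0.0, 2 * np.pi, size=k)
    x = np.sum(np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]),
               axis=0)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _shaped_noise(rng, n, fs, exponent):
    """Unit-RMS 1/f^alpha Gaussian noise, band-limited to the acquisition band."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    lo, hi = ACQ_BAND
    inband = (freqs >= lo) & (freqs <= hi)
    gain[inband] = freqs[inband] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _spike_train(rng, n, fs, rate, amplitude):
    """Poisson-timed biphasic (Gaussian-derivative) spike kernels."""
    out = np.zeros(n)
    n_events = rng.poisson(rate * n / fs)
    if n_events == 0:
        return out
    centers = np.sort(rng.uniform(0, n, size=n_events))
    width = 0.03 * fs  # ~30 ms half-width, epileptiform sharp transient
    t = np.arange(n)
    for c in centers:
        amp = amplitude * rng.uniform(0.6, 1.4) * rng.choice((-1.0, 1.0))
        z = (t - c) / width
        mask = np.abs(z) < 6
        out[mask] += amp * (-z[mask]) * np.exp(0.5 - 0.5 * z[mask] ** 2)
    return out


def generate_eeg(
    profile: GeneratorProfile | str,
    duration_s: float,
    fs: float = DEFAULT_FS,
    bit_depth: int = DEFAULT_BIT_DEPTH,
    seed: int = 0,
) -> EEGSignal:
    """Generate a synthetic EEG trace for one recording profile.

    Deterministic given ``seed``.  Output length is ``round(duration_s*fs)``
    samples, rounded and clipped to the signed ``bit_depth`` range.
    """
    if isinstance(profile, str):
        try:
            profile = PROFILES[profile]
        except KeyError:
            raise InvalidArgumentError(
                f"unknown profile {profile!r}; choose from {sorted(PROFILES)}"
            ) from None
    if duration_s <= 0 or fs <= 0:
        raise InvalidArgumentError("duration_s and fs must be positive")
    if not (8 <= bit_depth <= 16):
        raise InvalidArgumentError("bit_depth must lie in [8, 16]")
    n = int(round(duration_s * fs))
    if n < 1:
        raise InvalidArgumentError("duration_s * fs must be >= 1 sample")

    rng = np.random.default_rng(seed)
    mix = np.zeros(n)
    for band_name, power in sorted(profile.band_powers.items()):
        if power == 0:
            continue
        if band_name == "noise":
            comp = _shaped_noise(rng, n, fs, profile.noise_exponent)
        else:
            comp = _band_oscillation(rng, n, fs, BANDS[band_name])
        mix += np.sqrt(power) * comp

    rms = np.sqrt(np.mean(mix**2))
    if rms > 0:
        mix *= profile.amplitude_scale / rms
    if profile.spike_rate > 0:
        mix += _spike_train(rng, n, fs, profile.spike_rate,
                            3.0 * profile.amplitude_scale)

    lo, hi = bit_depth_range(bit_depth)
    samples = np.clip(np.rint(mix), lo, hi).astype(np.int64)
    return EEGSignal(samples, fs=fs, bit_depth=bit_depth, label=profile.name)
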