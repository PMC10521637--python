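"""Synthetic microbubble-emission plant.

The plant stands in for the physical chain *FUS transducer → circulating
microbubbles → PCD receiver* so the closed loop can be exercised end-to-end
without hardware or animal data. Per commanded pulse it synthesizes a PCD
voltage trace from four ingredients:

* **harmonic emissions** (stable cavitation) — tones at k·f0 (k = 1..4,
  f0 = 1.5 MHz) whose amplitudes scale as ``(p / p_ref)^alpha`` with
  commanded pressure ``p`` (``p_ref`` = 200 kPa);
* **broadband emission** (inertial cavitation) — white noise band-limited to
  2.5–4.0 MHz (so it contributes at the 3.3 MHz monitoring band, between
  harmonics and ultraharmonics) switched on by a logistic onset around the
  subject's inertial threshold (default 300 kPa, width 10 kPa); the band
  filter removes out-of-band power without renormalizing, so
  ``broadband_amp`` sets the in-band spectral level relative to the sensor
  noise floor;
* **sensor noise** — additive white Gaussian noise whose default level is
  set so the third-harmonic band SNR at the reference pressure is 20 dB;
* **per-pulse jitter** — a lognormal multiplicative fluctuation of all
  emissions (sigma = 0.05), emulating beat-to-beat variation in the bubble
  population at the focus.

Inter-subject variability — skull attenuation, injected dose, local
vascularity — is collapsed into a single lognormal emission gain per subject
(sigma = 0.3), which reproduces the spread of baseline stable cavitation
levels seen across animals. Microbubble availability follows the infusion
protocol: the pump starts 15 s before sonication at 12.8 µL/min, so bubbles
have reached the brain (availability 1) by the first dummy pulse.

With the defaults, the pressure that realizes a 2 dB target is about
200·10^(2/20) ≈ 252 kPa, below the 300 kPa inertial threshold (no broadband
events), while a 4 dB target needs ≈ 317 kPa, above it — mirroring the
in vivo observation that inertial cavitation appears only at the highest
target levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectral import DEFAULT_PULSE_LENGTH_S, DEFAULT_SAMPLE_RATE, PcdTrace

__all__ = [
    "SubjectParams",
    "PlantConfig",
    "InfusionModel",
    "derive_noise_floor_sd",
    "sample_subjects",
    "infusion_factor",
    "emission_amplitudes",
    "synth_trace",
    "SimulatedPulseSource",
]


@dataclass
class SubjectParams:
    """One synthetic subject.

    ``gain`` multiplies all emissions (skull / dose / vasculature
    variability); ``inertial_threshold_kPa`` is the pressure of broadband
    onset; ``seed`` seeds the subject's private pulse stream.
    """

    gain: float
    inertial_threshold_kPa: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("gain must be positive")
        if not self.inertial_threshold_kPa > 0:
            raise ValueError("inertial_threshold_kPa must be positive")


@dataclass
class InfusionModel:
    """Constant-rate microbubble infusion timing.

    The pump starts ``pre_delay_s`` (15 s) before sonication; availability at
    the focus ramps linearly from 0 to 1 over ``ramp_s`` (the transit time
    through the catheter and circulation) and stays at 1 until the syringe
    (``volume_uL`` at ``rate_uL_min``) is exhausted. Washout after the pump
    stops is not modelled: availability clamps at 1 through the session.
    """

    pre_delay_s: float = 15.0
    ramp_s: float = 15.0
    rate_uL_min: float = 12.8
    volume_uL: float = 30.0

    def __post_init__(self) -> None:
        for name in ("pre_delay_s", "ramp_s", "rate_uL_min", "volume_uL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def duration_s(self) -> float:
        """Time the pump runs: volume / rate."""
        return self.volume_uL / self.rate_uL_min * 60.0


@dataclass
class PlantConfig:
    """Emission-model constants.

    ``harmonic_amps_ref`` are the amplitudes (arbitrary units) of f0..4·f0 at
    the reference pressure for a gain-1 subject with full bubble
    availability. ``pressure_exponent`` (alpha) makes the stable level in dB
    linear in 20·log10(p); alpha = 1 places the study's target levels on
    both sides of the inertial threshold. ``noise_floor_sd`` defaults to the
    closed-form value giving ``target_band_snr_db`` of third-harmonic band
    SNR at the reference pressure (see :func:`derive_noise_floor_sd`).
    """

    f0: float = 1.5e6
    harmonic_amps_ref: tuple[float, ...] = (1.0, 0.3, 0.1, 0.03)
    p_ref_kPa: float = 200.0
    pressure_exponent: float = 1.0
    broadband_amp: float = 0.05
    onset_width_kPa: float = 10.0
    noise_floor_sd: float | None = None
    pulse_fluctuation_sd: float = 0.05
    gain_sd: float = 0.3
    inertial_threshold_kPa: float = 300.0
    sample_rate: float = DEFAULT_SAMPLE_RATE
    pulse_length_s: float = DEFAULT_PULSE_LENGTH_S
    broadband_band: tuple[float, float] = (2.5e6, 4.0e6)
    target_band_snr_db: float = 20.0
    snr_band_halfwidth: float = 2.0e4

    def __post_init__(self) -> None:
        for name in ("f0", "p_ref_kPa", "pressure_exponent", "broadband_amp",
                     "onset_width_kPa", "sample_rate", "pulse_length_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.pulse_fluctuation_sd < 0 or self.gain_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        lo, hi = self.broadband_band
        if not (0 < lo < hi <= self.sample_rate / 2):
            raise ValueError("broadband_band must lie within (0, Nyquist]")
        if self.noise_floor_sd is None:
            self.noise_floor_sd = derive_noise_floor_sd(self)
        if self.noise_floor_sd < 0:
            raise ValueError("noise_floor_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.sample_rate * self.pulse_length_s))


def derive_noise_floor_sd(config: PlantConfig) -> float:
    """Sensor-noise standard deviation giving the configured band SNR.

    For white Gaussian samples of standard deviation sigma, each interior
    rfft bin magnitude is Rayleigh with mean sigma·sqrt(N·pi/4), so the
    expected noise band sum over ``n_bins`` bins is
    ``n_bins · sigma · sqrt(N·pi/4)``. The third harmonic tone of amplitude A
    contributes A·N/2 to its band. Solving
    ``20·log10(tone / noise) = SNR`` for sigma gives the returned value.
    """
    n = int(round(config.sample_rate * config.pulse_length_s))
    df = config.sample_rate / n
    center = 3.0 * config.f0
    hw = config.snr_band_halfwidth
    freqs = np.arange(n // 2 + 1) * df
    n_bins = int(np.count_nonzero((freqs >= center - hw) & (freqs <= center + hw)))
    tone_sum = config.harmonic_amps_ref[2] * n / 2.0
    noise_sum = tone_sum / 10 ** (config.target_band_snr_db / 20.0)
    return float(noise_sum / (n_bins * math.sqrt(n * math.pi / 4.0)))


def sample_subjects(n: int, seed: int, config: PlantConfig | None = None) -> list[SubjectParams]:
    """Draw ``n`` synthetic subjects, deterministically for a given seed.

    Gains are lognormal(0, ``gain_sd``); each subject gets a private RNG
    stream derived from (master seed, subject index), so per-subject pulse
    sequences are reproducible regardless of how many subjects are drawn.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config if config is not None else PlantConfig()
    subjects = []
    for i in range(n):
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(i,))
        gain_child, pulse_child = ss.spawn(2)
        rng = np.random.default_rng(gain_child)
        gain = float(np.exp(rng.normal(0.0, config.gain_sd)))
        pulse_seed = int(pulse_child.generate_state(1)[0] & 0x7FFFFFFF)
        subjects.append(SubjectParams(
            gain=gain,
            inertial_threshold_kPa=config.inertial_threshold_kPa,
            seed=pulse_seed,
        ))
    return subjects


def infusion_factor(t_s: float, model: InfusionModel) -> float:
    """Microbubble availability m(t) in [0, 1], t since infusion start."""
    if t_s < 0:
        raise ValueError("t_s must be >= 0")
    if model.ramp_s == 0:
        return 1.0
    return min(t_s / model.ramp_s, 1.0)


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def emission_amplitudes(
    pressure_kPa: float,
    subject: SubjectParams,
    m: float,
    config: PlantConfig,
    jitter: float = 1.0,
) -> tuple[np.ndarray, float]:
    """(harmonic amplitudes f0..4f0, broadband amplitude) for one pulse.

    Harmonic k: ``gain · m · jitter · A_k · (p/p_ref)^alpha``; broadband:
    ``gain · m · jitter · B · logistic((p - threshold)/width)``. A pulse at
    exactly zero pressure emits nothing.
    """
    if pressure_kPa < 0:
        raise ValueError("pressure must be >= 0")
    amps = np.asarray(config.harmonic_amps_ref, dtype=float)
    if pressure_kPa == 0.0:
        return np.zeros_like(amps), 0.0
    scale = subject.gain * m * jitter
    harmonics = scale * amps * (pressure_kPa / config.p_ref_kPa) ** config.pressure_exponent
    onset = _logistic((pressure_kPa - subject.inertial_threshold_kPa)
                      / config.onset_width_kPa)
    broadband = scale * config.broadband_amp * onset
    return harmonics, float(broadband)


def _bandlimited_noise(rng: np.random.Generator, n: int, sample_rate: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-variance white noise passed through an ideal band filter.

    The filter only removes out-of-band power — no post-filter
    renormalization — so the in-band amplitude spectral density equals that
    of the original white noise. ``broadband_amp`` therefore sets the
    broadband component's in-band spectral level on the same per-sample
    scale as the sensor noise floor, which keeps the inertial-detection
    contour just below the subject's onset threshold rather than tens of
    kPa under it.
    """
    white = rng.standard_normal(n)
    xf = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    xf[(freqs < band[0]) | (freqs > band[1])] = 0.0
    return np.fft.irfft(xf, n=n)


def synth_trace(
    pressure_kPa: float,
    subject: SubjectParams,
    t_s: float,
    rng: np.random.Generator,
    config: PlantConfig | None = None,
    infusion: InfusionModel | None = None,
) -> PcdTrace:
    """Synthesize the PCD trace of one pulse.

    ``t_s`` is time since sonication start; bubble availability is evaluated
    at ``t_s + pre_delay_s`` on the infusion clock. Per pulse the stream is
    consumed in a fixed order — jitter, harmonic phases, broadband noise,
    sensor noise — so traces are reproducible for a given rng state.
    """
    config = config if config is not None else PlantConfig()
    infusion = infusion if infusion is not None else InfusionModel()
    if pressure_kPa < 0:
        raise ValueError("pressure must be >= 0")
    m = infusion_factor(t_s + infusion.pre_delay_s, infusion)

    jitter = 1.0
    if config.pulse_fluctuation_sd > 0:
        jitter = float(np.exp(rng.normal(0.0, config.pulse_fluctuation_sd)))
    harmonics, broadband = emission_amplitudes(pressure_kPa, subject, m, config, jitter)

    n = config.n_samples
    t = np.arange(n) / config.sample_rate
    x = np.zeros(n)
    if pressure_kPa > 0:
        phases = rng.uniform(0.0, 2.0 * math.pi, size=len(harmonics))
        for k, (amp, phi) in enumerate(zip(harmonics, phases), start=1):
            x += amp * np.sin(2.0 * math.pi * k * config.f0 * t + phi)
        if broadband > 0:
            x += broadband * _bandlimited_noise(rng, n, config.sample_rate,
                                                config.broadband_band)
    if config.noise_floor_sd > 0:
        x += config.noise_floor_sd * rng.standard_normal(n)

    return PcdTrace(samples=x, sample_rate=config.sample_rate,
                    pressure_kPa=pressure_kPa)


class SimulatedPulseSource:
    """Pulse source backed by the synthetic plant for one subject.

    Satisfies the controller's pressure-in / trace-out contract; the
    subject's private RNG stream advances one pulse at a time, so a session
    replayed from the same subject is bit-identical.
    """

    def __init__(self, subject: SubjectParams, config: PlantConfig | None = None,
                 infusion: InfusionModel | None = None):
        self.subject = subject
        self.config = config if config is not None else PlantConfig()
        self.infusion = infusion if infusion is not None else InfusionModel()
        self._rng = np.random.default_rng(subject.seed)

    def __call__(self, pressure_kPa: float, t_s: float) -> PcdTrace:
        return synth_trace(pressure_kPa, self.subject, t_s, self._rng,
                           self.config, self.infusion)
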