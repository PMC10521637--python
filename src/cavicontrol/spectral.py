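"""Spectral cavitation-dose metrics from passive cavitation detection (PCD).

During each focused-ultrasound (FUS) pulse a passive cavitation detector
records the acoustic emissions of circulating microbubbles. Sustained
low-amplitude bubble oscillation (stable cavitation) radiates at harmonics of
the 1.5 MHz drive frequency; violent bubble collapse (inertial cavitation)
radiates broadband noise. Two narrow-band magnitude sums quantify the two
regimes:

* **stable cavitation level** — sum of single-sided FFT magnitudes within
  ±20 kHz of the third harmonic (4.5 MHz), the harmonic closest to the PCD
  transducer's centre frequency;
* **inertial cavitation level** — the same sum within 3.3 ± 0.02 MHz, a band
  chosen between harmonics and ultraharmonics so it only picks up broadband
  emissions.

Both are expressed in dB relative to an *individual* baseline: the mean band
sum over ten low-pressure "dummy" pulses fired at the start of a session.
Referencing each subject to its own baseline absorbs inter-subject
differences in skull attenuation, microbubble dose and local vascularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_SAMPLE_RATE",
    "DEFAULT_PULSE_LENGTH_S",
    "PcdTrace",
    "Spectrum",
    "BandConfig",
    "Baseline",
    "CavitationReading",
    "compute_spectrum",
    "band_magnitude_sum",
    "level_db",
    "band_sums",
    "estimate_baseline",
    "analyze_pulse",
]

DEFAULT_SAMPLE_RATE = 40e6  # Hz
DEFAULT_PULSE_LENGTH_S = 6.7e-3  # s


@dataclass
class PcdTrace:
    """One pulse's sampled PCD voltage time series.

    Parameters
    ----------
    samples
        Voltage samples in arbitrary units (the absolute scale cancels in all
        baseline-referenced quantities).
    sample_rate
        Sampling rate in Hz. Default 40 MHz.
    pulse_index
        Position of the pulse within its session, 0-based.
    pressure_kPa
        Commanded peak-negative pressure for this pulse (kPa), as calibrated
        in water.
    """

    samples: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    pulse_index: int = 0
    pressure_kPa: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.pulse_index < 0:
            raise ValueError("pulse_index must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class Spectrum:
    """Single-sided magnitude spectrum with uniform bin spacing."""

    freqs: np.ndarray
    mags: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.mags = np.asarray(self.mags, dtype=np.float64)
        if self.freqs.shape != self.mags.shape:
            raise ValueError("freqs and mags must have the same shape")

    @property
    def df(self) -> float:
        """Bin spacing in Hz."""
        return float(self.freqs[1] - self.freqs[0])

    @property
    def nyquist(self) -> float:
        return float(self.freqs[-1])


@dataclass
class BandConfig:
    """Analysis bands and level conventions.

    ``stable_center`` defaults to the third harmonic of the FUS drive
    (3 × 1.5 MHz = 4.5 MHz); ``inertial_center`` sits at 3.3 MHz, between
    the second harmonic and the 5/2 ultraharmonic, so the band sum there
    responds to broadband emission only. Both bands are ±20 kHz.

    ``db_convention`` selects the dB definition applied to band-sum ratios:
    ``"amplitude"`` (20·log10, the default — magnitudes, not powers, are
    summed) or ``"power"`` (10·log10). ``baseline_average`` selects whether
    the dummy-pulse baseline is the mean of linear band sums (default) or the
    mean in dB (geometric mean of sums).
    """

    fus_frequency: float = 1.5e6
    stable_center: float | None = None
    stable_halfwidth: float = 2.0e4
    inertial_center: float = 3.3e6
    inertial_halfwidth: float = 2.0e4
    db_convention: str = "amplitude"
    baseline_average: str = "linear"
    gate: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.stable_center is None:
            self.stable_center = 3.0 * self.fus_frequency
        for name in ("fus_frequency", "stable_center", "stable_halfwidth",
                     "inertial_center", "inertial_halfwidth"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if (abs(self.stable_center - self.inertial_center)
                <= self.stable_halfwidth + self.inertial_halfwidth):
            raise ValueError("stable and inertial bands overlap")
        if self.db_convention not in ("amplitude", "power"):
            raise ValueError("db_convention must be 'amplitude' or 'power'")
        if self.baseline_average not in ("linear", "db"):
            raise ValueError("baseline_average must be 'linear' or 'db'")
        if self.gate is not None:
            a, b = self.gate
            if not (0.0 <= a < b <= 1.0):
                raise ValueError("gate must satisfy 0 <= start < stop <= 1")

    @property
    def db_factor(self) -> float:
        return 20.0 if self.db_convention == "amplitude" else 10.0


@dataclass
class Baseline:
    """Individual 0 dB reference from the dummy-sonication pulses."""

    stable_ref: float
    inertial_ref: float
    n_pulses: int = 10

    def __post_init__(self) -> None:
        if not (self.stable_ref > 0 and self.inertial_ref > 0):
            raise ValueError("baseline references must be positive")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")


@dataclass
class CavitationReading:
    """Per-pulse stable and inertial cavitation levels.

    ``stable_level_dB`` and ``inertial_level_dB`` are referenced to the
    session baseline: ``factor * log10(sum / ref)`` with ``factor`` set by the
    band configuration (20 by default).
    """

    stable_sum: float
    inertial_sum: float
    stable_level_dB: float
    inertial_level_dB: float
    pulse_index: int = 0
    pressure_kPa: float = 0.0


def compute_spectrum(trace: PcdTrace, gate: tuple[float, float] | None = None) -> Spectrum:
    """Single-sided magnitude spectrum of one pulse.

    A rectangular window over the full pulse is used (no taper); ``gate``
    optionally restricts the analysis to a ``(start, stop)`` fraction of the
    pulse, e.g. ``(0.1, 0.9)`` to drop transmit transients. Bin spacing is
    ``sample_rate / N`` with ``N`` the number of analysed samples.
    """
    x = trace.samples
    if gate is not None:
        a, b = gate
        if not (0.0 <= a < b <= 1.0):
            raise ValueError("gate must satisfy 0 <= start < stop <= 1")
        x = x[int(round(a * x.size)):int(round(b * x.size))]
        if x.size < 2:
            raise ValueError("gated trace too short")
    mags = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / trace.sample_rate)
    return Spectrum(freqs=freqs, mags=mags)


def band_magnitude_sum(spectrum: Spectrum, center: float, halfwidth: float) -> float:
    """Sum of spectral magnitudes over the closed band ``center ± halfwidth``.

    A bin contributes iff its centre frequency lies inside the closed
    interval. The band must lie within ``[0, Nyquist]``.
    """
    if not halfwidth > 0:
        raise ValueError("halfwidth must be positive")
    lo, hi = center - halfwidth, center + halfwidth
    if lo < 0 or hi > spectrum.nyquist:
        raise ValueError(
            f"band [{lo:g}, {hi:g}] Hz outside spectrum range [0, {spectrum.nyquist:g}] Hz"
        )
    mask = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    # sequential accumulation over the (few hundred) in-band bins, so the
    # result is independent of numpy's pairwise-summation blocking
    return float(sum(spectrum.mags[mask].tolist()))


def level_db(value: float, reference: float, factor: float = 20.0) -> float:
    """Level of ``value`` relative to ``reference`` in dB.

    ``factor`` is 20 for amplitude-like quantities (band magnitude sums,
    the default) or 10 for power-like quantities.
    """
    if not (value > 0 and reference > 0):
        raise ValueError("level_db requires positive value and reference")
    return factor * math.log10(value / reference)


def band_sums(trace: PcdTrace, bands: BandConfig) -> tuple[float, float]:
    """(stable, inertial) band magnitude sums for one pulse."""
    spec = compute_spectrum(trace, gate=bands.gate)
    stable = band_magnitude_sum(spec, bands.stable_center, bands.stable_halfwidth)
    inertial = band_magnitude_sum(spec, bands.inertial_center, bands.inertial_halfwidth)
    return stable, inertial


def estimate_baseline(
    traces: Sequence[PcdTrace],
    bands: BandConfig,
    n_expected: int = 10,
) -> Baseline:
    """Baseline from the dummy-sonication pulses.

    ``stable_ref`` and ``inertial_ref`` are the arithmetic means of the
    per-pulse linear band sums (or, with ``bands.baseline_average == "db"``,
    their geometric means, i.e. the mean taken in dB).
    """
    if len(traces) != n_expected:
        raise ValueError(
            f"expected {n_expected} dummy traces, got {len(traces)}"
        )
    pairs = [band_sums(t, bands) for t in traces]
    stable = np.array([p[0] for p in pairs], dtype=np.float64)
    inertial = np.array([p[1] for p in pairs], dtype=np.float64)
    if np.any(stable <= 0) or np.any(inertial <= 0):
        raise ValueError("dummy traces produced non-positive band sums")
    if bands.baseline_average == "linear":
        stable_ref, inertial_ref = stable.mean(), inertial.mean()
    else:
        stable_ref, inertial_ref = np.exp(np.log(stable).mean()), np.exp(np.log(inertial).mean())
    return Baseline(stable_ref=float(stable_ref), inertial_ref=float(inertial_ref),
                    n_pulses=n_expected)


def analyze_pulse(trace: PcdTrace, baseline: Baseline, bands: BandConfig) -> CavitationReading:
    """Stable and inertial cavitation levels of one pulse, re its baseline."""
    stable, inertial = band_sums(trace, bands)
    f = bands.db_factor
    return CavitationReading(
        stable_sum=stable,
        inertial_sum=inertial,
        stable_level_dB=level_db(stable, baseline.stable_ref, f),
        inertial_level_dB=level_db(inertial, baseline.inertial_ref, f),
        pulse_index=trace.pulse_index,
        pressure_kPa=trace.pressure_kPa,
    )
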