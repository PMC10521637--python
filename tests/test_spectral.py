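"""Spectral dose metrics: FFT, band sums, dB levels, baselines."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavicontrol import (
    BandConfig,
    Baseline,
    PcdTrace,
    Spectrum,
    analyze_pulse,
    band_magnitude_sum,
    compute_spectrum,
    estimate_baseline,
    level_db,
)
from .conftest import FAST_SAMPLE_RATE, make_tone_trace


def dft_magnitudes(x: np.ndarray) -> np.ndarray:
    """O(N^2) direct DFT magnitude oracle (single-sided)."""
    n = x.size
    k = np.arange(n // 2 + 1)
    t = np.arange(n)
    return np.abs((x[None, :] * np.exp(-2j * np.pi * k[:, None] * t[None, :] / n)).sum(axis=1))


@pytest.mark.parametrize("n,seed", [(256, 0), (256, 1), (512, 2), (257, 3)])
def test_spectrum_matches_direct_dft(n, seed):
    """FFT magnitudes equal the brute-force DFT sum to 1e-9 relative error."""
    rng = np.random.default_rng(seed)
    trace = PcdTrace(samples=rng.normal(size=n), sample_rate=1e6)
    spec = compute_spectrum(trace)
    expected = dft_magnitudes(trace.samples)
    np.testing.assert_allclose(spec.mags, expected, rtol=1e-9, atol=1e-9)
    assert spec.freqs[1] - spec.freqs[0] == pytest.approx(1e6 / n)


def test_dc_trace_concentrates_at_zero_frequency():
    trace = PcdTrace(samples=np.ones(1024), sample_rate=1e6)
    spec = compute_spectrum(trace)
    assert spec.mags[0] == pytest.approx(1024.0)
    assert np.all(np.abs(spec.mags[1:]) < 1e-9)


def test_pure_tone_occupies_single_bin():
    """An integer-cycle sinusoid puts all magnitude in its own bin."""
    trace = make_tone_trace({4.5e6: 2.0})
    spec = compute_spectrum(trace)
    k = int(round(4.5e6 / spec.df))
    assert spec.mags[k] == pytest.approx(2.0 * trace.samples.size / 2, rel=1e-9)
    others = np.delete(spec.mags, k)
    assert np.all(others < 1e-6 * spec.mags[k])


def test_trace_validation():
    with pytest.raises(ValueError):
        PcdTrace(samples=np.array([1.0]))
    with pytest.raises(ValueError):
        PcdTrace(samples=np.array([1.0, np.nan]))
    with pytest.raises(ValueError):
        PcdTrace(samples=np.ones(4), sample_rate=0.0)


def test_band_sum_matches_loop_oracle():
    rng = np.random.default_rng(42)
    n = 400
    spec = Spectrum(freqs=np.arange(n) * 1e3, mags=rng.random(n))
    center, hw = 150e3, 37e3
    expected = 0.0
    for f, m in zip(spec.freqs, spec.mags):
        if center - hw <= f <= center + hw:
            expected += m
    assert band_magnitude_sum(spec, center, hw) == expected


def test_band_sum_tone_in_and_out_of_band(bands):
    trace = make_tone_trace({4.5e6: 1.5})
    spec = compute_spectrum(trace)
    in_band = band_magnitude_sum(spec, bands.stable_center, bands.stable_halfwidth)
    out_band = band_magnitude_sum(spec, bands.inertial_center, bands.inertial_halfwidth)
    assert in_band == pytest.approx(1.5 * trace.samples.size / 2, rel=1e-9)
    assert out_band < 1e-6 * in_band


@settings(deadline=None, max_examples=25, derandomize=True)
@given(split=st.floats(min_value=0.05, max_value=0.95), seed=st.integers(0, 100))
def test_band_sum_additive_over_partitions(split, seed):
    """The sum over a band equals the sum over any two-piece partition."""
    rng = np.random.default_rng(seed)
    n = 256
    df = 1e3
    spec = Spectrum(freqs=np.arange(n) * df, mags=rng.random(n))
    lo, hi = 20e3, 180e3
    cut = lo + split * (hi - lo)
    # partition at a bin mid-point so no bin falls in both halves
    cut = (math.floor(cut / df) + 0.5) * df
    whole = band_magnitude_sum(spec, (lo + hi) / 2, (hi - lo) / 2)
    left = band_magnitude_sum(spec, (lo + cut) / 2, (cut - lo) / 2)
    right = band_magnitude_sum(spec, (cut + hi) / 2, (hi - cut) / 2)
    assert left + right == pytest.approx(whole, rel=1e-12)


def test_band_sum_errors():
    spec = Spectrum(freqs=np.arange(100) * 1e3, mags=np.ones(100))
    with pytest.raises(ValueError):
        band_magnitude_sum(spec, 95e3, 10e3)  # above Nyquist
    with pytest.raises(ValueError):
        band_magnitude_sum(spec, 5e3, 10e3)  # below zero
    with pytest.raises(ValueError):
        band_magnitude_sum(spec, 50e3, 0.0)


@pytest.mark.parametrize("value,ref,expected", [
    (1.0, 1.0, 0.0),
    (2.0, 1.0, 6.0205999132796239),
    (10.0, 1.0, 20.0),
    (1.0, 2.0, -6.0205999132796239),
])
def test_level_db_amplitude_convention(value, ref, expected):
    assert level_db(value, ref) == pytest.approx(expected, abs=1e-12)


def test_level_db_rejects_nonpositive():
    with pytest.raises(ValueError):
        level_db(0.0, 1.0)
    with pytest.raises(ValueError):
        level_db(1.0, -2.0)


def _dummy_traces(amplitudes, inertial_amp=0.2):
    return [make_tone_trace({4.5e6: a, 3.3e6: inertial_amp}, pulse_index=i)
            for i, a in enumerate(amplitudes)]


def test_estimate_baseline_is_arithmetic_mean(bands):
    """Band sums {1..10}·(n/2) average to 5.5·(n/2)."""
    traces = _dummy_traces([float(a) for a in range(1, 11)])
    baseline = estimate_baseline(traces, bands)
    n = traces[0].samples.size
    assert baseline.stable_ref == pytest.approx(5.5 * n / 2, rel=1e-9)
    assert baseline.n_pulses == 10


def test_estimate_baseline_identical_traces(bands):
    traces = _dummy_traces([2.0] * 10)
    baseline = estimate_baseline(traces, bands)
    n = traces[0].samples.size
    assert baseline.stable_ref == pytest.approx(2.0 * n / 2, rel=1e-9)


def test_estimate_baseline_wrong_count(bands):
    with pytest.raises(ValueError):
        estimate_baseline(_dummy_traces([1.0] * 9), bands)


def test_estimate_baseline_db_averaging():
    """dB-domain averaging gives the geometric mean of band sums."""
    bands = BandConfig(baseline_average="db")
    traces = _dummy_traces([1.0, 4.0] * 5)
    baseline = estimate_baseline(traces, bands)
    n = traces[0].samples.size
    assert baseline.stable_ref == pytest.approx(2.0 * n / 2, rel=1e-9)  # sqrt(1*4)


def test_analyze_pulse_doubled_harmonic(bands):
    """Doubling the third-harmonic amplitude reads +20·log10(2) dB."""
    baseline = estimate_baseline(_dummy_traces([1.0] * 10), bands)
    reading = analyze_pulse(make_tone_trace({4.5e6: 2.0, 3.3e6: 0.2}), baseline, bands)
    assert reading.stable_level_dB == pytest.approx(6.0206, abs=1e-3)
    assert reading.inertial_level_dB == pytest.approx(0.0, abs=1e-9)


def test_analyze_pulse_inertial_component(bands):
    """A 1.2x inertial-band component reads 20·log10(1.2) = +1.58 dB."""
    baseline = estimate_baseline(_dummy_traces([1.0] * 10), bands)
    reading = analyze_pulse(make_tone_trace({4.5e6: 1.0, 3.3e6: 0.24}), baseline, bands)
    assert reading.inertial_level_dB == pytest.approx(20 * math.log10(1.2), abs=1e-9)
    assert reading.stable_level_dB == pytest.approx(0.0, abs=1e-9)


def test_baseline_self_consistency(bands):
    """Dummy traces analyzed against their own baseline read 0 dB."""
    traces = _dummy_traces([3.0] * 10)
    baseline = estimate_baseline(traces, bands)
    for trace in traces:
        reading = analyze_pulse(trace, baseline, bands)
        assert abs(reading.stable_level_dB) < 1e-9
        assert abs(reading.inertial_level_dB) < 1e-9


@settings(deadline=None, max_examples=25, derandomize=True)
@given(c=st.floats(min_value=1e-3, max_value=1e3), seed=st.integers(0, 50))
def test_scale_covariance(c, seed):
    """Scaling all samples by c adds exactly 20·log10(c) to both levels."""
    bands = BandConfig()
    rng = np.random.default_rng(seed)
    base = make_tone_trace({4.5e6: 1.0, 3.3e6: 0.3})
    noisy = PcdTrace(samples=base.samples + 0.01 * rng.normal(size=base.samples.size),
                     sample_rate=base.sample_rate)
    baseline = estimate_baseline(_dummy_traces([1.0] * 10), bands)
    r0 = analyze_pulse(noisy, baseline, bands)
    scaled = PcdTrace(samples=c * noisy.samples, sample_rate=noisy.sample_rate)
    r1 = analyze_pulse(scaled, baseline, bands)
    shift = 20 * math.log10(c)
    assert r1.stable_level_dB - r0.stable_level_dB == pytest.approx(shift, abs=1e-8)
    assert r1.inertial_level_dB - r0.inertial_level_dB == pytest.approx(shift, abs=1e-8)


def test_power_convention_halves_levels():
    bands = BandConfig(db_convention="power")
    baseline = estimate_baseline(_dummy_traces([1.0] * 10), bands)
    reading = analyze_pulse(make_tone_trace({4.5e6: 2.0, 3.3e6: 0.2}), baseline, bands)
    assert reading.stable_level_dB == pytest.approx(10 * math.log10(2), abs=1e-9)


def test_gate_restricts_analysis_window():
    trace = make_tone_trace({4.5e6: 1.0})
    gated = compute_spectrum(trace, gate=(0.25, 0.75))
    assert gated.mags.size == trace.samples.size // 2 // 2 + 1


def test_band_config_rejects_overlapping_bands():
    with pytest.raises(ValueError):
        BandConfig(inertial_center=4.49e6)
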