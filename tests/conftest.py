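"""Shared fixtures: tone-trace builders and a fast plant configuration.

Most controller and end-to-end tests run the plant at a reduced scale
(10 MHz sampling, 1 ms pulses → 10,000 samples) chosen so every analysis
frequency still falls on an exact FFT bin (Δf = 1 kHz divides 1.5, 3.3 and
4.5 MHz) and the stable band stays below Nyquist. Full-protocol-scale
sessions (40 MHz, 6.7 ms) are exercised in the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from cavicontrol import BandConfig, ControllerConfig, PcdTrace, PlantConfig

FAST_SAMPLE_RATE = 10e6
FAST_PULSE_LENGTH_S = 1e-3


@pytest.fixture
def bands() -> BandConfig:
    return BandConfig()


@pytest.fixture
def fast_plant() -> PlantConfig:
    return PlantConfig(sample_rate=FAST_SAMPLE_RATE, pulse_length_s=FAST_PULSE_LENGTH_S)


@pytest.fixture
def fast_controller() -> ControllerConfig:
    return ControllerConfig(pulse_length_s=FAST_PULSE_LENGTH_S,
                            treatment_duration_s=30.0)


def make_tone_trace(
    tones: dict[float, float],
    n: int = 10_000,
    sample_rate: float = FAST_SAMPLE_RATE,
    pressure_kPa: float = 200.0,
    pulse_index: int = 0,
) -> PcdTrace:
    """Trace that is a sum of sinusoids {frequency_Hz: amplitude}.

    With the default n and rate every analysis frequency completes an
    integer number of cycles, so each tone lands on a single FFT bin with
    single-sided magnitude amplitude·n/2.
    """
    t = np.arange(n) / sample_rate
    x = np.zeros(n)
    for freq, amp in tones.items():
        x += amp * np.sin(2 * np.pi * freq * t)
    return PcdTrace(samples=x, sample_rate=sample_rate,
                    pressure_kPa=pressure_kPa, pulse_index=pulse_index)


@pytest.fixture
def tone_trace_factory():
    return make_tone_trace
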