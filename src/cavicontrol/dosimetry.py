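"""Derived protocol quantities: exposure timing and microbubble dosing.

Small closed-form helpers for the arithmetic that fixes the treatment
protocol — duty cycle, transcranial in situ pressure, contrast-agent
dilution — kept in one place so configuration files and reports agree on
the numbers.
"""

from __future__ import annotations

__all__ = [
    "duty_cycle",
    "in_situ_pressure",
    "diluted_concentration_per_mL",
    "pulses_in",
]


def duty_cycle(pulse_length_s: float, prf_Hz: float) -> float:
    """Transmit duty cycle (fraction): pulse length × PRF.

    Defaults of 6.7 ms at 2 Hz give 0.0134, i.e. 1.3 %.
    """
    if pulse_length_s <= 0 or prf_Hz <= 0:
        raise ValueError("pulse length and PRF must be positive")
    dc = pulse_length_s * prf_Hz
    if dc > 1:
        raise ValueError("duty cycle exceeds 1; check units")
    return dc


def in_situ_pressure(surface_pressure: float, attenuation_fraction: float = 0.18) -> float:
    """Pressure at the focus after skull attenuation.

    ``surface_pressure`` is the free-field (water-calibrated) peak-negative
    pressure; the mouse skull attenuates about 18 %, so 0.2 MPa in water is
    roughly 0.16 MPa in situ. Units are preserved.
    """
    if surface_pressure < 0 or not (0 <= attenuation_fraction < 1):
        raise ValueError("invalid pressure or attenuation fraction")
    return surface_pressure * (1.0 - attenuation_fraction)


def diluted_concentration_per_mL(
    agent_volume_mL: float = 1.3,
    agent_concentration_per_mL: float = 1.2e10,
    diluent_total_mL: float = 50.0,
) -> float:
    """Number concentration of a diluted microbubble suspension (per mL).

    The manufacturer-recommended infusion dose for activated Definity —
    1.3 mL of agent (≤ 1.2×10^10 microbubbles/mL) into 50 mL saline — gives
    3.12×10^8 microbubbles/mL.
    """
    if agent_volume_mL <= 0 or agent_concentration_per_mL <= 0 or diluent_total_mL <= 0:
        raise ValueError("all quantities must be positive")
    return agent_volume_mL * agent_concentration_per_mL / diluent_total_mL


def pulses_in(duration_s: float, prf_Hz: float) -> int:
    """Number of pulses transmitted in ``duration_s`` at ``prf_Hz``.

    The 5 s dummy sonication at 2 Hz comprises 10 baseline pulses.
    """
    if duration_s <= 0 or prf_Hz <= 0:
        raise ValueError("duration and PRF must be positive")
    return int(round(duration_s * prf_Hz))
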