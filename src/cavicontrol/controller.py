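"""Individualized closed-loop feedback control of the FUS output pressure.

The control law has three phases:

1. **Dummy** — ten pulses at a fixed low pressure (0.2 MPa) with microbubbles
   in circulation. Their mean stable and inertial band sums define the
   subject's individual 0 dB baseline; the dummy exposure is below the energy
   needed to open the blood-brain barrier, so the baseline is measured
   without treating.
2. **Ramp-up** — pressure increases pulse by pulse in 13 kPa steps (the
   waveform generator's minimum increment) until the measured stable
   cavitation level first reaches the target (0.5–4 dB above baseline).
3. **Maintain** — bang-bang regulation: if the level is inside
   target ± tolerance (±0.4 dB) the pressure is held; above the band it drops
   one step; below the band it rises one step. A maintain pulse inside the
   band is a *good pulse*.

Inertial cavitation is monitored and logged throughout but never alters the
control law; it serves purely as a safety readout.

:func:`run_session` closes the loop against any *pulse source* — an object
mapping a commanded pressure (and time) to a PCD trace. The built-in
synthetic plant (:mod:`cavicontrol.plant`) and a hardware front-end satisfy
the same contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Protocol

import numpy as np

from .session import Classification, Phase, PulseRecord, SessionLog
from .spectral import (
    BandConfig,
    Baseline,
    CavitationReading,
    PcdTrace,
    analyze_pulse,
    band_sums,
)

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "ControlDecision",
    "PulseSource",
    "start_session",
    "classify",
    "step",
    "run_session",
]


@dataclass
class ControllerConfig:
    """Controller constants for one treatment.

    Parameters
    ----------
    target_dB
        Target cavitation level, dB above the individual baseline stable
        cavitation level (study values: 0.5, 1, 2, 3, 4).
    tolerance_dB
        Half-width of the acceptance band around the target; ±0.4 dB reduces
        sensitivity to pulse-to-pulse noise.
    step_kPa
        Per-pulse pressure increment/decrement, 13 kPa (the minimum step of
        the driving waveform generator).
    dummy_pressure_kPa, dummy_pulses
        Dummy-sonication pressure (200 kPa) and pulse count (10 pulses = 5 s
        at 2 Hz).
    prf_Hz, pulse_length_s
        Pulse repetition frequency (2 Hz) and pulse length (6.7 ms), giving a
        1.3 % duty cycle.
    treatment_duration_s
        Duration of the post-dummy (ramp + maintain) sonication. Default
        120 s, consistent with a 30 µL infusion at 12.8 µL/min covering the
        session.
    pressure_cap_kPa, pressure_floor_kPa
        Safety clamps on the commanded pressure; a session that hits the cap
        is flagged.
    ramp_from_zero
        If True the first ramp pulse is transmitted at 0 kPa; by default the
        ramp starts one step up (13 kPa), since a 0 kPa pulse emits nothing.
    """

    target_dB: float = 2.0
    tolerance_dB: float = 0.4
    step_kPa: float = 13.0
    dummy_pressure_kPa: float = 200.0
    dummy_pulses: int = 10
    prf_Hz: float = 2.0
    pulse_length_s: float = 6.7e-3
    treatment_duration_s: float = 120.0
    pressure_cap_kPa: float = 1000.0
    pressure_floor_kPa: float = 0.0
    ramp_from_zero: bool = False

    def __post_init__(self) -> None:
        for name in ("target_dB", "tolerance_dB", "step_kPa", "dummy_pressure_kPa",
                     "prf_Hz", "pulse_length_s", "treatment_duration_s",
                     "pressure_cap_kPa"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.pressure_floor_kPa < 0:
            raise ValueError("pressure_floor_kPa must be >= 0")
        if self.dummy_pulses < 1:
            raise ValueError("dummy_pulses must be >= 1")
        if self.tolerance_dB >= self.target_dB:
            raise ValueError("tolerance_dB must be smaller than target_dB")
        if self.pressure_cap_kPa <= self.pressure_floor_kPa:
            raise ValueError("pressure_cap_kPa must exceed pressure_floor_kPa")

    @property
    def n_treatment_pulses(self) -> int:
        """Post-dummy pulse budget (ramp + maintain)."""
        return int(round(self.treatment_duration_s * self.prf_Hz))


@dataclass
class ControllerState:
    """Mutable controller state between pulses."""

    phase: Phase
    pressure_kPa: float
    pulses_in_phase: int = 0
    post_dummy_pulses: int = 0
    baseline: Optional[Baseline] = None
    dummy_stable_sums: list = field(default_factory=list)
    dummy_inertial_sums: list = field(default_factory=list)
    clamped: bool = False


@dataclass
class ControlDecision:
    """Outcome of processing one pulse's reading."""

    next_pressure_kPa: float
    classification: Classification
    phase_after: Phase
    good_pulse: Optional[bool] = None


class PulseSource(Protocol):
    """Contract: commanded pressure (kPa) and session time (s) in, trace out."""

    def __call__(self, pressure_kPa: float, t_s: float) -> PcdTrace: ...


def start_session(config: ControllerConfig) -> ControllerState:
    """Fresh controller state: dummy phase at the dummy pressure."""
    return ControllerState(phase=Phase.DUMMY, pressure_kPa=config.dummy_pressure_kPa)


def classify(stable_level_dB: float, config: ControllerConfig) -> Classification:
    """Position of a measured stable level relative to target ± tolerance.

    The band is closed: a level exactly on either boundary is IN_RANGE.
    """
    if not math.isfinite(stable_level_dB):
        raise ValueError("stable level must be finite")
    delta = stable_level_dB - config.target_dB
    if abs(delta) <= config.tolerance_dB:
        return Classification.IN_RANGE
    return Classification.LOW if delta < 0 else Classification.HIGH


def _clamp(pressure: float, config: ControllerConfig, state: ControllerState) -> float:
    lo, hi = config.pressure_floor_kPa, config.pressure_cap_kPa
    if pressure > hi:
        state.clamped = True
        return hi
    return max(lo, pressure)


def _baseline_from_sums(state: ControllerState, config: ControllerConfig,
                        bands: BandConfig) -> Baseline:
    s = np.asarray(state.dummy_stable_sums, dtype=float)
    i = np.asarray(state.dummy_inertial_sums, dtype=float)
    if np.any(s <= 0) or np.any(i <= 0):
        raise ValueError("dummy pulses produced non-positive band sums")
    if bands.baseline_average == "linear":
        stable_ref, inertial_ref = s.mean(), i.mean()
    else:
        stable_ref, inertial_ref = np.exp(np.log(s).mean()), np.exp(np.log(i).mean())
    return Baseline(stable_ref=float(stable_ref), inertial_ref=float(inertial_ref),
                    n_pulses=config.dummy_pulses)


def step(
    state: ControllerState,
    reading: CavitationReading,
    config: ControllerConfig,
    bands: BandConfig | None = None,
) -> tuple[ControllerState, ControlDecision]:
    """Advance the controller by one pulse.

    ``reading`` must have been produced at the pressure currently commanded
    by ``state``. Returns the updated state and the decision taken for the
    next pulse. Dummy readings only need valid band sums (their dB fields are
    ignored); ramp/maintain readings need ``stable_level_dB``.
    """
    bands = bands if bands is not None else BandConfig()
    if state.phase is Phase.DONE:
        raise RuntimeError("controller stepped after session end")
    if abs(reading.pressure_kPa - state.pressure_kPa) > 1e-9:
        raise ValueError(
            f"reading at {reading.pressure_kPa} kPa does not match commanded "
            f"{state.pressure_kPa} kPa"
        )

    state = replace(state,
                    dummy_stable_sums=list(state.dummy_stable_sums),
                    dummy_inertial_sums=list(state.dummy_inertial_sums))

    if state.phase is Phase.DUMMY:
        state.dummy_stable_sums.append(reading.stable_sum)
        state.dummy_inertial_sums.append(reading.inertial_sum)
        state.pulses_in_phase += 1
        if state.pulses_in_phase >= config.dummy_pulses:
            state.baseline = _baseline_from_sums(state, config, bands)
            state.phase = Phase.RAMP
            state.pulses_in_phase = 0
            first = 0.0 if config.ramp_from_zero else config.step_kPa
            state.pressure_kPa = _clamp(first, config, state)
            return state, ControlDecision(state.pressure_kPa, Classification.NA,
                                          Phase.RAMP)
        return state, ControlDecision(state.pressure_kPa, Classification.NA,
                                      Phase.DUMMY)

    # ramp / maintain share the pulse budget and end condition
    state.post_dummy_pulses += 1
    state.pulses_in_phase += 1
    ended = state.post_dummy_pulses >= config.n_treatment_pulses

    if state.phase is Phase.RAMP:
        if reading.stable_level_dB < config.target_dB:
            classification = Classification.NA
            good: Optional[bool] = None
            next_p = _clamp(state.pressure_kPa + config.step_kPa, config, state)
            phase_after = Phase.RAMP
        else:
            # target reached: this pulse is the last ramp pulse
            classification = Classification.NA
            good = None
            next_p = state.pressure_kPa
            phase_after = Phase.MAINTAIN
            state.pulses_in_phase = 0
    else:  # MAINTAIN
        classification = classify(reading.stable_level_dB, config)
        good = classification is Classification.IN_RANGE
        if classification is Classification.HIGH:
            next_p = _clamp(state.pressure_kPa - config.step_kPa, config, state)
        elif classification is Classification.LOW:
            next_p = _clamp(state.pressure_kPa + config.step_kPa, config, state)
        else:
            next_p = state.pressure_kPa
        phase_after = Phase.MAINTAIN

    if ended:
        phase_after = Phase.DONE
    state.phase = phase_after
    state.pressure_kPa = next_p
    return state, ControlDecision(next_p, classification, phase_after, good)


def run_session(
    config: ControllerConfig,
    pulse_source: PulseSource,
    bands: BandConfig | None = None,
    inertial_event_threshold_dB: float = 1.0,
    trace_sink: list | None = None,
) -> SessionLog:
    """Run one complete closed-loop treatment against a pulse source.

    The source is called once per pulse with the commanded pressure and the
    session time (seconds since the first dummy pulse); it returns the PCD
    trace for that pulse. With a deterministic source the log is bit-identical
    across runs. If the source raises, the log is finalized with the pulses
    recorded so far and ``status='source_error'``.

    ``trace_sink``, if given, receives every raw trace in pulse order (used
    to write trace archives for offline re-analysis).
    """
    bands = bands if bands is not None else BandConfig()
    state = start_session(config)
    log = SessionLog(target_dB=config.target_dB, tolerance_dB=config.tolerance_dB)
    pulse_idx = 0

    while state.phase is not Phase.DONE:
        t_s = pulse_idx / config.prf_Hz
        phase_now = state.phase
        try:
            trace = pulse_source(state.pressure_kPa, t_s)
        except Exception as exc:  # noqa: BLE001 - a dead source must not lose the log
            log.status = f"source_error: {exc}"
            break
        trace.pulse_index = pulse_idx
        trace.pressure_kPa = state.pressure_kPa
        if trace_sink is not None:
            trace_sink.append(trace)

        if phase_now is Phase.DUMMY:
            stable, inertial = band_sums(trace, bands)
            reading = CavitationReading(
                stable_sum=stable, inertial_sum=inertial,
                stable_level_dB=math.nan, inertial_level_dB=math.nan,
                pulse_index=pulse_idx, pressure_kPa=state.pressure_kPa,
            )
        else:
            reading = analyze_pulse(trace, state.baseline, bands)

        pressure_now = state.pressure_kPa
        state, decision = step(state, reading, config, bands)

        inertial_event = None
        if math.isfinite(reading.inertial_level_dB):
            inertial_event = reading.inertial_level_dB > inertial_event_threshold_dB

        log.records.append(PulseRecord(
            pulse_index=pulse_idx,
            time_s=t_s,
            phase=phase_now,
            pressure_kPa=pressure_now,
            stable_sum=reading.stable_sum,
            inertial_sum=reading.inertial_sum,
            stable_dB=reading.stable_level_dB,
            inertial_dB=reading.inertial_level_dB,
            classification=decision.classification,
            good_pulse=decision.good_pulse,
            inertial_event=inertial_event,
        ))
        pulse_idx += 1

    log.baseline = state.baseline
    log.clamped = state.clamped
    return log
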