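"""Feedback-control law: phases, classification, stepping, full sessions."""

import math

import numpy as np
import pytest

from cavicontrol import (
    BandConfig,
    Baseline,
    CavitationReading,
    Classification,
    ControllerConfig,
    ControllerState,
    Phase,
    PlantConfig,
    SimulatedPulseSource,
    SubjectParams,
    classify,
    good_pulse_rate,
    run_session,
    start_session,
    step,
)
from .conftest import FAST_PULSE_LENGTH_S, make_tone_trace


class StaticTonePlant:
    """Deterministic noiseless plant: third-harmonic amplitude ∝ pressure.

    The measured stable level is exactly 20·log10(p / dummy pressure), so
    controller trajectories have closed-form oracles.
    """

    def __init__(self, ref_pressure=200.0, ref_amp=0.1, inertial_amp=0.02):
        self.ref_pressure = ref_pressure
        self.ref_amp = ref_amp
        self.inertial_amp = inertial_amp

    def __call__(self, pressure_kPa, t_s):
        amp = self.ref_amp * pressure_kPa / self.ref_pressure
        return make_tone_trace({4.5e6: max(amp, 1e-12), 3.3e6: self.inertial_amp},
                               pressure_kPa=pressure_kPa)


class DeadPlant:
    """Emits a fixed weak tone regardless of pressure: never reaches target."""

    def __call__(self, pressure_kPa, t_s):
        return make_tone_trace({4.5e6: 0.1, 3.3e6: 0.02}, pressure_kPa=pressure_kPa)


def _cfg(**kw):
    kw.setdefault("pulse_length_s", FAST_PULSE_LENGTH_S)
    return ControllerConfig(**kw)


def _reading(level_db, pressure, inertial_db=0.0):
    return CavitationReading(stable_sum=1.0, inertial_sum=1.0,
                             stable_level_dB=level_db, inertial_level_dB=inertial_db,
                             pressure_kPa=pressure)


def _maintain_state(pressure):
    return ControllerState(phase=Phase.MAINTAIN, pressure_kPa=pressure,
                           baseline=Baseline(1.0, 1.0))


def test_start_session_is_dummy_at_dummy_pressure():
    state = start_session(_cfg())
    assert state.phase is Phase.DUMMY
    assert state.pressure_kPa == 200.0
    assert state.baseline is None


def test_config_validation():
    with pytest.raises(ValueError):
        _cfg(dummy_pulses=0)
    with pytest.raises(ValueError):
        _cfg(target_dB=0.3, tolerance_dB=0.4)  # tolerance must be < target
    with pytest.raises(ValueError):
        _cfg(step_kPa=-1)


def test_config_carries_target():
    assert _cfg(target_dB=2.0).target_dB == 2.0


@pytest.mark.parametrize("level,expected", [
    (2.0, Classification.IN_RANGE),
    (2.4, Classification.IN_RANGE),   # boundary inclusive
    (1.6, Classification.IN_RANGE),
    (2.41, Classification.HIGH),
    (1.5, Classification.LOW),
    (-3.0, Classification.LOW),
])
def test_classify_against_tolerance_band(level, expected):
    assert classify(level, _cfg(target_dB=2.0)) is expected


def test_classify_rejects_nonfinite():
    with pytest.raises(ValueError):
        classify(math.nan, _cfg())


def test_step_ramp_increases_by_one_step():
    cfg = _cfg(target_dB=2.0)
    state = ControllerState(phase=Phase.RAMP, pressure_kPa=195.0,
                            baseline=Baseline(1.0, 1.0))
    state, decision = step(state, _reading(1.2, 195.0), cfg)
    assert decision.next_pressure_kPa == 208.0
    assert decision.phase_after is Phase.RAMP


def test_step_ramp_exits_on_target_reached():
    cfg = _cfg(target_dB=2.0)
    state = ControllerState(phase=Phase.RAMP, pressure_kPa=247.0,
                            baseline=Baseline(1.0, 1.0))
    state, decision = step(state, _reading(2.1, 247.0), cfg)
    assert decision.phase_after is Phase.MAINTAIN
    assert decision.next_pressure_kPa == 247.0  # retained, not stepped


@pytest.mark.parametrize("level,expected_next,good", [
    (3.0, 237.0, False),   # HIGH -> step down
    (2.0, 250.0, True),    # IN_RANGE -> hold
    (1.0, 263.0, False),   # LOW -> step up
])
def test_step_maintain_bang_bang(level, expected_next, good):
    cfg = _cfg(target_dB=2.0)
    state, decision = step(_maintain_state(250.0), _reading(level, 250.0), cfg)
    assert decision.next_pressure_kPa == expected_next
    assert decision.good_pulse is good


def test_step_rejects_pressure_mismatch():
    with pytest.raises(ValueError):
        step(_maintain_state(250.0), _reading(2.0, 199.0), _cfg(target_dB=2.0))


def test_step_after_done_raises():
    state = ControllerState(phase=Phase.DONE, pressure_kPa=0.0)
    with pytest.raises(RuntimeError):
        step(state, _reading(2.0, 0.0), _cfg())


def test_dummy_phase_collects_baseline():
    cfg = _cfg(target_dB=2.0, dummy_pulses=3)
    state = start_session(cfg)
    for i in range(3):
        reading = CavitationReading(stable_sum=float(i + 1), inertial_sum=2.0,
                                    stable_level_dB=math.nan,
                                    inertial_level_dB=math.nan,
                                    pressure_kPa=200.0)
        state, decision = step(state, reading, cfg)
    assert state.phase is Phase.RAMP
    assert state.baseline.stable_ref == pytest.approx(2.0)  # mean of 1,2,3
    assert state.pressure_kPa == cfg.step_kPa  # first ramp pulse one step up


def test_session_ramp_is_arithmetic_with_13kPa_steps():
    cfg = _cfg(target_dB=2.0, treatment_duration_s=60.0)
    log = run_session(cfg, StaticTonePlant())
    ramp = [r.pressure_kPa for r in log.phase_records(Phase.RAMP)]
    diffs = np.diff(ramp)
    assert ramp[0] == 13.0
    assert np.all(diffs == 13.0)
    # ramp must end at the first pressure whose level reaches the target
    target_pressure = 200.0 * 10 ** (2.0 / 20.0)
    assert ramp[-1] >= target_pressure
    assert ramp[-2] < target_pressure


def test_session_pulse_counts():
    """5 s treatment at 2 Hz = 10 post-dummy pulses; 10 dummy records."""
    cfg = _cfg(target_dB=2.0, treatment_duration_s=5.0)
    log = run_session(cfg, StaticTonePlant())
    assert len(log.phase_records(Phase.DUMMY)) == 10
    post = [r for r in log.records if r.phase is not Phase.DUMMY]
    assert len(post) == 10
    assert len(log) == 20


def test_noiseless_convergence_full_good_pulse_rate():
    """Against a static monotone plant the maintain phase never leaves the
    band: one 13 kPa step changes the level by < 2x tolerance."""
    cfg = _cfg(target_dB=2.0, treatment_duration_s=60.0)
    log = run_session(cfg, StaticTonePlant())
    maintain = log.maintain_records
    assert len(maintain) > 50
    assert good_pulse_rate(log) == 100.0
    held = {r.pressure_kPa for r in maintain}
    assert len(held) == 1  # noiseless: pressure held constant


def test_maintain_pressure_changes_bounded(fast_plant):
    """With the stochastic plant every maintain step is -13, 0 or +13 kPa."""
    subject = SubjectParams(gain=1.0, seed=11)
    cfg = _cfg(target_dB=2.0, treatment_duration_s=45.0)
    log = run_session(cfg, SimulatedPulseSource(subject, fast_plant))
    maintain = log.maintain_records
    deltas = np.diff([r.pressure_kPa for r in maintain])
    assert set(np.round(deltas, 9)).issubset({-13.0, 0.0, 13.0})
    assert all(0.0 <= r.pressure_kPa <= cfg.pressure_cap_kPa for r in log.records)


def test_dead_plant_clamps_at_cap_and_flags():
    cfg = _cfg(target_dB=2.0, treatment_duration_s=60.0, pressure_cap_kPa=400.0)
    log = run_session(cfg, DeadPlant())
    assert log.clamped
    assert max(r.pressure_kPa for r in log.records) == 400.0
    # never exceeded the cap, never reached maintain
    assert not log.maintain_records


def test_session_determinism(fast_plant):
    """Same subject seed and config give bit-identical session logs."""
    cfg = _cfg(target_dB=2.0, treatment_duration_s=20.0)
    logs = []
    for _ in range(2):
        subject = SubjectParams(gain=1.1, seed=33)
        logs.append(run_session(cfg, SimulatedPulseSource(subject, fast_plant)))
    a, b = (l.to_dataframe() for l in logs)
    assert a.equals(b)


def test_source_failure_finalizes_log():
    calls = {"n": 0}

    def flaky(pressure_kPa, t_s):
        calls["n"] += 1
        if calls["n"] > 4:
            raise RuntimeError("probe unplugged")
        return make_tone_trace({4.5e6: 0.1, 3.3e6: 0.02}, pressure_kPa=pressure_kPa)

    log = run_session(_cfg(target_dB=2.0), flaky)
    assert len(log) == 4
    assert log.status.startswith("source_error")


def test_ramp_from_zero_option():
    cfg = _cfg(target_dB=2.0, ramp_from_zero=True, treatment_duration_s=30.0)
    log = run_session(cfg, StaticTonePlant())
    first_ramp = log.phase_records(Phase.RAMP)[0]
    assert first_ramp.pressure_kPa == 0.0
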