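"""Desk-scale experiment driver: targets × subjects → logs and summaries.

Mirrors the in vivo study design — several target cavitation levels, a small
cohort of subjects per target — entirely in silico. Each (target, subject)
pair runs one full closed-loop session against the synthetic plant; outputs
are per-pulse session logs, a per-session summary table, a per-target group
summary and a manifest recording every protocol constant, the configuration
and the master seed.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .controller import ControllerConfig, run_session
from .dosimetry import duty_cycle, in_situ_pressure
from .io import write_manifest, write_session_log, write_trace_archive
from .metrics import (
    DEFAULT_INERTIAL_EVENT_THRESHOLD_DB,
    session_summary,
    summaries_frame,
    summarize,
)
from .plant import InfusionModel, PlantConfig, SimulatedPulseSource, sample_subjects
from .session import Classification, Phase, PulseRecord, SessionLog
from .spectral import BandConfig, PcdTrace, analyze_pulse, band_sums, estimate_baseline
from .controller import classify

__all__ = ["run_experiment", "run_group", "reanalyze_archive", "build_manifest"]


def group_seed(master_seed: int, group_index: int) -> int:
    """Seed for one target group, derived from the master seed.

    Group 0 uses the master seed itself, so a single-target run is
    reproducible directly from the seed on the command line.
    """
    return int((master_seed + group_index) % 2**31)


def run_group(
    target_dB: float,
    n_subjects: int,
    seed: int,
    controller: ControllerConfig | None = None,
    plant: PlantConfig | None = None,
    bands: BandConfig | None = None,
    infusion: InfusionModel | None = None,
    trace_sinks: list | None = None,
) -> list[SessionLog]:
    """Run one target-level group of subjects; returns one log per subject."""
    controller = controller if controller is not None else ControllerConfig()
    plant = plant if plant is not None else PlantConfig()
    bands = bands if bands is not None else BandConfig()
    infusion = infusion if infusion is not None else InfusionModel()
    cfg = replace(controller, target_dB=float(target_dB),
                  pulse_length_s=plant.pulse_length_s)
    subjects = sample_subjects(n_subjects, seed, plant)
    logs = []
    for i, subject in enumerate(subjects):
        source = SimulatedPulseSource(subject, plant, infusion)
        sink = [] if trace_sinks is not None else None
        log = run_session(cfg, source, bands, trace_sink=sink)
        log.meta.update({
            "target_dB": float(target_dB),
            "subject": i,
            "gain": subject.gain,
            "inertial_threshold_kPa": subject.inertial_threshold_kPa,
            "group_seed": seed,
        })
        logs.append(log)
        if trace_sinks is not None:
            trace_sinks.append(sink)
    return logs


def run_experiment(
    config: RunConfig,
    out_dir: str | Path | None = None,
    save_traces: bool = False,
    strict: bool = False,
) -> tuple[list[SessionLog], pd.DataFrame, pd.DataFrame]:
    """Run targets × subjects; optionally write all outputs to ``out_dir``.

    Returns ``(logs, session_table, group_table)``. On disk (if requested):
    one CSV log per session, ``session_summaries.csv``,
    ``group_summary.csv``, ``manifest.json`` and, with ``save_traces``, one
    HDF5 trace archive per session (these are large at the full pulse
    length).
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    all_logs: list[SessionLog] = []
    for g, target in enumerate(config.targets):
        sinks: list | None = [] if save_traces else None
        logs = run_group(
            target, config.n_subjects, group_seed(config.seed, g),
            controller=config.controller, plant=config.plant,
            bands=config.bands, infusion=config.infusion,
            trace_sinks=sinks,
        )
        all_logs.extend(logs)
        if out is not None:
            for i, log in enumerate(logs):
                stem = f"session_target{target:g}dB_subject{i}"
                write_session_log(log, out / f"{stem}.csv")
                if save_traces:
                    write_trace_archive(out / f"{stem}.h5", sinks[i])

    session_table = summaries_frame(session_summary(l) for l in all_logs)
    group_table = summarize(all_logs, strict=strict)
    if out is not None:
        session_table.to_csv(out / "session_summaries.csv", index=False)
        group_table.to_csv(out / "group_summary.csv", index=False)
        write_manifest(out / "manifest.json", build_manifest(config))
    return all_logs, session_table, group_table


def build_manifest(config: RunConfig) -> dict:
    """Full record of a run: version, seed, configuration, protocol constants."""
    c, b, p = config.controller, config.bands, config.plant
    return {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "protocol": {
            "step_kPa": c.step_kPa,
            "tolerance_dB": c.tolerance_dB,
            "dummy_pressure_kPa": c.dummy_pressure_kPa,
            "dummy_pulses": c.dummy_pulses,
            "prf_Hz": c.prf_Hz,
            "pulse_length_s": c.pulse_length_s,
            "duty_cycle": duty_cycle(c.pulse_length_s, c.prf_Hz),
            "in_situ_dummy_pressure_kPa": in_situ_pressure(c.dummy_pressure_kPa),
            "sample_rate_Hz": p.sample_rate,
            "stable_band_Hz": [b.stable_center - b.stable_halfwidth,
                               b.stable_center + b.stable_halfwidth],
            "inertial_band_Hz": [b.inertial_center - b.inertial_halfwidth,
                                 b.inertial_center + b.inertial_halfwidth],
            "inertial_event_threshold_dB": DEFAULT_INERTIAL_EVENT_THRESHOLD_DB,
            "targets_dB": list(config.targets),
        },
    }


def reanalyze_archive(
    traces: list[PcdTrace],
    controller: ControllerConfig | None = None,
    bands: BandConfig | None = None,
    inertial_event_threshold_dB: float = DEFAULT_INERTIAL_EVENT_THRESHOLD_DB,
) -> SessionLog:
    """Offline re-analysis of an archived session.

    The first ``dummy_pulses`` traces are the dummy sonication (first-k
    convention); the baseline, phase boundaries, classifications and event
    flags are recomputed exactly as the online controller computes them, so
    re-analysis of an archive written during a simulated session reproduces
    the online session log.
    """
    controller = controller if controller is not None else ControllerConfig()
    bands = bands if bands is not None else BandConfig()
    k = controller.dummy_pulses
    if len(traces) < k:
        raise ValueError(
            f"archive has {len(traces)} pulses but {k} dummy pulses are expected"
        )
    if len(traces) == k:
        raise ValueError("archive contains only dummy pulses; nothing to analyze")

    baseline = estimate_baseline(traces[:k], bands, n_expected=k)
    log = SessionLog(target_dB=controller.target_dB,
                     tolerance_dB=controller.tolerance_dB, baseline=baseline)
    phase = Phase.DUMMY
    for i, trace in enumerate(traces):
        t_s = i / controller.prf_Hz
        if i < k:
            stable, inertial = band_sums(trace, bands)
            log.records.append(PulseRecord(
                pulse_index=i, time_s=t_s, phase=Phase.DUMMY,
                pressure_kPa=trace.pressure_kPa,
                stable_sum=stable, inertial_sum=inertial,
            ))
            continue
        if i == k:
            phase = Phase.RAMP
        reading = analyze_pulse(trace, baseline, bands)
        phase_now = phase
        if phase is Phase.RAMP:
            classification = Classification.NA
            good = None
            if reading.stable_level_dB >= controller.target_dB:
                phase = Phase.MAINTAIN  # this pulse is the last ramp pulse
        else:
            classification = classify(reading.stable_level_dB, controller)
            good = classification is Classification.IN_RANGE
        log.records.append(PulseRecord(
            pulse_index=i, time_s=t_s, phase=phase_now,
            pressure_kPa=trace.pressure_kPa,
            stable_sum=reading.stable_sum, inertial_sum=reading.inertial_sum,
            stable_dB=reading.stable_level_dB,
            inertial_dB=reading.inertial_level_dB,
            classification=classification, good_pulse=good,
            inertial_event=reading.inertial_level_dB > inertial_event_threshold_dB,
        ))
    return log
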