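"""Offline re-analysis of an archived session.

Simulates a session while archiving every raw PCD trace, re-reads the
archive and recomputes baseline, phases and metrics offline — the same path
a user would take with traces recorded from hardware.
"""

import tempfile
from pathlib import Path

from cavicontrol import (
    ControllerConfig,
    PlantConfig,
    SimulatedPulseSource,
    SubjectParams,
    good_pulse_rate,
    reanalyze_archive,
    run_session,
)
from cavicontrol.io import read_trace_archive, write_trace_archive

plant = PlantConfig(sample_rate=10e6, pulse_length_s=1e-3)  # reduced scale
config = ControllerConfig(target_dB=2.0, treatment_duration_s=30.0,
                          pulse_length_s=plant.pulse_length_s)
subject = SubjectParams(gain=1.1, seed=8)

traces = []
online = run_session(config, SimulatedPulseSource(subject, plant),
                     trace_sink=traces)

archive = Path(tempfile.mkdtemp()) / "session.h5"
write_trace_archive(archive, traces)
offline = reanalyze_archive(read_trace_archive(archive), config)

print(f"archive: {archive} ({len(traces)} pulses)")
print(f"online  GPR: {good_pulse_rate(online):.2f} %")
print(f"offline GPR: {good_pulse_rate(offline):.2f} %")
print(f"records identical: {online.to_dataframe().equals(offline.to_dataframe())}")

# The offline path identifies the first 10 pulses as the dummy sonication,
# recomputes the baseline and phase boundaries from the traces alone, and
# reproduces the online per-pulse records exactly.
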