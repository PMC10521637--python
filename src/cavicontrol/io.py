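"""On-disk formats: trace archives (HDF5), session logs (CSV), manifests.

Trace archives hold every raw PCD waveform of a session in one HDF5 file
(``samples[n_pulses][n_samples]`` float64 plus ``sample_rate`` and
``pressures_kPa``) and round-trip bit-exactly. Session logs are plain CSV
with a small ``# key=value`` metadata preamble, one header line and one row
per pulse; floats are written with ``repr`` so read→write→read is exact.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .session import Classification, Phase, PulseRecord, SessionLog
from .spectral import Baseline, PcdTrace

__all__ = [
    "write_trace_archive",
    "read_trace_archive",
    "write_session_log",
    "read_session_log",
    "write_manifest",
]

_LOG_COLUMNS = [
    "pulse_index", "time_s", "phase", "pressure_kPa", "stable_sum",
    "inertial_sum", "stable_dB", "inertial_dB", "classification",
    "good_pulse", "inertial_event",
]


def write_trace_archive(path: str | Path, traces: Sequence[PcdTrace]) -> None:
    """Write one session's raw traces to an HDF5 archive."""
    if not traces:
        raise ValueError("no traces to write")
    rates = {t.sample_rate for t in traces}
    if len(rates) != 1:
        raise ValueError("all traces in an archive must share one sample rate")
    lengths = {t.samples.size for t in traces}
    if len(lengths) != 1:
        raise ValueError("all traces in an archive must share one length")
    with h5py.File(path, "w") as f:
        f.create_dataset("samples",
                         data=np.stack([t.samples for t in traces]),
                         dtype=np.float64)
        f.create_dataset("pressures_kPa",
                         data=np.array([t.pressure_kPa for t in traces]))
        f.attrs["sample_rate"] = float(traces[0].sample_rate)


def read_trace_archive(path: str | Path) -> list[PcdTrace]:
    """Read a trace archive back into PcdTrace objects, in pulse order."""
    with h5py.File(path, "r") as f:
        if "sample_rate" not in f.attrs:
            raise ValueError(f"{path}: archive missing sample_rate")
        rate = float(f.attrs["sample_rate"])
        samples = f["samples"][...]
        pressures = f["pressures_kPa"][...]
    if samples.ndim != 2 or samples.shape[0] == 0:
        raise ValueError(f"{path}: empty or malformed archive")
    return [
        PcdTrace(samples=samples[i], sample_rate=rate, pulse_index=i,
                 pressure_kPa=float(pressures[i]))
        for i in range(samples.shape[0])
    ]


def _fmt_float(x: float) -> str:
    return repr(float(x))


def _fmt_optbool(b) -> str:
    return "" if b is None else str(int(b))


def _parse_optbool(s: str):
    return None if s == "" else bool(int(s))


def write_session_log(log: SessionLog, path: str | Path) -> None:
    """Write a SessionLog as CSV with a ``#`` metadata preamble."""
    path = Path(path)
    with path.open("w", newline="") as f:
        f.write(f"# target_dB={_fmt_float(log.target_dB)}\n")
        f.write(f"# tolerance_dB={_fmt_float(log.tolerance_dB)}\n")
        if log.baseline is not None:
            f.write(f"# baseline_stable={_fmt_float(log.baseline.stable_ref)}\n")
            f.write(f"# baseline_inertial={_fmt_float(log.baseline.inertial_ref)}\n")
            f.write(f"# baseline_n_pulses={log.baseline.n_pulses}\n")
        f.write(f"# clamped={int(log.clamped)}\n")
        f.write(f"# status={log.status}\n")
        for k, v in sorted(log.meta.items()):
            f.write(f"# meta.{k}={v}\n")
        writer = csv.writer(f)
        writer.writerow(_LOG_COLUMNS)
        for r in log.records:
            writer.writerow([
                r.pulse_index,
                _fmt_float(r.time_s),
                r.phase.value,
                _fmt_float(r.pressure_kPa),
                _fmt_float(r.stable_sum),
                _fmt_float(r.inertial_sum),
                _fmt_float(r.stable_dB),
                _fmt_float(r.inertial_dB),
                r.classification.value,
                _fmt_optbool(r.good_pulse),
                _fmt_optbool(r.inertial_event),
            ])


def _coerce_meta(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def read_session_log(path: str | Path) -> SessionLog:
    """Read a session-log CSV written by :func:`write_session_log`."""
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[PulseRecord] = []
    with path.open(newline="") as f:
        lines = []
        for line in f:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = val
            else:
                lines.append(line)
        reader = csv.reader(lines)
        cols = next(reader)
        if cols != _LOG_COLUMNS:
            raise ValueError(f"{path}: unexpected session-log columns {cols}")
        for row in reader:
            rows.append(PulseRecord(
                pulse_index=int(row[0]),
                time_s=float(row[1]),
                phase=Phase(row[2]),
                pressure_kPa=float(row[3]),
                stable_sum=float(row[4]),
                inertial_sum=float(row[5]),
                stable_dB=float(row[6]),
                inertial_dB=float(row[7]),
                classification=Classification(row[8]),
                good_pulse=_parse_optbool(row[9]),
                inertial_event=_parse_optbool(row[10]),
            ))
    baseline = None
    if "baseline_stable" in header:
        baseline = Baseline(
            stable_ref=float(header["baseline_stable"]),
            inertial_ref=float(header["baseline_inertial"]),
            n_pulses=int(header.get("baseline_n_pulses", 10)),
        )
    meta = {k[len("meta."):]: _coerce_meta(v)
            for k, v in header.items() if k.startswith("meta.")}
    return SessionLog(
        records=rows,
        target_dB=float(header.get("target_dB", "nan")),
        tolerance_dB=float(header.get("tolerance_dB", "nan")),
        baseline=baseline,
        clamped=bool(int(header.get("clamped", "0"))),
        status=header.get("status", "completed"),
        meta=meta,
    )


def write_manifest(path: str | Path, manifest: dict) -> None:
    """Write a run manifest (configuration, seed, version) as JSON."""
    with Path(path).open("w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True, default=str)
        f.write("\n")
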