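"""Session telemetry: per-pulse records and whole-treatment logs.

A :class:`SessionLog` is the complete record of one feedback-controlled
sonication — dummy, ramp-up and maintain phases — with one
:class:`PulseRecord` per transmitted pulse. It is the single exchange format
between the controller, the performance metrics and the on-disk CSV
representation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .spectral import Baseline

__all__ = ["Phase", "Classification", "PulseRecord", "SessionLog"]


class Phase(enum.Enum):
    """Controller phase a pulse was transmitted in."""

    DUMMY = "DUMMY"
    RAMP = "RAMP"
    MAINTAIN = "MAINTAIN"
    DONE = "DONE"


class Classification(enum.Enum):
    """Position of the measured stable level relative to the target band."""

    LOW = "LOW"
    IN_RANGE = "IN_RANGE"
    HIGH = "HIGH"
    NA = "NA"  # dummy / ramp pulses, where the band test does not apply


@dataclass
class PulseRecord:
    """Telemetry for a single transmitted pulse.

    ``stable_dB``/``inertial_dB`` are NaN for dummy pulses (the baseline that
    defines 0 dB does not exist yet). ``good_pulse`` is defined only in the
    maintain phase; ``inertial_event`` whenever a baseline exists.
    """

    pulse_index: int
    time_s: float
    phase: Phase
    pressure_kPa: float
    stable_sum: float
    inertial_sum: float
    stable_dB: float = math.nan
    inertial_dB: float = math.nan
    classification: Classification = Classification.NA
    good_pulse: Optional[bool] = None
    inertial_event: Optional[bool] = None


@dataclass
class SessionLog:
    """Ordered per-pulse records for one whole treatment."""

    records: list[PulseRecord] = field(default_factory=list)
    target_dB: float = math.nan
    tolerance_dB: float = math.nan
    baseline: Optional[Baseline] = None
    clamped: bool = False
    status: str = "completed"
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def phase_records(self, phase: Phase) -> list[PulseRecord]:
        return [r for r in self.records if r.phase is phase]

    @property
    def maintain_records(self) -> list[PulseRecord]:
        return self.phase_records(Phase.MAINTAIN)

    def to_dataframe(self) -> pd.DataFrame:
        """Per-pulse records as a pandas DataFrame (enums as strings)."""
        return pd.DataFrame(
            {
                "pulse_index": [r.pulse_index for r in self.records],
                "time_s": [r.time_s for r in self.records],
                "phase": [r.phase.value for r in self.records],
                "pressure_kPa": [r.pressure_kPa for r in self.records],
                "stable_sum": [r.stable_sum for r in self.records],
                "inertial_sum": [r.inertial_sum for r in self.records],
                "stable_dB": [r.stable_dB for r in self.records],
                "inertial_dB": [r.inertial_dB for r in self.records],
                "classification": [r.classification.value for r in self.records],
                "good_pulse": [r.good_pulse for r in self.records],
                "inertial_event": [r.inertial_event for r in self.records],
            }
        )
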