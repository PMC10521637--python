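"""Controller-performance and safety-surrogate metrics.

Two session-level quantities characterize a feedback-controlled treatment:

* **good pulse rate (GPR)** — the percentage of maintain-phase pulses whose
  stable cavitation level fell inside target ± tolerance; the controller's
  stability metric.
* **inertial cavitation probability (ICP)** — the percentage of
  maintain-phase pulses whose inertial cavitation level exceeded its
  baseline by more than 1 dB (strictly); a surrogate for vascular-damage
  risk.

Both exclude dummy and ramp pulses. Group summaries aggregate sessions per
target level with mean and sample (n−1) standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .session import Phase, SessionLog
from .spectral import CavitationReading

__all__ = [
    "DEFAULT_INERTIAL_EVENT_THRESHOLD_DB",
    "SessionSummary",
    "good_pulse_rate",
    "detect_inertial_event",
    "inertial_cavitation_probability",
    "session_summary",
    "summarize",
    "plot_session_levels",
    "plot_group_bars",
]

DEFAULT_INERTIAL_EVENT_THRESHOLD_DB = 1.0


@dataclass
class SessionSummary:
    """Per-session performance figures."""

    target_dB: float
    good_pulse_rate_pct: float
    inertial_cavitation_probability_pct: float
    n_maintain_pulses: int
    maintain_stable_dB_mean: float
    maintain_stable_dB_sd: float
    max_pressure_kPa: float
    baseline_stable: float
    baseline_inertial: float
    clamped: bool = False
    status: str = "completed"
    meta: dict = field(default_factory=dict)


def good_pulse_rate(log: SessionLog) -> float:
    """Percentage of maintain-phase pulses inside the target band."""
    maintain = log.maintain_records
    if not maintain:
        raise ValueError("session has no maintain-phase pulses")
    good = sum(1 for r in maintain if r.good_pulse)
    return 100.0 * good / len(maintain)


def detect_inertial_event(
    reading: CavitationReading,
    threshold_dB: float = DEFAULT_INERTIAL_EVENT_THRESHOLD_DB,
) -> bool:
    """True iff the inertial level is *over* ``threshold_dB`` above baseline.

    The comparison is strict: a level of exactly 1.0 dB is not an event.
    """
    if not math.isfinite(reading.inertial_level_dB):
        raise ValueError("inertial level must be finite")
    return reading.inertial_level_dB > threshold_dB


def inertial_cavitation_probability(log: SessionLog) -> float:
    """Percentage of maintain-phase pulses flagged as inertial events."""
    maintain = log.maintain_records
    if not maintain:
        raise ValueError("session has no maintain-phase pulses")
    events = sum(1 for r in maintain if r.inertial_event)
    return 100.0 * events / len(maintain)


def _sample_sd(values: Sequence[float]) -> float:
    """Sample (n−1) standard deviation, reported as 0 for a single value."""
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def session_summary(log: SessionLog) -> SessionSummary:
    """Collapse one SessionLog into its performance figures."""
    maintain = log.maintain_records
    levels = [r.stable_dB for r in maintain]
    return SessionSummary(
        target_dB=log.target_dB,
        good_pulse_rate_pct=good_pulse_rate(log),
        inertial_cavitation_probability_pct=inertial_cavitation_probability(log),
        n_maintain_pulses=len(maintain),
        maintain_stable_dB_mean=float(np.mean(levels)),
        maintain_stable_dB_sd=_sample_sd(levels),
        max_pressure_kPa=max(r.pressure_kPa for r in log.records),
        baseline_stable=log.baseline.stable_ref if log.baseline else math.nan,
        baseline_inertial=log.baseline.inertial_ref if log.baseline else math.nan,
        clamped=log.clamped,
        status=log.status,
        meta=dict(log.meta),
    )


def summaries_frame(summaries: Iterable[SessionSummary]) -> pd.DataFrame:
    """Tabulate per-session summaries (one row per session)."""
    rows = []
    for s in summaries:
        row = {
            "target_dB": s.target_dB,
            "good_pulse_rate_pct": s.good_pulse_rate_pct,
            "inertial_cavitation_probability_pct": s.inertial_cavitation_probability_pct,
            "n_maintain_pulses": s.n_maintain_pulses,
            "maintain_stable_dB_mean": s.maintain_stable_dB_mean,
            "maintain_stable_dB_sd": s.maintain_stable_dB_sd,
            "max_pressure_kPa": s.max_pressure_kPa,
            "baseline_stable": s.baseline_stable,
            "baseline_inertial": s.baseline_inertial,
            "clamped": s.clamped,
            "status": s.status,
        }
        row.update({f"meta_{k}": v for k, v in s.meta.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(logs: Iterable[SessionLog], strict: bool = False) -> pd.DataFrame:
    """Group summary: per-target mean and sample SD of each session metric.

    Rows are ordered by ascending target level. Sessions that ended clamped
    at the pressure cap stay flagged in the per-session table; with
    ``strict=True`` they are excluded from the group means.
    """
    summaries = [session_summary(log) for log in logs]
    if not summaries:
        raise ValueError("no sessions to summarize")
    if strict:
        summaries = [s for s in summaries if not s.clamped]
        if not summaries:
            raise ValueError("all sessions were clamped; nothing to summarize")
    df = summaries_frame(summaries)
    rows = []
    for target, grp in df.groupby("target_dB", sort=True):
        rows.append({
            "target_dB": target,
            "n_sessions": len(grp),
            "good_pulse_rate_mean_pct": grp["good_pulse_rate_pct"].mean(),
            "good_pulse_rate_sd_pct": _sample_sd(grp["good_pulse_rate_pct"].tolist()),
            "inertial_cavitation_probability_mean_pct":
                grp["inertial_cavitation_probability_pct"].mean(),
            "inertial_cavitation_probability_sd_pct":
                _sample_sd(grp["inertial_cavitation_probability_pct"].tolist()),
            "maintain_stable_dB_mean": grp["maintain_stable_dB_mean"].mean(),
            "maintain_stable_dB_sd": _sample_sd(grp["maintain_stable_dB_mean"].tolist()),
            "max_pressure_kPa_mean": grp["max_pressure_kPa"].mean(),
            "n_clamped": int(grp["clamped"].sum()),
        })
    return pd.DataFrame(rows)


def plot_session_levels(log: SessionLog, ax=None):
    """Stable/inertial level vs time for one session, with the target band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    df = log.to_dataframe()
    post = df[df["phase"] != Phase.DUMMY.value]
    ax.plot(post["time_s"], post["stable_dB"], lw=0.8, label="stable level")
    ax.plot(post["time_s"], post["inertial_dB"], lw=0.8, alpha=0.6,
            label="inertial level")
    if math.isfinite(log.target_dB):
        ax.axhline(log.target_dB, color="k", lw=0.8, ls="--")
        ax.axhspan(log.target_dB - log.tolerance_dB, log.target_dB + log.tolerance_dB,
                   color="k", alpha=0.1, label="target ± tolerance")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("level (dB re baseline)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_group_bars(group: pd.DataFrame, metric: str = "good_pulse_rate", ax=None):
    """Bar plot (mean ± SD) of a group metric across target levels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mean_col = f"{metric}_mean_pct"
    sd_col = f"{metric}_sd_pct"
    labels = [f"{t:g}" for t in group["target_dB"]]
    ax.bar(labels, group[mean_col], yerr=group[sd_col], capsize=4,
           color="#4878cf", alpha=0.85)
    ax.set_xlabel("target cavitation level (dB)")
    ax.set_ylabel(metric.replace("_", " ") + " (%)")
    return ax
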