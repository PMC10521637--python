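"""Run configuration: one structured text (YAML) file for a whole experiment.

Sections mirror the component configurations — ``controller``, ``plant``,
``bands``, ``infusion`` — plus an ``experiment`` section (targets, number of
subjects per target, master seed). Every field defaults to the study
protocol value, so an empty file reproduces the reference conditions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .controller import ControllerConfig
from .plant import InfusionModel, PlantConfig
from .spectral import BandConfig

__all__ = ["RunConfig", "load_run_config"]

DEFAULT_TARGETS = (0.5, 1.0, 2.0, 3.0, 4.0)


def _build(cls, overrides: dict | None):
    overrides = dict(overrides or {})
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    for key in ("harmonic_amps_ref", "broadband_band", "gate"):
        if key in overrides and overrides[key] is not None:
            overrides[key] = tuple(overrides[key])
    return cls(**overrides)


@dataclass
class RunConfig:
    """Everything one simulated experiment needs."""

    controller: ControllerConfig = field(default_factory=ControllerConfig)
    plant: PlantConfig = field(default_factory=PlantConfig)
    bands: BandConfig = field(default_factory=BandConfig)
    infusion: InfusionModel = field(default_factory=InfusionModel)
    targets: tuple[float, ...] = DEFAULT_TARGETS
    n_subjects: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.targets:
            raise ValueError("at least one target level is required")
        if any(t <= 0 for t in self.targets):
            raise ValueError("target levels must be positive (dB above baseline)")
        self.targets = tuple(float(t) for t in self.targets)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        exp = dict(raw.pop("experiment", {}) or {})
        kwargs = {
            "controller": _build(ControllerConfig, raw.pop("controller", None)),
            "plant": _build(PlantConfig, raw.pop("plant", None)),
            "bands": _build(BandConfig, raw.pop("bands", None)),
            "infusion": _build(InfusionModel, raw.pop("infusion", None)),
        }
        if raw:
            raise ValueError(f"unknown config sections: {sorted(raw)}")
        for key in ("targets", "n_subjects", "seed"):
            if key in exp:
                kwargs[key] = tuple(exp[key]) if key == "targets" else exp[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "controller": dataclasses.asdict(self.controller),
            "plant": dataclasses.asdict(self.plant),
            "bands": dataclasses.asdict(self.bands),
            "infusion": dataclasses.asdict(self.infusion),
            "experiment": {
                "targets": list(self.targets),
                "n_subjects": self.n_subjects,
                "seed": self.seed,
            },
        }

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; a missing path gives all defaults."""
    if path is None:
        return RunConfig()
    with Path(path).open() as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.from_dict(raw)
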