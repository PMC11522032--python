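"""Config schema and presets.

Experiments are described by a YAML document validated against the pydantic
models below.  Two geometry/protocol presets exist: ``mini`` (7 lattice
sites, 2 D-periods — the desk-scale system every test and sweep uses) and
``full`` (the cluster-scale fibril: 218-bead molecules, 20.2 nm diameter,
5 D-periods, 80 ns equilibration — provided for completeness, not exercised
by the test suite).
"""

from __future__ import annotations

from dataclasses import asdict
import yaml
from pydantic import BaseModel, Field, field_validator

from .builder import MINI_SPEC, FibrilSpec
from .crosslinker import CrosslinkConfig
from .engine import Protocol


class FibrilSection(BaseModel):
    beads_per_molecule: int | None = None
    r0: float | None = None
    diameter: float | None = None
    lattice_spacing: float | None = None
    d_period: float | None = None
    gap_fraction: float | None = None
    n_periods: int | None = None
    extension_beads: int | None = None
    clamp_beads: int | None = None
    waviness: float | None = None
    waviness_period: float | None = None
    seed: int | None = None


class CrosslinkSection(BaseModel):
    ecl_content: float = Field(0.0, ge=0.0, le=100.0)
    ecl_valence: str = "divalent"
    n_age: float = Field(0.0, ge=0.0)
    capture_radius: float = Field(24.0, gt=0.0)
    seed: int = 0

    @field_validator("ecl_valence")
    @classmethod
    def _valence(cls, v: str) -> str:
        if v not in ("divalent", "trivalent"):
            raise ValueError("ecl_valence must be 'divalent' or 'trivalent'")
        return v


class ProtocolSection(BaseModel):
    temperature: float | None = None
    equil_timestep: float | None = None
    equil_duration: float | None = None
    reequil_duration: float | None = None
    tensile_timestep: float | None = None
    pulling_speed: float | None = None
    damping: float | None = None
    thermostat_interval: int | None = None
    skin: float | None = None
    sample_interval: float | None = None
    max_strain: float | None = None
    stop_fraction: float | None = None
    seed: int | None = None
    deterministic: bool | None = None


class ExperimentConfig(BaseModel):
    """One fully specified run."""

    preset: str = "mini"
    fibril: FibrilSection = FibrilSection()
    crosslinks: CrosslinkSection = CrosslinkSection()
    protocol: ProtocolSection = ProtocolSection()
    forcefield_overrides: dict = {}
    output: str | None = None

    @field_validator("preset")
    @classmethod
    def _preset(cls, v: str) -> str:
        if v not in PRESETS:
            raise ValueError(f"unknown preset {v!r}; choose from {sorted(PRESETS)}")
        return v

    def fibril_spec(self) -> FibrilSpec:
        base = asdict(PRESETS[self.preset]["fibril"])
        base.update({k: v for k, v in self.fibril.model_dump().items() if v is not None})
        return FibrilSpec(**base)

    def crosslink_config(self) -> CrosslinkConfig:
        return CrosslinkConfig(**self.crosslinks.model_dump())

    def protocol_obj(self) -> Protocol:
        base = dict(PRESETS[self.preset]["protocol"])
        base.update({k: v for k, v in self.protocol.model_dump().items() if v is not None})
        return Protocol(**base)


class SweepConfig(BaseModel):
    """Grid of runs over cross-link densities and seeds."""

    n_age_values: list[float] = Field(min_length=1)
    ecl_contents: list[float] = Field(min_length=1)
    ecl_valences: list[str] = Field(default=["divalent"], min_length=1)
    seeds: list[int] = Field(default=[0], min_length=1)
    preset: str = "mini"
    output: str | None = None
    base: ExperimentConfig | None = None


#: preset geometry and protocol bundles
PRESETS: dict[str, dict] = {
    "mini": {
        "fibril": MINI_SPEC,
        "protocol": dict(
            temperature=300.0,
            equil_timestep=10.0,
            equil_duration=1.0e5,  # 0.1 ns
            reequil_duration=5.0e4,
            tensile_timestep=20.0,
            pulling_speed=1.0e-4,  # 10 m/s
            sample_interval=2000.0,
            max_strain=1.0,
        ),
    },
    "full": {
        "fibril": FibrilSpec(),
        "protocol": dict(
            temperature=300.0,
            equil_timestep=10.0,
            equil_duration=8.0e7,  # 80 ns
            reequil_duration=1.0e7,  # 10 ns
            tensile_timestep=1.0,
            pulling_speed=1.0e-4,
            sample_interval=10000.0,
            max_strain=1.0,
        ),
    },
}


def load_config(path) -> ExperimentConfig:
    """Parse and validate an experiment config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ExperimentConfig.model_validate(raw)


def load_sweep(path) -> SweepConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SweepConfig.model_validate(raw)
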