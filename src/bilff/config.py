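"""Run configuration: one human-readable YAML document per run.

All protocol constants are defaults here, never hard-coded in the
engine: 0.5 fs timestep, 800 pm LJ cutoff, 100 fs Nosé–Hoover
coupling, 2000 fs barostat coupling, 1 fs Berendsen coupling for the
500 K scramble stage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .molecules import Composition, build_molecule
from .units import ATM

__all__ = ["RunConfig", "StageConfig", "DEFAULT_STAGES"]


@dataclass
class StageConfig:
    """One protocol phase (ensemble, thermostat, duration)."""

    name: str
    ensemble: str  # nvt | npt
    thermostat: str
    temperature: float  # K
    duration_ps: float
    tau_t_fs: float = 100.0
    tau_p_fs: float = 2000.0
    pressure_atm: float = 1.0


DEFAULT_STAGES = [
    StageConfig("scramble", "nvt", "berendsen", 500.0, 25.0, tau_t_fs=1.0),
    StageConfig("densify", "npt", "nose-hoover", 350.0, 100.0),
    StageConfig("damp", "nvt", "langevin", 350.0, 5.0),
    StageConfig("production", "nvt", "nose-hoover", 350.0, 100.0),
]


@dataclass
class RunConfig:
    """Complete description of a simulation run."""

    composition: list[dict] = field(default_factory=list)  # {species, count}
    box_edge_pm: float = 2000.0
    forcefield_files: list[str] = field(default_factory=list)
    stages: list[StageConfig] = field(default_factory=lambda: [s for s in DEFAULT_STAGES])
    dt_fs: float = 0.5
    lj_cutoff_pm: float = 800.0
    electrostatics: str = "ewald"
    seed: int = 0
    stride: int = 20
    output_prefix: str = "run"

    def to_composition(self) -> Composition:
        items = [(build_molecule(c["species"]), int(c["count"])) for c in self.composition]
        return Composition(items, self.box_edge_pm)

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        stages = [StageConfig(**s) for s in d.pop("stages", [])]
        cfg = cls(**d)
        if stages:
            cfg.stages = stages
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())


def pressure_internal(p_atm: float) -> float:
    """Convert atm to internal kJ mol⁻¹ Å⁻³."""
    return p_atm * ATM
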