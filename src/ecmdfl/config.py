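"""Run configuration: validated JSON round-trip with filled defaults.

Units throughout: micrometres (lengths), seconds (time), nanonewtons
(forces).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .params import PhysicalParams

__all__ = ["SimulationConfig", "load_config", "save_config"]


@dataclass
class SimulationConfig:
    """Full description of one simulation / reduction run.

    ``dt`` is the integrator substep; ``record_every`` substeps make one
    recorded sample (the adhesion and polarity updates run at the recording
    cadence, which is the model's kinetic time step).
    """

    dt: float = 0.25
    t_end: float = 3600.0
    record_every: int = 4
    seed: int = 0
    network_seed: int | None = None  # fix the fiber network across runs that vary seed
    m_c: int = 50
    m_e: int = 50
    ridge: float = 1e-8
    domain: dict = field(default_factory=lambda: {"kind": "cylinder", "radius": 20.0, "length": 100.0})
    n_fibers: int = 48
    segments_per_fiber: int = 5
    crosslink_radius: float = 6.0
    cells: list = field(default_factory=list)  # [{"center": [x,y,z], "radius": r}, ...]
    params: PhysicalParams = field(default_factory=PhysicalParams)

    def __post_init__(self):
        if isinstance(self.params, dict):
            self.params = PhysicalParams.from_dict(self.params)
        self.validate()

    def validate(self) -> None:
        errs = []
        if self.dt <= 0:
            errs.append("dt: must be > 0")
        if self.t_end < self.dt:
            errs.append("t_end: must be >= dt")
        if self.record_every < 1:
            errs.append("record_every: must be >= 1")
        if self.m_c < 1:
            errs.append("m_c: latent dimension must be >= 1")
        if self.m_e < 1:
            errs.append("m_e: latent dimension must be >= 1")
        if self.n_fibers < 1 or self.segments_per_fiber < 1:
            errs.append("n_fibers/segments_per_fiber: must be >= 1")
        for c, cell in enumerate(self.cells):
            if "center" not in cell or "radius" not in cell:
                errs.append(f"cells[{c}]: needs 'center' and 'radius'")
        if errs:
            raise ValueError("invalid configuration: " + "; ".join(errs))

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    @property
    def sample_interval(self) -> float:
        return self.dt * self.record_every

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> SimulationConfig:
    """Load and validate a JSON configuration; defaults fill missing keys."""
    with open(path) as fh:
        text = fh.read().strip()
    if not text:
        required = sorted(SimulationConfig.__dataclass_fields__)
        raise ValueError(f"empty configuration file; recognised fields: {required}")
    return SimulationConfig.from_dict(json.loads(text))


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
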