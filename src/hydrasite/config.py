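"""Run configuration: every method threshold in one serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from . import constants as c

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    sasa_threshold: float = c.SASA_THRESHOLD
    location_cutoff: float = c.LOCATION_CUTOFF
    thermo_cutoff: float = c.THERMO_CUTOFF
    sigma: float = c.MIXTURE_SIGMA
    certainty_cutoff: float = c.CERTAINTY_CUTOFF
    linkage_threshold: float = c.LINKAGE_THRESHOLD
    cluster_weight_min: float = c.CLUSTER_WEIGHT_MIN
    occupancy_node_min: float = c.OCCUPANCY_NODE_MIN
    occupancy_loss_min: float = c.OCCUPANCY_LOSS_MIN
    first_layer_cutoff: float = c.FIRST_LAYER_CUTOFF
    displacement_tolerance: float = c.DISPLACEMENT_TOLERANCE
    grid_spacing: float = c.GRID_SPACING
    site_radius: float = c.SITE_RADIUS
    temperature: float = c.TEMPERATURE
    alpha: float = 0.1
    hidden: int = 32
    lr: float = 5e-3
    epochs: int = 300
    seed: int = 0
    units: str = "kcal/mol"          # internal unit; "kJ/mol" at reporting

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"invalid config key(s): {unknown}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
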