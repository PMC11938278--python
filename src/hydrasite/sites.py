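"""Shared hydration-site and water-prediction containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import TEMPERATURE

__all__ = ["WaterPrediction", "HydrationSite", "sites_to_arrays"]


@dataclass
class WaterPrediction:
    """A raw model output: predicted oxygen coordinate + certainty weight."""

    x: np.ndarray          # (3,) A
    w: float               # certainty in [0, 1]

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.shape != (3,) or not np.all(np.isfinite(self.x)):
            raise ValueError("prediction coordinate must be a finite 3-vector")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"certainty weight {self.w} outside [0, 1]")


@dataclass
class HydrationSite:
    """A hydration site: center plus optional occupancy and thermodynamics.

    ``dH`` and ``dS`` are the enthalpy and entropy changes for moving one
    water from bulk solvent into the site (kcal/mol and kcal/mol/K);
    ``dG = dH - T*dS`` at T = 300 K. ``weight`` carries the aggregated
    certainty for sites produced by the prediction pipeline.
    """

    center: np.ndarray
    occupancy: float | None = None
    dH: float | None = None
    dS: float | None = None
    weight: float | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=np.float64)
        if self.center.shape != (3,) or not np.all(np.isfinite(self.center)):
            raise ValueError("site center must be a finite 3-vector")

    def dG(self, temperature: float = TEMPERATURE) -> float:
        if self.dH is None or self.dS is None:
            raise ValueError("site has no thermodynamic labels")
        return self.dH - temperature * self.dS


def sites_to_arrays(sites: list[HydrationSite]) -> tuple[np.ndarray, np.ndarray]:
    """Split sites into (centers, occupancies); missing occupancy becomes 1."""
    centers = np.array([s.center for s in sites], dtype=np.float64).reshape(-1, 3)
    occ = np.array([1.0 if s.occupancy is None else s.occupancy
                    for s in sites], dtype=np.float64)
    return centers, occ
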