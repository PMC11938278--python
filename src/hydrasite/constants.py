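"""Physical constants and method defaults.

Energies are kept in kcal/mol internally; reporting boundaries (the MUP
benchmark, thermo CSV output with ``--units kJ/mol``) convert explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Gas constant in kcal / (mol K).
R_KCAL: float = 1.987204258640832e-3

#: Simulation / analysis temperature (K).
TEMPERATURE: float = 300.0

#: Concentration of pure water: 1 molecule per 29.9 A^3.
BULK_WATER_DENSITY: float = 1.0 / 29.9

#: Gaussian mixture standard deviation for the location loss (A).
MIXTURE_SIGMA: float = 0.5

KCAL_TO_KJ: float = 4.184


@dataclass(frozen=True)
class ThermoConstants:
    """Bundle of thermodynamic constants used across the package."""

    temperature: float = TEMPERATURE
    gas_constant: float = R_KCAL
    bulk_density: float = BULK_WATER_DENSITY
    sigma: float = MIXTURE_SIGMA


# Method defaults (each anchored to the published protocol).
SASA_THRESHOLD: float = 0.1          # fractional exposure gating water seeding
LOCATION_CUTOFF: float = 6.0         # A, location-model graph edges
THERMO_CUTOFF: float = 8.0           # A, thermo-model graph edges
CERTAINTY_CUTOFF: float = 0.035      # w_c, pre-clustering filter
LINKAGE_THRESHOLD: float = 2.0       # A, ward linkage distance threshold
CLUSTER_WEIGHT_MIN: float = 0.1      # final site gate on aggregated weight
OCCUPANCY_NODE_MIN: float = 0.3      # thermo-graph site-node filter
OCCUPANCY_LOSS_MIN: float = 0.5      # loss restriction (location + thermo)
FIRST_LAYER_CUTOFF: float = 3.5      # A, first/second hydration layer split
DISPLACEMENT_TOLERANCE: float = 2.4  # A, ligand water-displacement tolerance
GRID_SPACING: float = 0.25           # A, water density grid resolution
SITE_RADIUS: float = 1.0             # A, hydration-site radius
N_RBF: int = 32                      # RBF expansion size (edges and SASA)
N_EQUIVARIANT_LAYERS: int = 5
N_ATTENTION_LAYERS: int = 3
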