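"""Synthetic test fixtures: toy structures, planted sites, pseudo-trajectories.

The generator emulates the statistical shape of trajectory-derived hydration
data: protein-like heavy-atom structures, hydration sites planted at
hydrogen-bond geometry (2.8-3.0 A) off polar atoms, occupancies in [0, 1],
Gaussian positional spread per site, and smooth environment-determined
thermodynamic labels (more polar, more buried sites are enthalpically
stabilized; more mobile sites carry smaller entropy penalties). Structures
are geometric, not physically folded - every downstream contract is
geometric or statistical, so this is sufficient for testing; it does not
emulate force-field energetics or real conformational ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .sites import HydrationSite
from .structure_io import Atom, ProteinStructure, compute_sasa
from .trajectory_thermo import WaterTrajectory

__all__ = ["SyntheticSpec", "PlantedSite", "make_structure", "plant_sites",
           "make_trajectory", "toy_interaction_energy"]


@dataclass
class SyntheticSpec:
    n_residues: int = 8
    seed: int = 0
    site_offset_range: tuple[float, float] = (2.8, 3.0)  # H-bond geometry, A
    occupancy_range: tuple[float, float] = (0.35, 1.0)
    sigma_scale: float = 1.0            # scales per-site positional spread
    n_frames: int = 1000
    bulk_energy: float = -9.5           # kcal/mol, bulk water reference
    energy_noise: float = 0.2           # kcal/mol, per-observation jitter
    orientation_spread_deg: float | None = None  # None = uniform orientations
    max_sites: int | None = None


@dataclass
class PlantedSite(HydrationSite):
    """A planted reference site; ``sigma`` is its positional spread (A)."""

    sigma: float = 0.2


# Local heavy-atom template (offsets from CA, A). Deliberately inflated
# relative to covalent geometry so that *every* heavy-atom pair in the toy
# structure is >= 2 A apart (the generator's hard clash rule).
_TEMPLATE = {
    "N": np.array([2.05, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([-1.03, 1.78, 0.0]),
    "O": np.array([-2.055, 3.555, 0.0]),
    "CB": np.array([-1.0, -0.9, 1.6]),
    "TIP": np.array([-1.0, -2.13, 3.24]),
}

# residue -> (tip atom name, tip element); None = no tip atom
_RESIDUES: dict[str, tuple[str, str] | None] = {
    "GLY": None,
    "ALA": None,
    "SER": ("OG", "O"),
    "THR": ("OG1", "O"),
    "ASN": ("OD1", "O"),
    "ASP": ("OD1", "O"),
    "LYS": ("NZ", "N"),
    "LEU": ("CD1", "C"),
    "VAL": ("CG1", "C"),
    "PHE": ("CG", "C"),
}

_MIN_SEPARATION = 2.0   # A, hard heavy-atom clash limit


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_structure(spec: SyntheticSpec, max_retries: int = 200
                   ) -> ProteinStructure:
    """Self-avoiding extended backbone with templated sidechain dummy atoms.

    Guarantees: standard residue names, all heavy-atom pairs >= 2 A apart,
    bit-reproducible for a fixed seed.
    """
    if spec.n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(spec.seed)
    res_names = list(_RESIDUES)
    for _ in range(max_retries):
        atoms: list[Atom] = []
        coords: list[np.ndarray] = []
        ca_prev = np.zeros(3)
        direction = _random_unit(rng)
        ok = True
        for resi in range(1, spec.n_residues + 1):
            placed = False
            for _attempt in range(120):
                if resi == 1:
                    ca = np.zeros(3)
                else:
                    # persistent direction keeps the chain extended so the
                    # 2 A clash constraint is satisfiable
                    step = direction + 0.45 * rng.normal(size=3)
                    step /= np.linalg.norm(step)
                    ca = ca_prev + 3.8 * step
                rot = Rotation.random(random_state=rng).as_matrix()
                name = res_names[int(rng.integers(len(res_names)))]
                tip = _RESIDUES[name]
                res_atoms = []
                for atom_name, offset in _TEMPLATE.items():
                    if atom_name == "CB" and name == "GLY":
                        continue
                    if atom_name == "TIP":
                        if tip is None:
                            continue
                        pdb_name, element = tip
                    else:
                        pdb_name, element = atom_name, atom_name[0]
                    res_atoms.append((pdb_name, element, ca + rot @ offset))
                new_xyz = np.array([a[2] for a in res_atoms])
                if coords:
                    d = np.linalg.norm(
                        np.asarray(coords)[:, None, :] - new_xyz[None, :, :],
                        axis=-1)
                    if d.min() < _MIN_SEPARATION:
                        continue
                for pdb_name, element, xyz in res_atoms:
                    atoms.append(Atom(element=element, atom_name=pdb_name,
                                      residue_name=name, residue_index=resi,
                                      chain_id="A", coord=xyz))
                    coords.append(xyz)
                if resi > 1:
                    direction = (ca - ca_prev) / 3.8
                ca_prev = ca
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return ProteinStructure(atoms)
    raise RuntimeError("could not generate a clash-free structure; "
                       "spec may be unsatisfiable")


def _environment(center: np.ndarray, structure: ProteinStructure,
                 radius: float = 4.0) -> tuple[int, float]:
    coords = structure.coords
    d = np.linalg.norm(coords - center, axis=1)
    close = d <= radius
    n_close = int(close.sum())
    if n_close == 0:
        return 0, 0.0
    polar = np.array([e in ("N", "O") for e in structure.elements])
    return n_close, float(polar[close].mean())


def _thermo_rule(sigma: float, n_close: int, polar_frac: float
                 ) -> tuple[float, float]:
    """Smooth deterministic labels (kcal/mol): learnable from local geometry."""
    dH = -0.5 - 2.5 * polar_frac - 0.08 * n_close
    TdS = -1.8 + 4.0 * sigma
    return dH, TdS / 300.0   # (dH, dS)


def plant_sites(structure: ProteinStructure, spec: SyntheticSpec
                ) -> list[PlantedSite]:
    """Plant hydration sites at H-bond distance off polar (N/O) atoms.

    Site spread sigma increases with local hydrophobicity (mobile waters),
    and the entropy label increases monotonically with sigma; dH follows a
    smooth rule of neighbor count and polarity. Sites are pairwise > 2 A
    apart and clash-free against the protein.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    if structure.sasa is None:
        compute_sasa(structure)
    centroid = structure.coords.mean(axis=0)
    sites: list[PlantedSite] = []
    anchors = [i for i, a in enumerate(structure.atoms)
               if a.element in ("N", "O") and structure.sasa[i] > 0.1]
    for i in anchors:
        if spec.max_sites is not None and len(sites) >= spec.max_sites:
            break
        anchor = structure.atoms[i].coord
        outward = anchor - centroid
        norm = np.linalg.norm(outward)
        outward = outward / norm if norm > 1e-9 else _random_unit(rng)
        placed = None
        for _ in range(25):
            direction = outward + 0.35 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = rng.uniform(*spec.site_offset_range)
            candidate = anchor + dist * direction
            d_prot = np.linalg.norm(structure.coords - candidate, axis=1)
            if d_prot.min() < _MIN_SEPARATION:
                continue
            if not 2.75 <= np.linalg.norm(candidate - anchor) <= 3.05:
                continue
            if sites and min(np.linalg.norm(candidate - s.center)
                             for s in sites) <= _MIN_SEPARATION:
                continue
            placed = candidate
            break
        if placed is None:
            continue
        n_close, polar_frac = _environment(placed, structure)
        sigma = spec.sigma_scale * (0.15 + 0.15 * (1.0 - polar_frac))
        dH, dS = _thermo_rule(sigma, n_close, polar_frac)
        occ = rng.uniform(*spec.occupancy_range)
        sites.append(PlantedSite(center=placed, occupancy=float(occ),
                                 dH=dH, dS=dS, sigma=float(sigma)))
    return sites


def make_trajectory(sites: list[PlantedSite], spec: SyntheticSpec
                    ) -> WaterTrajectory:
    """Sample a pseudo-trajectory from planted sites.

    Per frame each site emits a water with probability equal to its
    occupancy, position Gaussian(center, sigma^2 I), orientation uniform on
    SO(3) (or concentrated when ``orientation_spread_deg`` is set), and an
    interaction energy bulk_energy + dH + noise so that the mean-minus-bulk
    enthalpy estimator recovers the planted dH.
    """
    if len(sites) == 0:
        raise ValueError("make_trajectory requires at least one site")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    mean_quats = Rotation.random(len(sites), random_state=rng)
    frames, energies, orientations = [], [], []
    for _ in range(spec.n_frames):
        xyz, ene, quat = [], [], []
        for k, s in enumerate(sites):
            if rng.random() >= s.occupancy:
                continue
            xyz.append(s.center + rng.normal(0.0, s.sigma, size=3))
            ene.append(spec.bulk_energy + s.dH
                       + rng.normal(0.0, spec.energy_noise))
            if spec.orientation_spread_deg is None:
                quat.append(Rotation.random(random_state=rng).as_quat())
            else:
                spread = np.deg2rad(spec.orientation_spread_deg)
                wobble = Rotation.from_rotvec(rng.normal(0, spread, size=3))
                quat.append((mean_quats[k] * wobble).as_quat())
        frames.append(np.array(xyz).reshape(-1, 3))
        energies.append(np.array(ene))
        orientations.append(np.array(quat).reshape(-1, 4))
    return WaterTrajectory(frames=frames, energies=energies,
                           orientations=orientations)


# Toy nonbonded evaluator so fixtures can carry self-consistent energies
# without any force field. Parameters are arbitrary but fixed.
_CHARGES = {"O": -0.40, "N": -0.35, "C": 0.08, "S": 0.0}
_LJ_EPS = 0.15      # kcal/mol
_LJ_SIGMA = 3.2     # A
_WATER_CHARGE = -0.80
_COULOMB_K = 332.06  # kcal A / (mol e^2)


def toy_interaction_energy(water_xyz: np.ndarray,
                           structure: ProteinStructure,
                           cutoff: float = 8.0) -> float:
    """Lennard-Jones + Coulomb water-protein interaction (kcal/mol)."""
    water_xyz = np.asarray(water_xyz, dtype=np.float64)
    coords = structure.coords
    d = np.linalg.norm(coords - water_xyz, axis=1)
    mask = (d < cutoff) & (d > 1e-6)
    d = d[mask]
    if len(d) == 0:
        return 0.0
    q = np.array([_CHARGES.get(e, 0.0)
                  for e, m in zip(structure.elements, mask) if m])
    sr6 = (_LJ_SIGMA / d) ** 6
    lj = 4.0 * _LJ_EPS * (sr6 ** 2 - sr6)
    coul = _COULOMB_K * _WATER_CHARGE * q / d
    return float(np.sum(lj + coul))
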