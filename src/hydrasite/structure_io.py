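"""Protein structure parsing, solvent accessibility and node featurization.

The location and thermodynamics models both consume protein heavy atoms
described by a 92-dimensional feature vector: a 38-slot one-hot over PDB
heavy-atom name classes, a 21-slot one-hot over residue types (20 standard
amino acids + other), a 32-center radial-basis expansion of the fractional
solvent-accessible surface area (SASA), and a single atom/water flag.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .constants import N_RBF

__all__ = [
    "Atom", "ProteinStructure", "ParseError", "parse_structure",
    "parse_ligand", "structure_to_pdb", "compute_sasa", "featurize",
    "water_feature_vector", "sasa_table", "ATOM_VOCAB", "RESIDUE_VOCAB",
    "FEATURE_DIM",
]


class ParseError(ValueError):
    """Raised for unusable PDB input."""


@dataclass
class Atom:
    element: str
    atom_name: str
    residue_name: str
    residue_index: int
    chain_id: str
    coord: np.ndarray

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=np.float64)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.atom_name}: invalid coordinate")


@dataclass
class ProteinStructure:
    atoms: list[Atom]
    sasa: np.ndarray | None = field(default=None)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=np.float64)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def __len__(self) -> int:
        return len(self.atoms)


# Fixed heavy-atom name vocabulary: 37 named PDB atom classes covering the
# 20 standard amino acids, plus one reserved "other" slot (38 total).
ATOM_VOCAB: list[str] = [
    "N", "CA", "C", "O", "OXT", "CB",
    "CG", "CG1", "CG2", "CD", "CD1", "CD2",
    "CE", "CE1", "CE2", "CE3", "CZ", "CZ2", "CZ3", "CH2",
    "ND1", "ND2", "NE", "NE1", "NE2", "NZ", "NH1", "NH2",
    "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH",
    "SD", "SG",
]
ATOM_OTHER = len(ATOM_VOCAB)  # slot 37 (38th)

RESIDUE_VOCAB: list[str] = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
RESIDUE_OTHER = len(RESIDUE_VOCAB)  # slot 20 (21st)

N_ATOM_TYPES = ATOM_OTHER + 1       # 38
N_RESIDUE_TYPES = RESIDUE_OTHER + 1  # 21
FEATURE_DIM = N_ATOM_TYPES + N_RESIDUE_TYPES + N_RBF + 1  # 92

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "TIP", "TIP3", "SPC", "SOL"}
_ION_RESNAMES = {"NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "BR", "IOD"}

# Bondi van der Waals radii (A) for protein heavy atoms.
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}


def _validate_coordinates(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldstr = line[lo:hi].strip()
                try:
                    float(fieldstr)
                except ValueError:
                    raise ParseError(
                        f"malformed coordinate field {fieldstr!r} on line {lineno}"
                    ) from None


def parse_structure(pdb_text: str, keep_hydrogens: bool = False) -> ProteinStructure:
    """Parse PDB text into a heavy-atom protein structure.

    Hydrogens are removed unless ``keep_hydrogens``; HETATM records (waters,
    ions, ligands) are excluded. Alternate locations are resolved by keeping
    the highest-occupancy conformer; multi-chain files are read as one atom
    set. Raises :class:`ParseError` for empty input or malformed coordinates.
    """
    if not any(line.startswith("ATOM") for line in pdb_text.splitlines()):
        raise ParseError("no ATOM records found in PDB input")
    _validate_coordinates(pdb_text)
    pdb_file = pdb.PDBFile.read(io.StringIO(pdb_text))
    array = pdb_file.get_structure(model=1, altloc="occupancy")
    mask = ~array.hetero
    if not keep_hydrogens:
        mask &= array.element != "H"
    array = array[mask]
    if array.array_length() == 0:
        raise ParseError("no usable ATOM records after filtering")
    atoms = [
        Atom(element=str(e), atom_name=str(n), residue_name=str(r),
             residue_index=int(ri), chain_id=str(c), coord=xyz)
        for e, n, r, ri, c, xyz in zip(
            array.element, array.atom_name, array.res_name,
            array.res_id, array.chain_id, array.coord)
    ]
    return ProteinStructure(atoms)


def parse_ligand(pdb_text: str) -> np.ndarray:
    """Extract ligand heavy-atom coordinates (HETATM, waters/ions excluded)."""
    pdb_file = pdb.PDBFile.read(io.StringIO(pdb_text))
    array = pdb_file.get_structure(model=1, altloc="occupancy")
    mask = (array.element != "H")
    resnames = np.char.upper(array.res_name.astype(str))
    mask &= ~np.isin(resnames, sorted(_WATER_RESNAMES | _ION_RESNAMES))
    if array.hetero.any():
        mask &= array.hetero
    coords = array.coord[mask]
    if len(coords) == 0:
        raise ParseError("no ligand heavy atoms found")
    return np.asarray(coords, dtype=np.float64)


def structure_to_pdb(structure: ProteinStructure) -> str:
    """Serialize a structure back to PDB text (fixtures, round-trips)."""
    array = struc.AtomArray(len(structure))
    for i, a in enumerate(structure.atoms):
        array.coord[i] = a.coord
        array.chain_id[i] = a.chain_id
        array.res_id[i] = a.residue_index
        array.res_name[i] = a.residue_name
        array.atom_name[i] = a.atom_name
        array.element[i] = a.element
        array.hetero[i] = False
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(array)
    out = io.StringIO()
    pdb_file.write(out)
    return out.getvalue()


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere point set."""
    i = np.arange(n, dtype=np.float64) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def compute_sasa(structure: ProteinStructure, probe_radius: float = 1.4,
                 n_sphere_points: int = 960,
                 point_rotation: np.ndarray | None = None) -> np.ndarray:
    """Per-atom fractional SASA by the Shrake-Rupley method.

    The fraction is the share of ``n_sphere_points`` test points on the
    probe-expanded sphere of each atom that are not occluded by any other
    atom's probe-expanded sphere; multiplying by 4*pi*(r_vdw+probe)^2 gives
    the absolute area. The point set is fixed, so results are deterministic;
    ``point_rotation`` rotates the test points (used to express the rigid-
    motion convention: rotating structure and point set together is exact).
    """
    if len(structure) == 0:
        raise ValueError("structure has no atoms")
    unknown = sorted({e.upper() for e in structure.elements}
                     - set(VDW_RADII))
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {unknown}")
    radii = np.array([VDW_RADII[e.upper()] for e in structure.elements])
    coords = structure.coords
    expanded = radii + probe_radius
    points = _sphere_points(n_sphere_points)
    if point_rotation is not None:
        points = points @ np.asarray(point_rotation).T
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    fractions = np.empty(len(structure))
    for i in range(len(structure)):
        sphere = coords[i] + expanded[i] * points
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach)
                     if j != i]
        free = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((sphere - coords[j]) ** 2, axis=1)
            free &= d2 > expanded[j] ** 2
        fractions[i] = free.mean()
    structure.sasa = fractions
    return fractions


def rbf_expand_scalar(values: np.ndarray, n_centers: int = N_RBF,
                      lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Gaussian RBF expansion with centers evenly spaced on [lo, hi]."""
    if not lo < hi:
        raise ValueError("rbf range requires lo < hi")
    values = np.asarray(values, dtype=np.float64)
    if np.any(~np.isfinite(values)):
        raise ValueError("rbf_expand received non-finite input")
    centers = np.linspace(lo, hi, n_centers)
    width = centers[1] - centers[0]
    return np.exp(-((values[..., None] - centers) ** 2) / width ** 2)


def _atom_slot(atom_name: str) -> int:
    try:
        return ATOM_VOCAB.index(atom_name.upper())
    except ValueError:
        return ATOM_OTHER


def _residue_slot(res_name: str) -> int:
    try:
        return RESIDUE_VOCAB.index(res_name.upper())
    except ValueError:
        return RESIDUE_OTHER


def featurize(structure: ProteinStructure, node_type: str = "atom") -> np.ndarray:
    """Build the (N, 92) node feature matrix for protein atoms.

    Requires SASA; unknown atom names / residues fall into the reserved
    "other" slots. ``node_type="water"`` sets the trailing flag to 1 (used
    when features are attached to water nodes seeded at atom positions).
    """
    if structure.sasa is None:
        raise ValueError("compute_sasa must run before featurize")
    n = len(structure)
    feats = np.zeros((n, FEATURE_DIM))
    for i, a in enumerate(structure.atoms):
        feats[i, _atom_slot(a.atom_name)] = 1.0
        feats[i, N_ATOM_TYPES + _residue_slot(a.residue_name)] = 1.0
    offset = N_ATOM_TYPES + N_RESIDUE_TYPES
    feats[:, offset:offset + N_RBF] = rbf_expand_scalar(
        np.asarray(structure.sasa, dtype=np.float64))
    feats[:, -1] = 1.0 if node_type == "water" else 0.0
    return feats


def water_feature_vector() -> np.ndarray:
    """Feature vector for a free water node (site node in the thermo graph)."""
    v = np.zeros(FEATURE_DIM)
    v[ATOM_OTHER] = 1.0
    v[N_ATOM_TYPES + RESIDUE_OTHER] = 1.0
    offset = N_ATOM_TYPES + N_RESIDUE_TYPES
    v[offset:offset + N_RBF] = rbf_expand_scalar(np.array(0.0))
    v[-1] = 1.0
    return v


def sasa_table(structure: ProteinStructure) -> str:
    """Per-atom SASA as CSV text (chain, resi, atom, sasa)."""
    if structure.sasa is None:
        raise ValueError("compute_sasa must run before sasa_table")
    lines = ["chain,resi,atom,sasa"]
    for a, s in zip(structure.atoms, structure.sasa):
        lines.append(f"{a.chain_id},{a.residue_index},{a.atom_name},{s:.6f}")
    return "\n".join(lines) + "\n"
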