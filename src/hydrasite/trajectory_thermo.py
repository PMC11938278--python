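"""Trajectory-based hydration-site thermodynamics.

Water-oxygen observations from a (pseudo-)trajectory are binned onto a
0.25 A density grid; hydration sites of radius 1 A are extracted greedily
from density peaks; per site we compute

* occupancy - fraction of frames with a water inside the site radius,
* dH        - mean water interaction energy in the site minus the bulk
              reference (interaction energies are inputs: in production
              they come from MD post-processing, in tests from the
              synthetic generator),
* dS        - entropy change from discretized integration of the external-
              mode probability density of the site waters' translations
              and rotations, referenced to bulk density C = 1/29.9 A^-3
              and a uniform (Haar) orientation distribution,
* dG = dH - T*dS at T = 300 K.

Both entropy terms are (negative) Kullback-Leibler-type integrals
-R * integral p ln(p / p_bulk), so a water as diffuse as bulk loses
nothing and increasingly localized/oriented waters lose more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import (BULK_WATER_DENSITY, GRID_SPACING, R_KCAL, SITE_RADIUS,
                        TEMPERATURE)
from .sites import HydrationSite

__all__ = [
    "WaterTrajectory", "DensityGrid", "accumulate_density", "extract_sites",
    "occupancy", "site_observations", "site_enthalpy", "site_entropy",
    "free_energy", "analyze_trajectory",
]


@dataclass
class WaterTrajectory:
    """Per-frame water oxygen coordinates with optional energies/orientations."""

    frames: list[np.ndarray]                      # each (k_i, 3)
    energies: list[np.ndarray] | None = None      # each (k_i,), kcal/mol
    orientations: list[np.ndarray] | None = None  # each (k_i, 4) unit quats

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("trajectory must contain at least one frame")
        self.frames = [np.asarray(f, dtype=np.float64).reshape(-1, 3)
                       for f in self.frames]
        for f in self.frames:
            if not np.all(np.isfinite(f)):
                raise ValueError("non-finite water coordinate in trajectory")

    @property
    def frame_count(self) -> int:
        return len(self.frames)


@dataclass
class DensityGrid:
    origin: np.ndarray
    spacing: float
    counts: np.ndarray                       # (nx, ny, nz) observation counts
    frame_count: int = field(default=1)

    def voxel_centers(self, index: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(index) + 0.5) * self.spacing


def accumulate_density(traj: WaterTrajectory, spacing: float = GRID_SPACING,
                       bounds: tuple[np.ndarray, np.ndarray] | None = None
                       ) -> DensityGrid:
    """Bin all (frame, water) observations onto a regular grid.

    Conservation: the summed voxel counts equal the number of in-bounds
    observations exactly.
    """
    if traj.frame_count == 0:
        raise ValueError("empty trajectory")
    all_xyz = (np.vstack([f for f in traj.frames if len(f)])
               if any(len(f) for f in traj.frames) else np.zeros((0, 3)))
    if bounds is None:
        if len(all_xyz) == 0:
            raise ValueError("trajectory contains no waters and no bounds given")
        lo = all_xyz.min(axis=0) - 2.0 * spacing
        hi = all_xyz.max(axis=0) + 2.0 * spacing
    else:
        lo, hi = (np.asarray(b, dtype=np.float64) for b in bounds)
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    counts = np.zeros(shape, dtype=np.int64)
    if len(all_xyz):
        idx = np.floor((all_xyz - lo) / spacing).astype(int)
        inb = np.all((idx >= 0) & (idx < shape), axis=1)
        np.add.at(counts, tuple(idx[inb].T), 1)
    return DensityGrid(origin=lo, spacing=spacing, counts=counts,
                       frame_count=traj.frame_count)


def extract_sites(grid: DensityGrid, site_radius: float = SITE_RADIUS,
                  min_peak_count: int | None = None) -> np.ndarray:
    """Greedy density-peak extraction of hydration-site centers.

    Repeatedly takes the highest-count voxel (ties broken by lexicographic
    voxel index), forms the density-weighted centroid of all density within
    ``site_radius`` of it, and removes that density. Peaks landing within
    2 * site_radius of an already-extracted center are merged (absorbed
    without emitting a new site). Stops when the top peak falls below
    ``min_peak_count`` (default: 1% of the frame count, at least 2).
    """
    if min_peak_count is None:
        min_peak_count = max(2, int(round(0.01 * grid.frame_count)))
    counts = grid.counts.astype(np.float64).copy()
    if counts.sum() == 0:
        return np.zeros((0, 3))
    occupied = np.argwhere(counts > 0)
    centers_xyz = grid.voxel_centers(occupied)
    values = counts[tuple(occupied.T)]
    sites: list[np.ndarray] = []
    while True:
        if values.max() < min_peak_count:
            break
        top = values.max()
        cand = np.flatnonzero(values == top)
        # lexicographic voxel-index tie-break
        cand = cand[np.lexsort(occupied[cand].T[::-1])]
        peak_xyz = centers_xyz[cand[0]]
        near = np.linalg.norm(centers_xyz - peak_xyz, axis=1) <= site_radius
        w = values[near]
        centroid = (w[:, None] * centers_xyz[near]).sum(axis=0) / w.sum()
        merged = any(np.linalg.norm(centroid - s) < 2.0 * site_radius
                     for s in sites)
        if not merged:
            sites.append(centroid)
        values[near] = 0.0
        if values.max() <= 0:
            break
    return np.array(sites).reshape(-1, 3)


def occupancy(site_center: np.ndarray, traj: WaterTrajectory,
              site_radius: float = SITE_RADIUS) -> float:
    """Fraction of frames with at least one water inside the site sphere."""
    site_center = np.asarray(site_center, dtype=np.float64)
    hits = 0
    for frame in traj.frames:
        if len(frame) and np.any(
                np.linalg.norm(frame - site_center, axis=1) <= site_radius):
            hits += 1
    return hits / traj.frame_count


def site_observations(site_center: np.ndarray, traj: WaterTrajectory,
                      site_radius: float = SITE_RADIUS):
    """Collect (positions, energies, orientations) of site waters."""
    site_center = np.asarray(site_center, dtype=np.float64)
    pos, ene, ori = [], [], []
    for i, frame in enumerate(traj.frames):
        if len(frame) == 0:
            continue
        inside = np.linalg.norm(frame - site_center, axis=1) <= site_radius
        if not inside.any():
            continue
        pos.append(frame[inside])
        if traj.energies is not None:
            ene.append(np.asarray(traj.energies[i])[inside])
        if traj.orientations is not None:
            ori.append(np.asarray(traj.orientations[i])[inside])
    positions = np.vstack(pos) if pos else np.zeros((0, 3))
    energies = np.concatenate(ene) if ene else None
    orientations = np.vstack(ori) if ori else None
    return positions, energies, orientations


def site_enthalpy(energies: np.ndarray, bulk_reference: float) -> float:
    """dH = mean site interaction energy minus the bulk reference."""
    energies = np.asarray(energies, dtype=np.float64)
    if energies.size == 0:
        raise ValueError("site_enthalpy requires at least one observation")
    return float(energies.mean() - bulk_reference)


def _translational_entropy(positions: np.ndarray, bin_width: float,
                           bulk_density: float) -> float:
    lo = positions.min(axis=0) - bin_width
    idx = np.floor((positions - lo) / bin_width).astype(int)
    _, counts = np.unique(idx, axis=0, return_counts=True)
    f = counts / len(positions)
    v_bin = bin_width ** 3
    return float(-R_KCAL * np.sum(f * np.log(f / (bulk_density * v_bin))))


def _rotational_entropy(orientations: np.ndarray, angle_bin_deg: float) -> float:
    # ZYZ Euler angles; binning uniform in (alpha, cos(beta), gamma) makes
    # the Haar measure uniform across bins.
    angles = Rotation.from_quat(np.asarray(orientations)).as_euler("ZYZ")
    n_ang = max(1, int(round(360.0 / angle_bin_deg)))
    n_cos = max(1, int(round(180.0 / angle_bin_deg)))
    ia = np.clip(((angles[:, 0] + np.pi) / (2 * np.pi) * n_ang).astype(int),
                 0, n_ang - 1)
    ic = np.clip(((np.cos(angles[:, 1]) + 1.0) / 2.0 * n_cos).astype(int),
                 0, n_cos - 1)
    ig = np.clip(((angles[:, 2] + np.pi) / (2 * np.pi) * n_ang).astype(int),
                 0, n_ang - 1)
    flat = (ia * n_cos + ic) * n_ang + ig
    _, counts = np.unique(flat, return_counts=True)
    f = counts / len(orientations)
    u = 1.0 / (n_ang * n_cos * n_ang)   # uniform Haar fraction per bin
    return float(-R_KCAL * np.sum(f * np.log(f / u)))


def site_entropy(positions: np.ndarray,
                 orientations: np.ndarray | None = None,
                 trans_bin: float = GRID_SPACING,
                 rot_bin_deg: float = 30.0,
                 bulk_density: float = BULK_WATER_DENSITY,
                 min_observations: int = 50) -> float:
    """dS (kcal/mol/K) from discretized external-mode PDF integration.

    Translational part: -R * sum f ln(f / (C * v_bin)) over occupied voxels
    of a ``trans_bin`` histogram (uniform occupation of a volume V gives
    R * ln(V * C)). Rotational part: the analogous discrete KL against the
    uniform orientation distribution; omitted when no orientations are given.
    """
    positions = np.asarray(positions, dtype=np.float64).reshape(-1, 3)
    if len(positions) < min_observations:
        raise ValueError(
            f"site_entropy needs >= {min_observations} observations, "
            f"got {len(positions)}")
    ds = _translational_entropy(positions, trans_bin, bulk_density)
    if orientations is not None:
        ds += _rotational_entropy(orientations, rot_bin_deg)
    return ds


def free_energy(dH: float, dS: float,
                temperature: float = TEMPERATURE) -> float:
    """dG = dH - T * dS."""
    return dH - temperature * dS


def analyze_trajectory(traj: WaterTrajectory, bulk_energy: float = 0.0,
                       spacing: float = GRID_SPACING,
                       site_radius: float = SITE_RADIUS,
                       min_peak_count: int | None = None,
                       min_entropy_obs: int = 50,
                       temperature: float = TEMPERATURE
                       ) -> list[HydrationSite]:
    """Full pipeline: density -> sites -> occupancy + thermodynamics."""
    grid = accumulate_density(traj, spacing)
    centers = extract_sites(grid, site_radius, min_peak_count)
    out: list[HydrationSite] = []
    for center in centers:
        occ = occupancy(center, traj, site_radius)
        pos, ene, ori = site_observations(center, traj, site_radius)
        dH = site_enthalpy(ene, bulk_energy) if ene is not None else None
        dS = None
        if len(pos) >= min_entropy_obs:
            dS = site_entropy(pos, ori, min_observations=min_entropy_obs)
        out.append(HydrationSite(center=center, occupancy=occ, dH=dH, dS=dS))
    return out
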