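"""File formats: site tables, frame tables, OpenDX grids, model checkpoints.

All outputs are plain text. Site and frame tables are CSV (pandas); density
grids are OpenDX; model checkpoints are single-file JSON containing the
model config, a hash of it, and the parameter arrays.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sites import HydrationSite, WaterPrediction
from .trajectory_thermo import DensityGrid, WaterTrajectory

__all__ = [
    "sites_to_dataframe", "write_sites_csv", "read_sites_csv",
    "write_frames_csv", "read_frames_csv", "write_dx", "write_sites_pdb",
    "save_checkpoint", "load_checkpoint", "config_hash",
]


def sites_to_dataframe(sites: list[HydrationSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append({
            "x": s.center[0], "y": s.center[1], "z": s.center[2],
            "occupancy": s.occupancy, "dH": s.dH, "dS": s.dS,
            "weight": s.weight,
        })
    return pd.DataFrame(rows)


def write_sites_csv(sites: list[HydrationSite], path: str | Path) -> None:
    sites_to_dataframe(sites).to_csv(path, index=False)


def read_sites_csv(path: str | Path) -> list[HydrationSite]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        def val(col):
            return (float(row[col])
                    if col in df.columns and pd.notna(row[col]) else None)
        out.append(HydrationSite(
            center=np.array([row["x"], row["y"], row["z"]]),
            occupancy=val("occupancy"), dH=val("dH"), dS=val("dS"),
            weight=val("weight")))
    return out


def write_frames_csv(traj: WaterTrajectory, path: str | Path) -> None:
    rows = []
    for f, frame in enumerate(traj.frames):
        for k in range(len(frame)):
            row = {"frame": f, "water_id": k,
                   "x": frame[k, 0], "y": frame[k, 1], "z": frame[k, 2]}
            if traj.energies is not None:
                row["energy"] = traj.energies[f][k]
            if traj.orientations is not None:
                q = traj.orientations[f][k]
                row.update(qx=q[0], qy=q[1], qz=q[2], qw=q[3])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_frames_csv(path: str | Path) -> WaterTrajectory:
    df = pd.read_csv(path)
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    if n_frames == 0:
        raise ValueError(f"no frames in {path}")
    has_e = "energy" in df.columns
    has_q = all(c in df.columns for c in ("qx", "qy", "qz", "qw"))
    frames, energies, orientations = [], [], []
    grouped = dict(tuple(df.groupby("frame")))
    for f in range(n_frames):
        g = grouped.get(f)
        if g is None:
            frames.append(np.zeros((0, 3)))
            energies.append(np.zeros(0))
            orientations.append(np.zeros((0, 4)))
            continue
        frames.append(g[["x", "y", "z"]].to_numpy(dtype=np.float64))
        energies.append(g["energy"].to_numpy(dtype=np.float64)
                        if has_e else np.zeros(len(g)))
        orientations.append(g[["qx", "qy", "qz", "qw"]].to_numpy(np.float64)
                            if has_q else np.zeros((len(g), 4)))
    return WaterTrajectory(frames=frames,
                           energies=energies if has_e else None,
                           orientations=orientations if has_q else None)


def write_dx(grid: DensityGrid, path: str | Path) -> None:
    """Serialize a density grid in OpenDX scalar-field format."""
    nx, ny, nz = grid.counts.shape
    s = grid.spacing
    o = grid.origin
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}",
        f"delta {s:.6f} 0 0",
        f"delta 0 {s:.6f} 0",
        f"delta 0 0 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.counts.astype(float).ravel(order="C")
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6g}" for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    Path(path).write_text("\n".join(lines) + "\n")


def write_sites_pdb(sites: list[HydrationSite], path: str | Path) -> None:
    """Emit sites as HETATM oxygen records (resname HOH) for visualization."""
    lines = []
    for i, s in enumerate(sites, start=1):
        x, y, z = s.center
        occ = 1.0 if s.occupancy is None else s.occupancy
        lines.append(
            f"HETATM{i:5d}  O   HOH A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}           O")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def save_checkpoint(path: str | Path, kind: str, config: dict,
                    state: dict[str, np.ndarray]) -> None:
    payload = {
        "kind": kind,
        "config": config,
        "config_hash": config_hash(config),
        "state": {k: v.tolist() for k, v in state.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[str, dict, dict[str, np.ndarray]]:
    payload = json.loads(Path(path).read_text())
    if config_hash(payload["config"]) != payload["config_hash"]:
        raise ValueError(f"checkpoint {path}: config hash mismatch")
    state = {k: np.asarray(v, dtype=np.float64)
             for k, v in payload["state"].items()}
    return payload["kind"], payload["config"], state
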