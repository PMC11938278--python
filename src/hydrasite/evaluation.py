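"""Evaluation metrics for hydration-site prediction.

GTRR (ground-truth recovery rate): fraction of reference sites with at
least one prediction within a distance cutoff r. PHR (prediction hit
rate): fraction of predictions within r of at least one reference site.
Matching is any-within-r (many-to-one allowed); an optional one-to-one
Hungarian variant is available for sensitivity checks. Sites are split
into first/second hydration layers at 3.5 A (inclusive) from the nearest
protein heavy atom.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .constants import FIRST_LAYER_CUTOFF

__all__ = ["gtrr", "phr", "classify_layer", "binned_gtrr",
           "regression_metrics", "DEFAULT_OCCUPANCY_BINS"]

DEFAULT_OCCUPANCY_BINS: list[tuple[float, float]] = [
    (0.5, 0.6), (0.6, 0.7), (0.7, 0.8), (0.8, 0.9), (0.9, 1.0)]


def _as_coords(points) -> np.ndarray:
    pts = [getattr(p, "center", getattr(p, "x", p)) for p in points]
    return np.asarray(pts, dtype=np.float64).reshape(-1, 3)


def _min_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each row of a to its nearest row of b."""
    return cKDTree(b).query(a)[0]


def gtrr(refs, preds, r: float, one_to_one: bool = False) -> float:
    """Fraction of reference sites recovered within r by some prediction."""
    if r <= 0:
        raise ValueError("cutoff r must be positive")
    refs = _as_coords(refs)
    if len(refs) == 0:
        raise ValueError("gtrr undefined for empty reference set")
    preds = _as_coords(preds)
    if len(preds) == 0:
        return 0.0
    if one_to_one:
        return _matched_fraction(refs, preds, r)
    return float(np.mean(_min_dists(refs, preds) <= r))


def phr(refs, preds, r: float, one_to_one: bool = False) -> float:
    """Fraction of predictions within r of some reference site."""
    if r <= 0:
        raise ValueError("cutoff r must be positive")
    preds = _as_coords(preds)
    if len(preds) == 0:
        raise ValueError("phr undefined for empty prediction set")
    refs = _as_coords(refs)
    if len(refs) == 0:
        return 0.0
    if one_to_one:
        return _matched_fraction(preds, refs, r)
    return float(np.mean(_min_dists(preds, refs) <= r))


def _matched_fraction(a: np.ndarray, b: np.ndarray, r: float) -> float:
    """One-to-one (Hungarian) matching variant: matched share of `a`."""
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    cost = np.where(d <= r, d, 1e6)
    ia, ib = linear_sum_assignment(cost)
    return float(np.sum(d[ia, ib] <= r) / len(a))


def classify_layer(site, structure) -> str:
    """"first" if the site is within 3.5 A (inclusive) of a heavy atom."""
    center = np.asarray(getattr(site, "center", site), dtype=np.float64)
    coords = structure.coords if hasattr(structure, "coords") else \
        np.asarray(structure, dtype=np.float64)
    if len(coords) == 0:
        raise ValueError("structure has no atoms")
    dmin = np.min(np.linalg.norm(coords - center, axis=1))
    return "first" if dmin <= FIRST_LAYER_CUTOFF else "second"


def binned_gtrr(refs, preds, bins=None, cutoffs=(0.5, 1.0, 1.5, 2.0)
                ) -> dict[tuple[float, float], dict[float, float | None]]:
    """GTRR per occupancy bin and cutoff; empty bins are None, not 0."""
    bins = bins or DEFAULT_OCCUPANCY_BINS
    table: dict[tuple[float, float], dict[float, float | None]] = {}
    for lo, hi in bins:
        closed_top = hi >= max(b[1] for b in bins)
        members = [s for s in refs if s.occupancy is not None
                   and (lo <= s.occupancy < hi
                        or (closed_top and s.occupancy == hi))]
        row: dict[float, float | None] = {}
        for r in cutoffs:
            row[r] = gtrr(members, preds, r) if members else None
        table[(lo, hi)] = row
    return table


def regression_metrics(pred, target) -> tuple[float, float, float]:
    """(R^2, MSE, RMSE) with R^2 = 1 - SS_res / SS_tot."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape or pred.size < 2:
        raise ValueError("pred and target must be equal-length vectors (n >= 2)")
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("target has zero variance; R^2 undefined")
    res = target - pred
    mse = float(np.mean(res ** 2))
    r2 = 1.0 - float(np.sum(res ** 2)) / ss_tot
    return r2, mse, float(np.sqrt(mse))
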