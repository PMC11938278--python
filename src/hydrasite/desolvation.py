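"""Ligand desolvation scoring from hydration-site displacement.

A hydration site is displaced by a ligand pose if its center lies within a
tolerance (2.4 A default) of any ligand heavy atom. The desolvation score
is the negated sum of the displaced sites' dG values (kJ/mol): expelling a
water that was *unfavorable* in its site (dG > 0 relative to bulk) yields a
favorable, negative desolvation term. Predicted scores are compared against
experimental binding free energies after a slope-one calibration (an
intercept-only shift), and goodness of fit is reported as
R^2 = 1 - SS_res / SS_tot plus RMSE.

The package ships the 12-ligand major-urinary-protein (MUP) benchmark table
(kJ/mol) used by ``benchmark_table``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .constants import DISPLACEMENT_TOLERANCE
from .evaluation import regression_metrics
from .sites import HydrationSite

__all__ = ["LigandPose", "displaced_sites", "desolvation_energy",
           "slope_one_calibrate", "benchmark_table", "load_mup_table"]


@dataclass
class LigandPose:
    coords: np.ndarray         # (k, 3) heavy-atom coordinates, A
    ligand_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if len(self.coords) < 1:
            raise ValueError("ligand pose must contain at least one atom")


def displaced_sites(sites: list[HydrationSite], ligand: LigandPose,
                    tolerance: float = DISPLACEMENT_TOLERANCE
                    ) -> list[HydrationSite]:
    """Sites whose center is within ``tolerance`` of any ligand heavy atom."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    out = []
    for s in sites:
        d = np.linalg.norm(ligand.coords - s.center, axis=1)
        if np.min(d) <= tolerance:
            out.append(s)
    return out


def desolvation_energy(displaced: list[HydrationSite],
                       temperature: float = 300.0) -> float:
    """Signed desolvation score: minus the sum of displaced-site dG values.

    Sign convention: a displaced site with dG > 0 (water unhappier in the
    site than in bulk) contributes favorably (negatively), so scores for
    hydrophobic pockets come out negative. Empty input scores 0.
    """
    return float(-sum(s.dG(temperature) for s in displaced))


def slope_one_calibrate(pred, exp) -> np.ndarray:
    """Intercept-only calibration: shift predictions to match the mean.

    Equivalent to regressing the experimental values on the predictions with
    the slope fixed to one; residuals of the calibrated values sum to zero
    and any constant offset in the predictions is absorbed.
    """
    pred = np.asarray(pred, dtype=np.float64)
    exp = np.asarray(exp, dtype=np.float64)
    if pred.shape != exp.shape or pred.size < 2:
        raise ValueError("pred and exp must be equal-length vectors (n >= 2)")
    return pred + (exp.mean() - pred.mean())


def benchmark_table(pred_sets: dict[str, np.ndarray], exp: np.ndarray
                    ) -> dict[str, dict[str, float]]:
    """Per-method (R^2, MSE, RMSE) after slope-one calibration."""
    out = {}
    for name, pred in pred_sets.items():
        calibrated = slope_one_calibrate(pred, exp)
        r2, mse, rmse = regression_metrics(calibrated, exp)
        out[name] = {"r2": r2, "mse": mse, "rmse": rmse}
    return out


def load_mup_table(path: str | None = None) -> pd.DataFrame:
    """Load the packaged MUP desolvation benchmark (kJ/mol) or a custom CSV."""
    if path is not None:
        return pd.read_csv(path)
    with resources.files("hydrasite.data").joinpath("mup_benchmark.csv").open() as fh:
        return pd.read_csv(fh)
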