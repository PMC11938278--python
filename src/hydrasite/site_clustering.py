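"""Post-processing of raw water predictions into final hydration sites.

Predictions below the certainty cutoff w_c = 0.035 are discarded; the rest
are grouped by Ward agglomerative clustering with a 2 A linkage distance
threshold; each cluster is reduced to its certainty-weighted centroid and
kept only if its aggregated certainty weight exceeds 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .constants import CERTAINTY_CUTOFF, CLUSTER_WEIGHT_MIN, LINKAGE_THRESHOLD
from .sites import HydrationSite, WaterPrediction

__all__ = ["Cluster", "filter_low_certainty", "cluster_predictions",
           "finalize_sites", "predictions_to_sites"]


@dataclass
class Cluster:
    members: list[WaterPrediction]
    centroid: np.ndarray
    weight: float


def filter_low_certainty(preds: list[WaterPrediction],
                         w_c: float = CERTAINTY_CUTOFF) -> list[WaterPrediction]:
    """Keep exactly the predictions with certainty weight >= w_c."""
    return [p for p in preds if p.w >= w_c]


def _sorted_by_coord(preds: list[WaterPrediction]) -> list[WaterPrediction]:
    # deterministic, order-independent tie-breaking
    order = np.lexsort(np.array([p.x for p in preds]).T[::-1])
    return [preds[i] for i in order]


def cluster_predictions(preds: list[WaterPrediction],
                        distance_threshold: float = LINKAGE_THRESHOLD,
                        aggregation: str = "sum") -> list[Cluster]:
    """Ward agglomerative clustering of prediction coordinates.

    Clusters are merged while their Ward linkage distance is below the
    threshold (2 A default). Linkage operates on unweighted coordinates;
    certainty weights enter only the centroid and the aggregated cluster
    weight. ``aggregation`` is "sum" (default: accumulated evidence, so the
    0.1 gate is independent of how many predictions a protein produces) or
    "mean".
    """
    if len(preds) == 0:
        raise ValueError("cluster_predictions requires at least one prediction")
    preds = _sorted_by_coord(preds)
    coords = np.array([p.x for p in preds])
    if len(preds) == 1:
        labels = np.array([1])
    else:
        labels = fcluster(linkage(coords, method="ward"),
                          t=distance_threshold, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        members = [p for p, l in zip(preds, labels) if l == lab]
        xs = np.array([p.x for p in members])
        ws = np.array([p.w for p in members])
        if ws.sum() <= 0:
            continue
        centroid = (ws[:, None] * xs).sum(axis=0) / ws.sum()
        if aggregation == "sum":
            weight = float(ws.sum())
        elif aggregation == "mean":
            weight = float(ws.mean())
        else:
            raise ValueError(f"unknown aggregation: {aggregation}")
        clusters.append(Cluster(members=members, centroid=centroid,
                                weight=weight))
    clusters.sort(key=lambda c: tuple(c.centroid))
    return clusters


def finalize_sites(clusters: list[Cluster],
                   min_cluster_weight: float = CLUSTER_WEIGHT_MIN
                   ) -> list[HydrationSite]:
    """Emit one site per cluster whose aggregated weight exceeds the gate."""
    return [HydrationSite(center=c.centroid, weight=c.weight)
            for c in clusters if c.weight > min_cluster_weight]


def predictions_to_sites(preds: list[WaterPrediction],
                         w_c: float = CERTAINTY_CUTOFF,
                         distance_threshold: float = LINKAGE_THRESHOLD,
                         min_cluster_weight: float = CLUSTER_WEIGHT_MIN,
                         aggregation: str = "sum") -> list[HydrationSite]:
    """Full pipeline: certainty filter -> ward clustering -> weight gate."""
    kept = filter_low_certainty(preds, w_c)
    if len(kept) == 0:
        return []
    clusters = cluster_predictions(kept, distance_threshold, aggregation)
    return finalize_sites(clusters, min_cluster_weight)
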