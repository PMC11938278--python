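"""The hydration-site location model.

Water nodes are seeded on solvent-exposed heavy atoms (fractional SASA
above 0.1) and perturbed by five E(3)-equivariant attention layers; the
6 A distance graph is rebuilt before each layer so waters that moved pick
up new neighborhoods. Every water node emits a coordinate and a certainty
weight in [0, 1].

Training minimizes a divergence between two Gaussian mixtures (sigma =
0.5 A): one over the predictions weighted by their normalized certainties,
one over the reference sites with occupancy >= 0.5 weighted by normalized
occupancy. The divergence surrogate is the closed-form L2 distance
integral((p - q)^2), which is symmetric and uniquely minimized at p = q,
plus a concentration penalty alpha * sum(w_tilde^2) that discourages the
model from loading all certainty onto few predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (LOCATION_CUTOFF, MIXTURE_SIGMA, N_EQUIVARIANT_LAYERS,
                        N_RBF, OCCUPANCY_LOSS_MIN, SASA_THRESHOLD)
from .graph_builder import build_graph
from .nn import MLP, Adam, ParamStore, Tensor, concat, gather, segment_sum
from .sites import HydrationSite, WaterPrediction, sites_to_arrays
from .structure_io import ProteinStructure, featurize

__all__ = [
    "LossConfig", "initialize_waters", "normalize_weights", "mixture_loss",
    "mixture_loss_grad", "SiteModel", "train_site_model",
]


@dataclass
class LossConfig:
    alpha: float = 0.1          # weight of the concentration penalty
    sigma: float = MIXTURE_SIGMA
    occupancy_min: float = OCCUPANCY_LOSS_MIN

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def initialize_waters(structure: ProteinStructure,
                      sasa_threshold: float = SASA_THRESHOLD) -> np.ndarray:
    """Seed coordinates: one water per heavy atom with SASA > threshold."""
    if structure.sasa is None:
        raise ValueError("compute_sasa must run before initialize_waters")
    mask = np.asarray(structure.sasa) > sasa_threshold
    return structure.coords[mask]


def normalize_weights(w: np.ndarray) -> np.ndarray:
    """Normalized certainty weights w_tilde = w / sum(w)."""
    w = np.asarray(w, dtype=np.float64)
    if np.any(w < 0):
        raise ValueError("certainty weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("all certainty weights are zero; mixture undefined")
    return w / total


def _mixture_loss_t(x: Tensor, w: Tensor, ref_xyz: np.ndarray,
                    ref_occ: np.ndarray, cfg: LossConfig):
    """Tensor-valued loss L = L1 + alpha * L2 (see module docstring)."""
    n = x.data.shape[0]
    sigma2 = cfg.sigma ** 2
    kernel = (4.0 * np.pi * sigma2) ** -1.5
    inv = 1.0 / (4.0 * sigma2)

    wt = w * (w.sum() ** -1.0)                     # w_tilde
    v = ref_occ / ref_occ.sum()                    # reference mixture weights

    xsq = (x ** 2).sum(axis=1, keepdims=True)      # (n, 1)
    d2_pp = xsq + xsq.T - 2.0 * (x @ x.T)
    a_pp = (d2_pp * -inv).exp()
    ysq = np.sum(ref_xyz ** 2, axis=1)[None, :]    # (1, m)
    d2_pq = xsq + ysq - 2.0 * (x @ ref_xyz.T)
    a_pq = (d2_pq * -inv).exp()

    d2_qq = (ref_xyz[:, None, :] - ref_xyz[None, :, :]) ** 2
    l_qq = float(v @ np.exp(-d2_qq.sum(-1) * inv) @ v)

    wt_row = wt.reshape(1, n)
    l_pp = (wt_row @ a_pp @ wt.reshape(n, 1)).reshape(1)
    l_pq = (wt_row @ a_pq @ v.reshape(-1, 1)).reshape(1)
    l1 = (l_pp - 2.0 * l_pq + l_qq) * kernel
    l2 = (wt ** 2).sum()
    return (l1 + cfg.alpha * l2).reshape(()), l1, l2


def _loss_inputs(preds, refs, cfg: LossConfig):
    if len(preds) == 0:
        raise ValueError("mixture_loss requires at least one prediction")
    x = np.array([p.x for p in preds], dtype=np.float64)
    w = np.array([p.w for p in preds], dtype=np.float64)
    refs = [r for r in refs
            if r.occupancy is None or r.occupancy >= cfg.occupancy_min]
    if len(refs) == 0:
        raise ValueError("mixture_loss requires at least one reference site "
                         f"with occupancy >= {cfg.occupancy_min}")
    ref_xyz, ref_occ = sites_to_arrays(refs)
    return x, w, ref_xyz, ref_occ


def mixture_loss(preds: list[WaterPrediction], refs: list[HydrationSite],
                 cfg: LossConfig | None = None) -> tuple[float, float, float]:
    """Total loss and its parts (L, L1, L2) on plain numpy inputs."""
    cfg = cfg or LossConfig()
    x, w, ref_xyz, ref_occ = _loss_inputs(preds, refs, cfg)
    normalize_weights(w)  # validation: rejects all-zero weights
    loss, l1, l2 = _mixture_loss_t(Tensor(x), Tensor(w), ref_xyz, ref_occ, cfg)
    return loss.item(), float(l1.data.reshape(())), float(l2.data.reshape(()))


def mixture_loss_grad(preds, refs, cfg: LossConfig | None = None):
    """Analytic gradients of the loss w.r.t. coordinates and raw weights."""
    cfg = cfg or LossConfig()
    x_np, w_np, ref_xyz, ref_occ = _loss_inputs(preds, refs, cfg)
    x, w = Tensor(x_np), Tensor(w_np)
    loss, _, _ = _mixture_loss_t(x, w, ref_xyz, ref_occ, cfg)
    loss.backward()
    return loss.item(), x.grad.copy(), w.grad.copy()


class SiteModel:
    """EGNN-style equivariant attention network for water placement.

    Messages are invariant functions of node features and inter-node
    distance; coordinate updates are attention-gated sums of relative
    position vectors, so predictions transform with any rigid motion of
    the input and protein atoms never move.
    """

    def __init__(self, hidden: int = 32, n_layers: int = N_EQUIVARIANT_LAYERS,
                 cutoff: float = LOCATION_CUTOFF,
                 sasa_threshold: float = SASA_THRESHOLD, seed: int = 0):
        self.hidden = hidden
        self.n_layers = n_layers
        self.cutoff = cutoff
        self.sasa_threshold = sasa_threshold
        self.store = ParamStore(seed)
        h, f = hidden, 92
        self.embed = self.store.linear("embed", f, h)
        self.mlps = []
        for layer in range(n_layers):
            self.mlps.append({
                "edge": MLP(self.store, f"l{layer}.edge", [2 * h + N_RBF, h, h]),
                "att": MLP(self.store, f"l{layer}.att", [h, 1]),
                "coord": MLP(self.store, f"l{layer}.coord", [h, h, 1],
                             out_scale=0.3),
                "node": MLP(self.store, f"l{layer}.node", [2 * h, h, h]),
            })
        self.head = MLP(self.store, "weight_head", [h, h, 1])
        self._rbf_centers = np.linspace(0.0, cutoff, N_RBF)
        self._rbf_width = self._rbf_centers[1] - self._rbf_centers[0]

    # -- forward -----------------------------------------------------------

    def _edge_rbf(self, d: Tensor) -> Tensor:
        c = self._rbf_centers[None, :]
        return (((d - c) ** 2) * (-1.0 / self._rbf_width ** 2)).exp()

    def forward(self, protein_coords: np.ndarray, protein_feats: np.ndarray,
                seed_coords: np.ndarray, seed_feats: np.ndarray,
                coord_log: list | None = None):
        """Run the network; returns (water coords, weights) as Tensors.

        If ``coord_log`` is a list, the full (protein + water) coordinate
        array is appended to it after every layer (numpy copies), which lets
        callers verify that protein positions stay bit-identical.
        """
        n_p, n_w = len(protein_coords), len(seed_coords)
        n = n_p + n_w
        feats = np.vstack([protein_feats, seed_feats])
        kind = np.concatenate([np.zeros(n_p, dtype=np.intp),
                               np.ones(n_w, dtype=np.intp)])
        water_mask = (kind == 1).astype(np.float64)[:, None]

        x = Tensor(np.vstack([protein_coords, seed_coords]))
        h = Tensor(feats) @ self.embed[0] + self.embed[1]

        for layer in self.mlps:
            # topology refresh from current coordinates (no grad through it)
            graph = build_graph(x.data, self.cutoff, node_kind=kind)
            src, dst = graph.directed_edges()
            if len(src) == 0:
                if coord_log is not None:
                    coord_log.append(x.data.copy())
                continue
            rel = gather(x, dst) - gather(x, src)
            d2 = (rel ** 2).sum(axis=1, keepdims=True)
            d = (d2 + 1e-12).sqrt()
            msg_in = concat([gather(h, src), gather(h, dst),
                             self._edge_rbf(d)], axis=1)
            m = layer["edge"](msg_in).tanh()
            att = layer["att"](m).sigmoid()
            s = layer["coord"](m)
            deg = np.zeros(n)
            np.add.at(deg, dst, 1.0)
            norm = 1.0 / (deg + 1.0)
            dx = segment_sum(rel * (d + 1.0) ** -1.0 * (s * att), dst, n)
            x = x + dx * (water_mask * norm[:, None])
            agg = segment_sum(m * att, dst, n) * norm[:, None]
            h = h + layer["node"](concat([h, agg], axis=1))
            if coord_log is not None:
                coord_log.append(x.data.copy())

        h_w = gather(h, np.arange(n_p, n, dtype=np.intp))
        w = self.head(h_w).sigmoid().reshape(-1)
        x_w = gather(x, np.arange(n_p, n, dtype=np.intp))
        return x_w, w

    def predict_raw(self, structure: ProteinStructure) -> list[WaterPrediction]:
        """Deterministic inference: seeded waters -> (coordinate, certainty)."""
        seeds = initialize_waters(structure, self.sasa_threshold)
        if len(seeds) == 0:
            return []
        atom_feats = featurize(structure, node_type="atom")
        water_feats = featurize(structure, node_type="water")
        water_feats = water_feats[np.asarray(structure.sasa)
                                  > self.sasa_threshold]
        x_w, w = self.forward(structure.coords, atom_feats, seeds, water_feats)
        return [WaterPrediction(x=xi, w=float(wi))
                for xi, wi in zip(x_w.data, w.data)]

    # -- persistence ---------------------------------------------------------

    def config(self) -> dict:
        return {"hidden": self.hidden, "n_layers": self.n_layers,
                "cutoff": self.cutoff, "sasa_threshold": self.sasa_threshold}

    @classmethod
    def from_config(cls, config: dict, state: dict | None = None,
                    seed: int = 0) -> "SiteModel":
        model = cls(seed=seed, **config)
        if state is not None:
            model.store.load_state_dict(state)
        return model


def train_site_model(structures: list[ProteinStructure],
                     references: list[list[HydrationSite]],
                     cfg: LossConfig | None = None,
                     hidden: int = 32, lr: float = 6e-3, epochs: int = 300,
                     lr_decay: float = 0.997, sigma_start: float = 2.0,
                     sigma_decay: float = 0.99, seed: int = 0,
                     callback=None) -> tuple[SiteModel, list[float]]:
    """Overfit-scale trainer: Adam on the mixture loss over all structures.

    References are restricted to occupancy >= cfg.occupancy_min before the
    loss. The mixture width is deterministically annealed from
    ``sigma_start`` down to the target cfg.sigma (0.5 A): a broad early
    mixture gives every reference mode long-range pull on the predictions,
    avoiding mode dropping; the final phase optimizes the target loss
    exactly. Returns the model and the per-epoch loss history.
    """
    cfg = cfg or LossConfig()
    model = SiteModel(hidden=hidden, seed=seed)
    opt = Adam(model.store, lr=lr)

    cases = []
    for structure, refs in zip(structures, references):
        seeds = initialize_waters(structure, model.sasa_threshold)
        if len(seeds) == 0:
            raise ValueError("structure has no solvent-exposed seed atoms")
        refs = [r for r in refs
                if r.occupancy is None or r.occupancy >= cfg.occupancy_min]
        if len(refs) == 0:
            raise ValueError("no reference sites with occupancy >= "
                             f"{cfg.occupancy_min}")
        atom_feats = featurize(structure, node_type="atom")
        water_feats = featurize(structure, node_type="water")[
            np.asarray(structure.sasa) > model.sasa_threshold]
        ref_xyz, ref_occ = sites_to_arrays(refs)
        cases.append((structure.coords, atom_feats, seeds, water_feats,
                      ref_xyz, ref_occ))

    history = []
    for epoch in range(epochs):
        sigma = max(cfg.sigma, sigma_start * sigma_decay ** epoch)
        epoch_cfg = LossConfig(alpha=cfg.alpha, sigma=sigma,
                               occupancy_min=cfg.occupancy_min)
        opt.zero_grad()
        total = 0.0
        for coords, atom_feats, seeds, water_feats, ref_xyz, ref_occ in cases:
            x_w, w = model.forward(coords, atom_feats, seeds, water_feats)
            loss, _, _ = _mixture_loss_t(x_w, w, ref_xyz, ref_occ, epoch_cfg)
            loss.backward()
            total += loss.item()
        opt.step()
        opt.lr *= lr_decay
        history.append(total / len(cases))
        if callback is not None and callback(epoch, history[-1], model):
            break
    return model, history
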