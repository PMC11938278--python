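"""The thermodynamic head: per-site (dH, -TdS) prediction.

A graph is built over protein heavy atoms and hydration sites (occupancy
> 0.3 when training labels are available) with an 8 A cutoff and no
intra-protein edges. Three graph-attention layers update node features from
distance-expanded edge features, and a feed-forward head maps each site
node to a two-dimensional output: the enthalpy change dH and the
temperature-scaled entropy term T*dS (both kcal/mol), from which
dG = dH - T*dS follows exactly.

Training minimizes the sum of the mean squared errors of dH and of T*dS
over sites with occupancy >= 0.5, at T = 300 K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (N_ATTENTION_LAYERS, N_RBF, OCCUPANCY_LOSS_MIN,
                        OCCUPANCY_NODE_MIN, TEMPERATURE, THERMO_CUTOFF)
from .graph_builder import SpatialGraph, build_graph
from .nn import (MLP, Adam, ParamStore, Tensor, concat, gather, segment_sum,
                 segment_softmax)
from .sites import HydrationSite
from .structure_io import ProteinStructure, featurize, water_feature_vector

__all__ = ["ThermoPrediction", "build_thermo_graph", "ThermoModel",
           "thermo_loss", "train_thermo_model"]


@dataclass
class ThermoPrediction:
    dH: float                 # kcal/mol
    TdS: float                # kcal/mol (T-scaled entropy change)

    @property
    def dG(self) -> float:
        return self.dH - self.TdS


def build_thermo_graph(structure: ProteinStructure,
                       sites: list[HydrationSite],
                       cutoff: float = THERMO_CUTOFF,
                       occupancy_min: float | None = OCCUPANCY_NODE_MIN
                       ) -> tuple[SpatialGraph, list[HydrationSite]]:
    """Protein + site graph: atom-site and site-site edges under 8 A only.

    Sites carrying occupancy are kept as nodes only if occupancy exceeds
    ``occupancy_min`` (pass None to skip the filter at pure inference time).
    Returns the graph and the retained sites, in node order.
    """
    if occupancy_min is not None:
        kept = [s for s in sites
                if s.occupancy is None or s.occupancy > occupancy_min]
    else:
        kept = list(sites)
    if len(kept) == 0:
        raise ValueError("no sites pass the occupancy filter "
                         f"(occupancy > {occupancy_min})")
    if structure.sasa is None:
        raise ValueError("compute_sasa must run before build_thermo_graph")
    n_p = len(structure)
    coords = np.vstack([structure.coords,
                        np.array([s.center for s in kept])])
    kind = np.concatenate([np.zeros(n_p, dtype=np.intp),
                           np.ones(len(kept), dtype=np.intp)])
    feats = np.vstack([featurize(structure, node_type="atom"),
                       np.tile(water_feature_vector(), (len(kept), 1))])
    graph = build_graph(coords, cutoff, node_kind=kind, node_features=feats,
                        exclude_pairs="atom-atom")
    return graph, kept


class ThermoModel:
    """Three-layer graph attention network + feed-forward thermo head."""

    def __init__(self, hidden: int = 32, n_layers: int = N_ATTENTION_LAYERS,
                 cutoff: float = THERMO_CUTOFF, seed: int = 0,
                 out_scale: float = 5.0):
        self.hidden = hidden
        self.n_layers = n_layers
        self.cutoff = cutoff
        self.out_scale = out_scale   # kcal/mol scale of the linear head
        self.store = ParamStore(seed)
        h = hidden
        self.embed = self.store.linear("embed", 92, h)
        self.layers = []
        for i in range(n_layers):
            self.layers.append({
                "proj": self.store.linear(f"l{i}.proj", h, h),
                "att": MLP(self.store, f"l{i}.att", [2 * h + N_RBF, h, 1]),
                "self": self.store.linear(f"l{i}.self", h, h),
            })
        self.head = MLP(self.store, "head", [h, h, 2])

    def _forward_graph(self, graph: SpatialGraph) -> Tensor:
        n = graph.n_nodes
        h = Tensor(graph.node_features) @ self.embed[0] + self.embed[1]
        src, dst = graph.directed_edges()
        if len(src) > 0:
            edge_rbf = np.vstack([graph.edge_features, graph.edge_features])
        for layer in self.layers:
            self_term = h @ layer["self"][0] + layer["self"][1]
            if len(src) == 0:
                h = self_term.tanh()
                continue
            z = h @ layer["proj"][0] + layer["proj"][1]
            e_in = concat([gather(z, src), gather(z, dst), Tensor(edge_rbf)],
                          axis=1)
            logits = layer["att"](e_in).leaky_relu()
            alpha = segment_softmax(logits, dst, n)
            msg = segment_sum(gather(z, src) * alpha, dst, n)
            h = (msg + self_term).tanh()
        return h

    def predict_thermo(self, structure: ProteinStructure,
                       sites: list[HydrationSite],
                       occupancy_min: float | None = None
                       ) -> list[ThermoPrediction]:
        """One (dH, TdS) pair per site node; rigid-motion invariant."""
        graph, kept = build_thermo_graph(structure, sites, self.cutoff,
                                         occupancy_min)
        out = self._site_outputs(graph, n_sites=len(kept))
        return [ThermoPrediction(dH=float(o[0]), TdS=float(o[1]))
                for o in out.data]

    def _site_outputs(self, graph: SpatialGraph, n_sites: int) -> Tensor:
        h = self._forward_graph(graph)
        site_idx = np.arange(graph.n_nodes - n_sites, graph.n_nodes,
                             dtype=np.intp)
        return self.head(gather(h, site_idx)) * self.out_scale

    def config(self) -> dict:
        return {"hidden": self.hidden, "n_layers": self.n_layers,
                "cutoff": self.cutoff, "out_scale": self.out_scale}

    @classmethod
    def from_config(cls, config: dict, state: dict | None = None,
                    seed: int = 0) -> "ThermoModel":
        model = cls(seed=seed, **config)
        if state is not None:
            model.store.load_state_dict(state)
        return model


def thermo_loss(preds: list[ThermoPrediction], refs: list[HydrationSite],
                occupancy_min: float = OCCUPANCY_LOSS_MIN,
                temperature: float = TEMPERATURE) -> float:
    """MSE(dH) + MSE(T*dS) over reference sites with occupancy >= 0.5."""
    pairs = [(p, r) for p, r in zip(preds, refs)
             if (r.occupancy is None or r.occupancy >= occupancy_min)]
    if len(pairs) == 0:
        raise ValueError("no reference sites with occupancy >= "
                         f"{occupancy_min}")
    dh_err = np.array([p.dH - r.dH for p, r in pairs])
    tds_err = np.array([p.TdS - temperature * r.dS for p, r in pairs])
    return float(np.mean(dh_err ** 2) + np.mean(tds_err ** 2))


def _thermo_cases(structures, site_lists, cutoff, occupancy_min, temperature):
    cases = []
    for structure, sites in zip(structures, site_lists):
        graph, kept = build_thermo_graph(structure, sites, cutoff,
                                         OCCUPANCY_NODE_MIN)
        mask = np.array([s.occupancy is None or s.occupancy >= occupancy_min
                         for s in kept])
        if not mask.any():
            raise ValueError("no trainable sites with occupancy >= "
                             f"{occupancy_min}")
        target = np.array([[s.dH, temperature * s.dS] for s in kept])
        cases.append((graph, len(kept), mask.astype(np.float64), target))
    return cases


def train_thermo_model(structures: list[ProteinStructure],
                       site_lists: list[list[HydrationSite]],
                       hidden: int = 16, lr: float = 5e-3, epochs: int = 400,
                       occupancy_min: float = OCCUPANCY_LOSS_MIN,
                       temperature: float = TEMPERATURE, seed: int = 0,
                       weight_decay: float = 2e-2,
                       validation_fraction: float = 0.2, n_restarts: int = 3,
                       callback=None) -> tuple["ThermoModel", list[float]]:
    """Adam training of the thermo head on labelled hydration sites.

    Small labelled site sets are easy to memorize, so the trainer is
    regularized on three fronts: decoupled weight decay, a validation split
    (the last ``validation_fraction`` of the structures, used whenever more
    than four are supplied) whose best-loss parameters are snapshotted, and
    ``n_restarts`` independent initializations of which the best-validation
    run is returned.
    """
    n_val = int(round(validation_fraction * len(structures)))
    if len(structures) <= 4:
        n_val = 0
    split = len(structures) - n_val
    cutoff = THERMO_CUTOFF
    cases = _thermo_cases(structures[:split], site_lists[:split],
                          cutoff, occupancy_min, temperature)
    val_cases = _thermo_cases(structures[split:], site_lists[split:],
                              cutoff, occupancy_min, temperature)
    if not val_cases:
        n_restarts = 1

    best_overall = (np.inf, None, None, [])   # (val, model, state, history)
    for attempt in range(n_restarts):
        model = ThermoModel(hidden=hidden, seed=seed + 7919 * attempt)
        opt = Adam(model.store, lr=lr, weight_decay=weight_decay)

        def batch_loss(batch, accumulate: bool) -> float:
            total = 0.0
            for graph, n_sites, mask, target in batch:
                out = model._site_outputs(graph, n_sites)
                err = (out - target) ** 2
                loss = (err.sum(axis=1) * mask).sum() * (1.0 / mask.sum())
                if accumulate:
                    loss.backward()
                total += loss.item()
            return total / len(batch)

        history = []
        best_val, best_state = np.inf, None
        for epoch in range(epochs):
            opt.zero_grad()
            history.append(batch_loss(cases, accumulate=True))
            opt.step()
            if val_cases and (epoch + 1) % 10 == 0:
                val = batch_loss(val_cases, accumulate=False)
                if val < best_val:
                    best_val = val
                    best_state = model.store.state_dict()
            if callback is not None and callback(epoch, history[-1], model):
                break
        if best_state is not None:
            model.store.load_state_dict(best_state)
        else:
            best_val = history[-1]
        if best_val < best_overall[0]:
            best_overall = (best_val, model, model.store.state_dict(), history)

    _, model, state, history = best_overall
    model.store.load_state_dict(state)
    return model, history
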