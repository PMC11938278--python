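"""Parameter containers, MLPs and the Adam optimizer used by both models."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, gather, segment_sum

__all__ = ["ParamStore", "MLP", "Adam", "segment_softmax"]


class ParamStore:
    """Flat name -> Tensor parameter map with seeded initialization."""

    def __init__(self, seed: int | None = None):
        self.params: dict[str, Tensor] = {}
        self.rng = np.random.default_rng(seed)

    def linear(self, name: str, n_in: int, n_out: int, scale: float | None = None):
        if f"{name}.W" not in self.params:
            s = scale if scale is not None else np.sqrt(1.0 / n_in)
            self.params[f"{name}.W"] = Tensor(
                self.rng.normal(0.0, s, size=(n_in, n_out)))
            self.params[f"{name}.b"] = Tensor(np.zeros(n_out))
        return self.params[f"{name}.W"], self.params[f"{name}.b"]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        # update in place: layer objects hold references to these Tensors
        for k, v in state.items():
            v = np.asarray(v, dtype=np.float64)
            if k in self.params:
                if self.params[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for parameter {k}")
                self.params[k].data = v
            else:
                self.params[k] = Tensor(v)


class MLP:
    """Small tanh MLP; the final layer is linear (optionally down-scaled)."""

    def __init__(self, store: ParamStore, name: str, sizes: list[int],
                 out_scale: float | None = None):
        self.layers = []
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            last = i == len(sizes) - 2
            scale = out_scale if (last and out_scale is not None) else None
            self.layers.append((store.linear(f"{name}.{i}", a, b, scale=scale), last))

    def __call__(self, x: Tensor) -> Tensor:
        for (W, b), last in self.layers:
            x = x @ W + b
            if not last:
                x = x.tanh()
        return x


def segment_softmax(logits: Tensor, segment_ids: np.ndarray,
                    num_segments: int) -> Tensor:
    """Softmax over rows sharing a segment id (attention normalization).

    The per-segment max is treated as a constant shift, which leaves the
    softmax value and its gradient unchanged while keeping exp() bounded.
    """
    if logits.data.ndim > 1 and logits.data.shape[1] != 1:
        raise ValueError("segment_softmax expects one logit per row")
    seg = np.asarray(segment_ids, dtype=np.intp)
    shift = np.full(num_segments, -np.inf)
    np.maximum.at(shift, seg, logits.data.reshape(-1))
    shift[~np.isfinite(shift)] = 0.0
    shifted = logits - shift[seg].reshape(logits.data.shape)
    e = shifted.exp()
    denom = segment_sum(e, seg, num_segments)
    return e / gather(denom, seg)


class Adam:
    """Adam with optional decoupled weight decay (applied to weights only)."""

    def __init__(self, store: ParamStore, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.store = store
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in store.params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in store.params.items()}

    def zero_grad(self):
        for p in self.store.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.store.params.items():
            if p.grad is None:
                continue
            if self.weight_decay > 0.0 and k.endswith(".W"):
                p.data *= 1.0 - self.lr * self.weight_decay
            if k not in self.m:
                self.m[k] = np.zeros_like(p.data)
                self.v[k] = np.zeros_like(p.data)
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
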