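"""Building blocks of the relation-attention segmentation network.

The attention update follows the network's defining recipe:

* self-attention ``F_SA = softmax(Q K^T / d_a) V`` — note the scale is the
  raw query/key width ``d_a``, not the conventional ``sqrt(d_a)``; both are
  supported via ``scale`` ("da" default, "sqrt" optional),
* relation attention ``F_RA = F_in - F_SA`` followed by the residual
  ``F_out = LBR(F_RA) + F_in`` where LBR is Linear–BatchNorm–ReLU,
* position encoding ``delta = phi(xyz)`` with ``phi`` a two-layer MLP with
  one ReLU, combined as ``F_in = psi(concat(f, delta))`` with ``psi`` linear.

Attention can run globally over a feature field or restricted to k-NN
patches (the form used inside the network).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, softmax

__all__ = [
    "Module",
    "Linear",
    "BatchNorm",
    "LBR",
    "SelfAttention",
    "RelationAttention",
    "PositionEncoder",
    "self_attention",
    "position_encode",
    "relation_attention",
]


class Module:
    """Parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        limit = np.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
        self.weight = Tensor(rng.uniform(-limit, limit, (d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x) -> Tensor:
        out = _lift(x) @ self.weight
        return out + self.bias if self.bias is not None else out


class BatchNorm(Module):
    """Feature-wise normalisation over all leading axes (the point axis).

    The network processes one whole cloud per forward pass, so the "batch"
    is the cloud itself: statistics are computed over the current cloud's
    points at training *and* inference time (instance-normalisation
    behaviour).  This keeps inference deterministic per cloud and avoids
    the train/eval statistics mismatch that running estimates suffer when
    every forward pass sees a differently-posed cloud.  Running estimates
    are still tracked during training for inspection.
    """

    def __init__(self, d: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)

    def __call__(self, x, training: bool = True) -> Tensor:
        x = _lift(x)
        flat_axes = tuple(range(x.ndim - 1))
        # reduce over every axis but the feature axis
        mean = x
        for ax in reversed(flat_axes):
            mean = mean.mean(axis=ax)
        centered = x - mean
        var = centered * centered
        for ax in reversed(flat_axes):
            var = var.mean(axis=ax)
        if training:
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * np.atleast_1d(mean.data)
            self.running_var = m * self.running_var + (1 - m) * np.atleast_1d(var.data)
        inv_std = (var + self.eps) ** -0.5
        return centered * inv_std * self.gamma + self.beta


class LBR(Module):
    """Linear -> BatchNorm -> ReLU."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.linear = Linear(d_in, d_out, rng)
        self.bn = BatchNorm(d_out)

    def __call__(self, x, training: bool = True) -> Tensor:
        return self.bn(self.linear(x), training=training).relu()


class SelfAttention(Module):
    """Scaled dot-product self-attention, global or within k-NN patches."""

    def __init__(self, d_model: int, d_a: int, rng: np.random.Generator, scale: str = "da"):
        if d_a > d_model:
            raise ValueError(f"d_a={d_a} must be <= d_model={d_model}")
        if scale not in ("da", "sqrt"):
            raise ValueError("scale must be 'da' or 'sqrt'")
        self.wq = Linear(d_model, d_a, rng, bias=False)
        self.wk = Linear(d_model, d_a, rng, bias=False)
        self.wv = Linear(d_model, d_model, rng, bias=False)
        self.d_a = d_a
        self.scale = scale

    def _denom(self) -> float:
        return float(self.d_a) if self.scale == "da" else float(np.sqrt(self.d_a))

    def __call__(self, x, neighbors: np.ndarray | None = None) -> Tensor:
        x = _lift(x)
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        if neighbors is None:
            scores = (q @ k.transpose()) * (1.0 / self._denom())
            attn = softmax(scores, axis=-1)  # rows sum to 1
            return attn @ v
        # local: each point attends over its k-NN patch
        k_nb = k.gather(neighbors)  # (M, k, d_a)
        v_nb = v.gather(neighbors)  # (M, k, d_model)
        scores = (q.expand_dims(1) * k_nb).sum(axis=-1) * (1.0 / self._denom())  # (M, k)
        attn = softmax(scores, axis=-1)
        return (attn.expand_dims(-1) * v_nb).sum(axis=1)

    def attention_rows(self, x, neighbors: np.ndarray | None = None) -> np.ndarray:
        """Softmax attention weights (for inspection/testing)."""
        x = _lift(x)
        q, k = self.wq(x), self.wk(x)
        if neighbors is None:
            scores = (q @ k.transpose()) * (1.0 / self._denom())
        else:
            k_nb = k.gather(neighbors)
            scores = (q.expand_dims(1) * k_nb).sum(axis=-1) * (1.0 / self._denom())
        return softmax(scores, axis=-1).data


class RelationAttention(Module):
    """Residual relation-attention block.

    The update subtracts the self-attention transform from the input (a
    Laplacian-style deviation feature), maps it through LBR, and adds the
    input back: zeroing the LBR recovers the identity map.
    """

    def __init__(self, d_model: int, d_a: int, rng: np.random.Generator, scale: str = "da"):
        self.sa = SelfAttention(d_model, d_a, rng, scale=scale)
        self.lbr = LBR(d_model, d_model, rng)

    def __call__(self, x, neighbors: np.ndarray | None = None, training: bool = True) -> Tensor:
        x = _lift(x)
        f_sa = self.sa(x, neighbors=neighbors)
        f_ra = x - f_sa
        return self.lbr(f_ra, training=training) + x


class PositionEncoder(Module):
    """phi: 2-layer MLP (one ReLU) on xyz; psi: linear on concat(f, delta)."""

    def __init__(self, d_feat: int, d_model: int, rng: np.random.Generator, d_pos: int | None = None):
        d_pos = d_model if d_pos is None else d_pos
        self.phi1 = Linear(3, d_pos, rng)
        self.phi2 = Linear(d_pos, d_pos, rng)
        self.psi = Linear(d_feat + d_pos, d_model, rng)

    def __call__(self, coords, f) -> Tensor:
        delta = self.phi2(self.phi1(coords).relu())
        return self.psi(concat([_lift(f), delta], axis=-1))


# -- functional wrappers (NumPy in, NumPy out) -----------------------------


def self_attention(f_in: np.ndarray, weights: SelfAttention, neighbors=None) -> np.ndarray:
    """Apply a configured self-attention block to a feature field."""
    return weights(np.asarray(f_in, dtype=float), neighbors=neighbors).data


def position_encode(coords: np.ndarray, f: np.ndarray, encoder: PositionEncoder) -> np.ndarray:
    """Combine raw features with encoded coordinates into network input."""
    return encoder(np.asarray(coords, dtype=float), np.asarray(f, dtype=float)).data


def relation_attention(
    f_in: np.ndarray, block: RelationAttention, neighbors=None, training: bool = False
) -> np.ndarray:
    """Apply a relation-attention block; output shape equals input shape."""
    return block(np.asarray(f_in, dtype=float), neighbors=neighbors, training=training).data
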