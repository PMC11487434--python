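"""Relation-attention encoder–decoder for point-cloud part segmentation.

U-Net-style: the input cloud is embedded to ``base_width`` features by an
MLP, then passed through four downsampling stages (FPS subset, local
max-pooling over k-NN patches, per-stage position encoding, relation
attention) and four mirrored upsampling stages (inverse-distance
interpolation from the coarse level, concatenation with the same-resolution
encoder features, Linear–BatchNorm–ReLU fusion).  A small head maps the
restored full-resolution features to per-point class scores.

Coordinates are normalised to the unit sphere before entering the network;
the pyramid (FPS levels, k-NN patches, interpolation weights) depends only
on geometry and is cached per cloud.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ..io import PointCloud
from .autodiff import Tensor, concat
from .graph import Pyramid, build_pyramid
from .layers import LBR, Linear, Module, PositionEncoder, RelationAttention

__all__ = ["NetworkConfig", "RelationAttentionSegNet", "encode_decode"]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    Defaults follow the full-size network (3072-point input, widths
    64/128/256/512, 1/4 downsampling per stage, so the bottleneck holds 12
    points); tests and the training sanity check use a reduced copy.
    """

    input_points: int = 3072
    base_width: int = 64
    stage_widths: tuple = (64, 128, 256, 512)
    downsample_ratio: int = 4
    num_classes: int = 2
    k_neighbors: int = 16
    attention_scale: str = "da"  # "da" (as defined) or "sqrt" (conventional)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stage_widths) != 4:
            raise ValueError("stage_widths must have exactly 4 entries")
        if self.input_points < self.downsample_ratio ** len(self.stage_widths):
            raise ValueError("input_points too small for 4 downsampling stages")


class RelationAttentionSegNet(Module):
    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        base = config.base_width
        widths = list(config.stage_widths)
        self.embed = LBR(3, base, rng)
        prev = base
        self.pool_lbrs, self.posencs, self.ras = [], [], []
        for w in widths:
            self.pool_lbrs.append(LBR(prev, w, rng))
            self.posencs.append(PositionEncoder(w, w, rng))
            self.ras.append(RelationAttention(w, max(1, w // 4), rng, scale=config.attention_scale))
            prev = w
        # decoder: coarse -> fine, fusing skip features at each resolution
        skip_widths = [base] + widths[:-1]
        self.dec_lbrs = []
        for w_coarse, w_skip in zip(reversed(widths), reversed(skip_widths)):
            self.dec_lbrs.append(LBR(w_coarse + w_skip, w_skip, rng))
        self.head_lbr = LBR(base, base, rng)
        self.head_out = Linear(base, config.num_classes, rng)
        self._pyramid_cache: dict = {}

    # -- geometry ----------------------------------------------------------
    def pyramid_for(self, points: np.ndarray, cache_key=None) -> Pyramid:
        if cache_key is not None and cache_key in self._pyramid_cache:
            return self._pyramid_cache[cache_key]
        pts = np.asarray(points, dtype=float)
        centered = pts - pts.mean(axis=0)
        radius = np.linalg.norm(centered, axis=1).max()
        if radius <= 0:
            raise ValueError("degenerate cloud")
        unit = centered / radius
        # start FPS from the point farthest from the centroid: a geometric,
        # order-independent choice so outputs are permutation-equivariant
        start = int(np.argmax(np.linalg.norm(unit, axis=1)))
        pyr = build_pyramid(
            unit,
            n_stages=len(self.config.stage_widths),
            ratio=self.config.downsample_ratio,
            k_neighbors=self.config.k_neighbors,
            start=start,
        )
        if cache_key is not None:
            self._pyramid_cache[cache_key] = pyr
        return pyr

    # -- forward -----------------------------------------------------------
    def forward(self, pyramid: Pyramid, training: bool = False) -> Tensor:
        f = self.embed(pyramid.coords, training=training)
        skips = [f]
        for stage, pool_lbr, posenc, ra in zip(
            pyramid.stages, self.pool_lbrs, self.posencs, self.ras
        ):
            # local max-pool over k-NN patches of the finer level
            patch = f.gather(stage.pool_idx)  # (M, k, w_prev)
            pooled = patch.max(axis=1)
            g = pool_lbr(pooled, training=training)
            g = posenc(stage.coords, g)
            f = ra(g, neighbors=stage.attn_idx, training=training)
            skips.append(f)
        # decode coarse -> fine
        for stage, skip, dec in zip(reversed(pyramid.stages), reversed(skips[:-1]), self.dec_lbrs):
            up = f.gather(stage.up_idx)  # (M_fine, 3, w)
            up = (up * Tensor(stage.up_w[:, :, None])).sum(axis=1)
            f = dec(concat([up, skip], axis=-1), training=training)
        f = self.head_lbr(f, training=training)
        return self.head_out(f)

    def scores(self, points: np.ndarray, cache_key=None, training: bool = False) -> np.ndarray:
        return self.forward(self.pyramid_for(points, cache_key), training=training).data

    def predict(self, cloud) -> np.ndarray:
        """Per-point class labels for a cloud (eval mode).

        A cloud larger than the network's input size is first FPS-sampled
        down to it (the sample-then-predict pipeline); points outside the
        sample are returned as class 0 (unclassified background).
        """
        pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, float)
        m = self.config.input_points
        if pts.shape[0] > m:
            from ..sampling import farthest_point_sampling

            idx = farthest_point_sampling(pts, m).indices
            labels = np.zeros(pts.shape[0], dtype=np.int64)
            labels[idx] = np.argmax(self.scores(pts[idx]), axis=1)
            return labels
        return np.argmax(self.scores(pts), axis=1)

    # -- (de)serialisation -------------------------------------------------
    def _named_state(self) -> dict:
        state: dict[str, np.ndarray] = {}

        def walk(obj: Module, prefix: str):
            for name, value in vars(obj).items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor) and value.requires_grad:
                    state[key] = value.data
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, list) and value and isinstance(value[0], Module):
                    for i, item in enumerate(value):
                        walk(item, f"{key}.{i}.")
                elif isinstance(value, np.ndarray) and name.startswith("running_"):
                    state[key] = value

        walk(self, "")
        return state

    def save(self, path) -> None:
        """Single-file checkpoint archive with the config embedded."""
        state = self._named_state()
        np.savez(path, __config__=json.dumps(asdict(self.config)), **state)

    @classmethod
    def load(cls, path) -> "RelationAttentionSegNet":
        with np.load(path, allow_pickle=False) as blob:
            cfg_dict = json.loads(str(blob["__config__"]))
            cfg_dict["stage_widths"] = tuple(cfg_dict["stage_widths"])
            model = cls(NetworkConfig(**cfg_dict))
            state = model._named_state()
            for key, arr in state.items():
                arr[...] = blob[key]
        return model


def encode_decode(
    cloud, config: NetworkConfig | None = None, model: RelationAttentionSegNet | None = None
) -> np.ndarray:
    """Run the encoder–decoder on one cloud, returning N x s class scores.

    With no trained ``model``, a randomly initialised network from
    ``config`` is used (deterministic given ``config.seed``).
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, dtype=float)
    if model is None:
        cfg = config if config is not None else NetworkConfig(input_points=pts.shape[0])
        model = RelationAttentionSegNet(cfg)
    return model.scores(pts)
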