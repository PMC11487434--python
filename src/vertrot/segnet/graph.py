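"""Geometric scaffolding of the encoder–decoder: k-NN patches, FPS
pyramids, and inverse-distance interpolation for upsampling.

The point pyramid depends only on the coordinates, never on features or
weights, so it is built once per cloud and reused across training steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ..sampling import farthest_point_sampling

__all__ = ["knn_group", "interpolation_weights", "Pyramid", "build_pyramid"]


def knn_group(cloud, k: int) -> np.ndarray:
    """Each point's ``k`` nearest neighbours (self included), ties by index.

    Exact brute-force with a stable sort so that equal distances resolve to
    the lower index; O(N^2), fine at network stage sizes.
    """
    pts = np.asarray(cloud if isinstance(cloud, np.ndarray) else cloud.points, dtype=float)
    n = pts.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, N={n}]")
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return np.argsort(d2, axis=1, kind="stable")[:, :k]


def _cross_knn(query: np.ndarray, ref: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k nearest points of ``ref`` for each row of ``query`` (distances, idx)."""
    tree = cKDTree(ref)
    d, idx = tree.query(query, k=min(k, ref.shape[0]))
    if idx.ndim == 1:
        d, idx = d[:, None], idx[:, None]
    return d, idx


def interpolation_weights(
    fine: np.ndarray, coarse: np.ndarray, k: int = 3, eps: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-distance weights over the ``k`` nearest coarse points.

    The point-set realisation of "trilinear" upsampling: each fine point's
    feature is the weighted mean of its 3 nearest coarse features, weights
    1/(d+eps) normalised to sum to 1 (an exact-coincidence point gets
    essentially all the mass).
    """
    d, idx = _cross_knn(fine, coarse, k)
    w = 1.0 / (d + eps)
    w /= w.sum(axis=1, keepdims=True)
    return idx, w


@dataclass
class PyramidStage:
    """One encoder resolution level."""

    coords: np.ndarray  # (M, 3)
    sample_idx: np.ndarray  # indices into the previous stage
    pool_idx: np.ndarray  # (M, k) neighbours in the previous stage (for max-pool)
    attn_idx: np.ndarray  # (M, k) neighbours within this stage (for attention)
    up_idx: np.ndarray  # (M_prev, 3) coarse indices for upsampling back
    up_w: np.ndarray  # (M_prev, 3) interpolation weights


@dataclass
class Pyramid:
    """Fixed multi-resolution structure of one input cloud."""

    coords: np.ndarray  # stage-0 (input) coordinates
    attn_idx: np.ndarray  # stage-0 attention neighbourhoods
    stages: list  # list[PyramidStage], coarse-ward


def build_pyramid(
    points: np.ndarray,
    n_stages: int = 4,
    ratio: int = 4,
    k_neighbors: int = 16,
    start: int = 0,
) -> Pyramid:
    """FPS pyramid with per-stage pooling/attention/upsampling indices."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < ratio**n_stages:
        raise ValueError(
            f"cloud of {n} points cannot be downsampled {n_stages} times by 1/{ratio}"
        )
    stages: list[PyramidStage] = []
    prev = pts
    k0 = min(k_neighbors, n)
    attn0 = knn_group(pts, k0)
    for depth in range(n_stages):
        m = prev.shape[0] // ratio
        # FPS places its start point first, so index 0 at deeper stages
        # keeps the same physical start point
        stage_start = start if depth == 0 else 0
        sample = farthest_point_sampling(prev, m, start=stage_start).indices
        coords = prev[sample]
        _, pool_idx = _cross_knn(coords, prev, min(k_neighbors, prev.shape[0]))
        attn_idx = knn_group(coords, min(k_neighbors, m))
        up_idx, up_w = interpolation_weights(prev, coords, k=3)
        stages.append(
            PyramidStage(
                coords=coords,
                sample_idx=sample,
                pool_idx=pool_idx,
                attn_idx=attn_idx,
                up_idx=up_idx,
                up_w=up_w,
            )
        )
        prev = coords
    return Pyramid(coords=pts, attn_idx=attn0, stages=stages)
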