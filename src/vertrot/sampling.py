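"""Farthest-point sampling and its entropy-augmented variant.

Plain FPS greedily picks the point farthest from the already-selected set,
which yields uniform coverage but ignores how informative a region is.  The
entropy-augmented variant weights the max–min distance by the Shannon
entropy of each candidate's local distance distribution, biasing selection
toward regions whose neighbourhood geometry is heterogeneous (edges,
protrusions, sparse patches) — useful for vertebrae, where the arch and
pedicles are sampled much more densely than the body.

Score for candidate ``c`` given the selected set ``S``::

    score(c) = d_min(c, S) * (1 + lambda * H_hat(c))

where ``H_hat(c)`` is the entropy of the histogram of c's k nearest-neighbour
distances, min–max rescaled to [0, 1] over the whole cloud.  ``lambda = 0``
reduces bit-for-bit to plain FPS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree, distance_matrix

from .io import LabeledPointCloud, PointCloud

__all__ = [
    "SamplingResult",
    "pairwise_distances",
    "distance_entropy",
    "local_entropies",
    "farthest_point_sampling",
    "entropy_fps",
    "resample_to_size",
]

DEFAULT_BINS = 32
DEFAULT_EPS = 1e-12


def _as_points(cloud) -> np.ndarray:
    if isinstance(cloud, PointCloud):
        return cloud.points
    pts = np.asarray(cloud, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected N x 3 points, got shape {pts.shape}")
    return pts


@dataclass(frozen=True)
class SamplingResult:
    """Selected indices into the source cloud, with per-pick scores."""

    indices: np.ndarray
    scores: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.indices)


def pairwise_distances(cloud) -> np.ndarray:
    """Full symmetric Euclidean distance matrix."""
    pts = _as_points(cloud)
    d = distance_matrix(pts, pts)
    np.fill_diagonal(d, 0.0)
    return d


def distance_entropy(
    distances,
    bins: int = DEFAULT_BINS,
    eps: float = DEFAULT_EPS,
    bin_range: tuple | None = None,
) -> float:
    """Shannon entropy (natural log) of the histogram of a distance multiset.

    ``H = -sum_i P_i * log(P_i + eps)`` over occupied histogram bins, where
    ``P`` is the bin frequency distribution.  A degenerate multiset (all
    distances equal) occupies a single bin and gives H ~ 0.  ``bin_range``
    fixes the histogram support explicitly (used to put several
    neighbourhoods on a common discretisation).
    """
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty distance set")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    lo, hi = (d.min(), d.max()) if bin_range is None else bin_range
    if hi - lo <= np.finfo(float).eps * max(abs(hi), abs(lo), 1.0) * bins:
        # all distances (numerically) identical: a single occupied bin
        return float(-np.log(1.0 + eps))
    counts, _ = np.histogram(d, bins=bins, range=(lo, hi))
    p = counts / counts.sum()
    occupied = p > 0
    return float(-np.sum(p[occupied] * np.log(p[occupied] + eps)))


def local_entropies(
    cloud,
    k_local: int = 16,
    bins: int = DEFAULT_BINS,
    eps: float = DEFAULT_EPS,
    normalize: bool = True,
) -> np.ndarray:
    """Per-point distance-distribution entropy of the k-NN neighbourhood.

    All neighbourhoods are histogrammed on one common bin range (0 to the
    largest k-NN distance in the cloud), so the entropy is sensitive to
    local density: a point inside a dense clump concentrates its mass in
    few bins (low entropy) while a point in a sparse or heterogeneous
    region spreads over many (high entropy).  With ``normalize=True`` the
    entropies are min–max rescaled to [0, 1] over the cloud (all-equal
    entropies map to zero).
    """
    pts = _as_points(cloud)
    n = pts.shape[0]
    if k_local >= n:
        raise ValueError(f"k_local={k_local} must be < N={n}")
    tree = cKDTree(pts)
    # self is always the nearest neighbour at distance 0; drop it
    dists, _ = tree.query(pts, k=k_local + 1)
    dists = dists[:, 1:]
    common = (0.0, float(dists.max()))
    h = np.array(
        [distance_entropy(row, bins=bins, eps=eps, bin_range=common) for row in dists]
    )
    if normalize:
        span = h.max() - h.min()
        h = (h - h.min()) / span if span > 0 else np.zeros_like(h)
    return h


def _greedy_maxmin(
    pts: np.ndarray, m: int, start: int, weights: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy max–min selection; ``weights`` multiplies the min-distance
    score (None = plain FPS).  Ties break to the lowest index (argmax)."""
    n = pts.shape[0]
    indices = np.empty(m, dtype=np.int64)
    scores = np.empty(m, dtype=float)
    indices[0] = start
    scores[0] = np.inf
    dmin = np.linalg.norm(pts - pts[start], axis=1)
    for j in range(1, m):
        score = dmin if weights is None else dmin * weights
        pick = int(np.argmax(score))
        indices[j] = pick
        scores[j] = float(score[pick])
        np.minimum(dmin, np.linalg.norm(pts - pts[pick], axis=1), out=dmin)
    return indices, scores


def _resolve_start(start, n: int) -> int:
    if start is None:
        return 0
    start = int(start)
    if not 0 <= start < n:
        raise ValueError(f"start index {start} out of range [0, {n})")
    return start


def farthest_point_sampling(cloud, m: int, start: int = 0) -> SamplingResult:
    """Greedy max–min (farthest point) subset of size ``m``.

    Deterministic given ``start``; every prefix of the result is itself the
    FPS result for that smaller size.
    """
    pts = _as_points(cloud)
    n = pts.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"m={m} must be in [1, N={n}]")
    start = _resolve_start(start, n)
    indices, scores = _greedy_maxmin(pts, m, start, None)
    return SamplingResult(indices=indices, scores=scores)


def entropy_fps(
    cloud,
    m: int,
    k_local: int = 16,
    bins: int = DEFAULT_BINS,
    eps: float = DEFAULT_EPS,
    lam: float = 1.0,
    start: int = 0,
) -> SamplingResult:
    """FPS with the max–min distance weighted by local distance entropy.

    ``lam = 0`` is bit-identical to :func:`farthest_point_sampling`.
    """
    pts = _as_points(cloud)
    n = pts.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"m={m} must be in [1, N={n}]")
    if lam < 0:
        raise ValueError("lambda weight must be nonnegative")
    start = _resolve_start(start, n)
    if lam == 0.0 or n == 1:
        weights = None
    else:
        h = local_entropies(pts, k_local=k_local, bins=bins, eps=eps, normalize=True)
        weights = 1.0 + lam * h
    indices, scores = _greedy_maxmin(pts, m, start, weights)
    return SamplingResult(indices=indices, scores=scores)


def resample_to_size(
    labeled: LabeledPointCloud,
    m: int = 3072,
    draws: int = 2,
    seed: int = 0,
    method: str = "entropy-fps",
    lam: float = 1.0,
    k_local: int = 16,
    bins: int = DEFAULT_BINS,
) -> list[LabeledPointCloud]:
    """Fixed-size downsampling for network input, with dataset expansion.

    Each draw is an independent FPS (or entropy-FPS) subset of size ``m``
    started from a different seed-derived index; labels follow their points.
    Multiple draws of the same vertebra expand a small labelled dataset.
    """
    n = len(labeled)
    if m > n:
        raise ValueError(f"cannot resample {n} points up to {m} (no upsampling)")
    if draws < 1:
        raise ValueError("draws must be >= 1")
    rng = np.random.default_rng(seed)
    starts = rng.choice(n, size=draws, replace=(draws > n))
    out = []
    for start in starts:
        if method == "fps":
            res = farthest_point_sampling(labeled.cloud, m, start=int(start))
        elif method == "entropy-fps":
            res = entropy_fps(
                labeled.cloud, m, k_local=k_local, bins=bins, lam=lam, start=int(start)
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        out.append(
            LabeledPointCloud(
                PointCloud(labeled.cloud.points[res.indices], name=labeled.cloud.name),
                labeled.labels[res.indices],
            )
        )
    return out
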