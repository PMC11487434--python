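"""Synthetic labelled vertebra phantoms with known ground truth.

The phantom emulates a single vertebra as reconstructed surface data: a
squat elliptical-cylinder body, two parallel endplate caps (with a short
labelled rim band), and two posterior pedicle blobs, with the pedicle/arch
region sampled more densely than the body (the density skew that motivates
entropy-weighted sampling).  The whole cloud is rotated axially about the
endplate axis by a known angle, optionally tilted, and optionally perturbed
by isotropic Gaussian surface noise applied *after* labelling so labels
stay exact.

Every structure is generated with mirror symmetry (caps and rims across the
sagittal plane, the right pedicle as the mirror image of the left, the
lower cap as the mirror image of the upper), so the exact group means obey
the local-frame construction and the measured angle of a noiseless phantom
equals the applied axial angle to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .anatomy import EndplateCenters, PedicleCenters, local_frame, rotation_angle, transverse_plane
from .io import LabeledPointCloud, PointCloud

__all__ = ["PhantomConfig", "PhantomTruth", "generate_vertebra", "generate_dataset"]


@dataclass
class PhantomConfig:
    """Geometry and sampling parameters (mm, degrees)."""

    body_radius_x: float = 22.0  # lateral semi-axis of the body ellipse
    body_radius_y: float = 16.0  # antero-posterior semi-axis
    body_height: float = 28.0
    endplate_thickness: float = 2.0  # rim band below/above each cap labelled as endplate
    pedicle_lateral: float = 15.0  # +/- x offset of the pedicle centers
    pedicle_posterior: float = 20.0  # -y offset of the pedicle centers
    pedicle_radius: float = 4.0
    n_body: int = 2400
    n_endplate: int = 700  # per cap (disk + rim)
    n_pedicle: int = 400  # per pedicle, before density skew
    density_skew: float = 2.0  # multiplies pedicle/arch point counts
    noise_sd: float = 0.0
    theta_deg: float = 0.0  # axial rotation about the endplate axis
    tilt_deg: float = 0.0  # subsequent tilt about the global x-axis
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "body_radius_x",
            "body_radius_y",
            "body_height",
            "endplate_thickness",
            "pedicle_lateral",
            "pedicle_posterior",
            "pedicle_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.endplate_thickness * 2 >= self.body_height:
            raise ValueError("endplate rim bands overlap: thickness too large")
        if self.noise_sd < 0 or self.density_skew <= 0:
            raise ValueError("noise_sd must be >= 0 and density_skew > 0")


@dataclass
class PhantomTruth:
    """Generator ground truth for one phantom."""

    theta_true: float  # angle the landmark construction yields (pre-noise)
    applied_axial_deg: float
    endplate_centers: EndplateCenters
    pedicle_centers: PedicleCenters
    endplate_labels: np.ndarray = field(repr=False, default=None)
    pedicle_labels: np.ndarray = field(repr=False, default=None)
    rotation: np.ndarray = field(repr=False, default=None)


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _mirror_x(pts: np.ndarray) -> np.ndarray:
    out = pts.copy()
    out[:, 0] *= -1.0
    return out


def _mirror_z(pts: np.ndarray) -> np.ndarray:
    out = pts.copy()
    out[:, 2] *= -1.0
    return out


def _upper_cap(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Disk + rim band at the top of the body, sagittally mirror-symmetric."""
    half_h = cfg.body_height / 2.0
    n_disk = max(2, int(round(cfg.n_endplate * 0.75))) // 2
    n_rim = max(2, cfg.n_endplate - 2 * n_disk) // 2
    # area-uniform points on the elliptical disk (x > 0 half, then mirrored)
    r = np.sqrt(rng.uniform(0.0, 1.0, n_disk))
    phi = rng.uniform(-np.pi / 2.0, np.pi / 2.0, n_disk)
    disk = np.column_stack(
        [
            cfg.body_radius_x * r * np.cos(phi),
            cfg.body_radius_y * r * np.sin(phi),
            np.full(n_disk, half_h),
        ]
    )
    phi_rim = rng.uniform(-np.pi / 2.0, np.pi / 2.0, n_rim)
    z_rim = rng.uniform(half_h - cfg.endplate_thickness, half_h, n_rim)
    rim = np.column_stack(
        [
            cfg.body_radius_x * np.cos(phi_rim),
            cfg.body_radius_y * np.sin(phi_rim),
            z_rim,
        ]
    )
    half = np.vstack([disk, rim])
    return np.vstack([half, _mirror_x(half)])


def _body(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Lateral surface between the rim bands (background for both tasks)."""
    half_h = cfg.body_height / 2.0 - cfg.endplate_thickness
    phi = rng.uniform(0.0, 2.0 * np.pi, cfg.n_body)
    z = rng.uniform(-half_h, half_h, cfg.n_body)
    return np.column_stack(
        [cfg.body_radius_x * np.cos(phi), cfg.body_radius_y * np.sin(phi), z]
    )


def _left_pedicle(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    n = max(2, int(round(cfg.n_pedicle * cfg.density_skew)))
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    center = np.array([-cfg.pedicle_lateral, -cfg.pedicle_posterior, 0.0])
    return center + cfg.pedicle_radius * v


def generate_vertebra(
    config: PhantomConfig | None = None, **overrides
) -> tuple[LabeledPointCloud, LabeledPointCloud, PhantomTruth]:
    """One phantom: endplate-task labels, pedicle-task labels, ground truth.

    Both labelled clouds share the same underlying points.
    """
    cfg = config if config is not None else PhantomConfig(**overrides)
    if config is not None and overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(cfg.seed)

    upper = _upper_cap(cfg, rng)
    lower = _mirror_z(upper)
    body = _body(cfg, rng)
    left = _left_pedicle(cfg, rng)
    right = _mirror_x(left)

    points = np.vstack([upper, lower, body, left, right])
    n_up, n_lo, n_bd, n_pd = len(upper), len(lower), len(body), len(left)
    ep_labels = np.zeros(len(points), dtype=np.int64)
    ep_labels[: n_up + n_lo] = 1
    pd_labels = np.zeros(len(points), dtype=np.int64)
    pd_labels[n_up + n_lo + n_bd :] = 1

    rot = _rot_x(cfg.tilt_deg) @ _rot_z(cfg.theta_deg)
    points = points @ rot.T

    # exact group means of the generated structures are the true landmarks
    ep_true = EndplateCenters(
        upper=upper.mean(axis=0) @ rot.T, lower=lower.mean(axis=0) @ rot.T
    )
    left_c, right_c = left.mean(axis=0) @ rot.T, right.mean(axis=0) @ rot.T
    if left_c[0] > right_c[0]:
        left_c, right_c = right_c, left_c
    pc_true = PedicleCenters(left=left_c, right=right_c)
    frame = local_frame(ep_true, pc_true)
    plane = transverse_plane(ep_true)
    theta_true = rotation_angle(frame, plane_normal=plane.normal)

    if cfg.noise_sd > 0:
        points = points + rng.normal(scale=cfg.noise_sd, size=points.shape)

    cloud = PointCloud(points, name=f"phantom-seed{cfg.seed}")
    truth = PhantomTruth(
        theta_true=float(theta_true),
        applied_axial_deg=float(cfg.theta_deg),
        endplate_centers=ep_true,
        pedicle_centers=pc_true,
        endplate_labels=ep_labels,
        pedicle_labels=pd_labels,
        rotation=rot,
    )
    return (
        LabeledPointCloud(cloud, ep_labels),
        LabeledPointCloud(cloud, pd_labels),
        truth,
    )


def generate_dataset(
    n: int,
    theta_range: tuple = (0.0, 25.0),
    config: PhantomConfig | None = None,
    seed: int = 0,
) -> tuple[list, pd.DataFrame]:
    """``n`` phantoms with axial angles uniform in ``theta_range``.

    Returns the list of ``(endplate_task, pedicle_task, truth)`` triples and
    a manifest table of the ground truths.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = theta_range
    template = asdict(config) if config is not None else asdict(PhantomConfig())
    rng = np.random.default_rng(seed)
    thetas = rng.uniform(lo, hi, n)
    items, rows = [], []
    for i, theta in enumerate(thetas):
        params = dict(template)
        params["theta_deg"] = float(theta)
        params["seed"] = int(rng.integers(0, 2**31 - 1))
        triple = generate_vertebra(PhantomConfig(**params))
        items.append(triple)
        rows.append(
            {
                "index": i,
                "theta_applied_deg": params["theta_deg"],
                "theta_true_deg": triple[2].theta_true,
                "noise_sd": params["noise_sd"],
                "seed": params["seed"],
                "n_points": len(triple[0]),
            }
        )
    return items, pd.DataFrame(rows)
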