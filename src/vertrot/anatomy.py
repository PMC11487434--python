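"""From segmented structures to the vertebral rotation angle.

Given the endplate and pedicle point clouds of one vertebra (predicted by
the network or supplied as labels), the measurement proceeds:

1. split the endplate cloud into upper/lower caps (k-means, k=2) and take
   the cluster means as endplate centers;
2. cluster the pedicle cloud into left/right (k-means, k=2);
3. vertebral centroid = midpoint of the endplate centers; the transverse
   plane passes through it with normal along the endplate axis;
4. local frame: z along the endplate axis, y from the pedicle midpoint
   toward the centroid (anterior), x = y x z.  y and z are not forced
   orthogonal — the angle uses only in-plane projections, so a small
   non-orthogonality is harmless;
5. rotation angle = angle between the projections of the local y-axis and
   the global reference axis (default (0,1,0)) onto the transverse plane,
   reported unsigned in [0, 180] degrees (a signed variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .io import PointCloud

__all__ = [
    "EndplateCenters",
    "PedicleCenters",
    "Plane",
    "LocalFrame",
    "DegenerateGeometryError",
    "split_endplates",
    "pedicle_centers",
    "vertebral_centroid",
    "transverse_plane",
    "local_frame",
    "rotation_angle",
    "measure_vertebra",
    "center_offset",
]

GLOBAL_Y = np.array([0.0, 1.0, 0.0])


class DegenerateGeometryError(ValueError):
    """Landmark configuration too degenerate to define the requested object."""


@dataclass(frozen=True)
class EndplateCenters:
    upper: np.ndarray
    lower: np.ndarray

    def axis(self) -> np.ndarray:
        return np.asarray(self.upper, float) - np.asarray(self.lower, float)


@dataclass(frozen=True)
class PedicleCenters:
    left: np.ndarray
    right: np.ndarray
    assignment_rule: str = "left = smaller projection on global X"

    def midpoint(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.left, float) + np.asarray(self.right, float))


@dataclass(frozen=True)
class Plane:
    point: np.ndarray
    normal: np.ndarray


@dataclass(frozen=True)
class LocalFrame:
    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray


def _unit(v: np.ndarray, what: str, tol: float) -> np.ndarray:
    n = np.linalg.norm(v)
    if n <= tol:
        raise DegenerateGeometryError(f"{what} has near-zero length ({n:.3g})")
    return v / n


def _tolerance(points: np.ndarray | None, rel: float = 1e-6) -> float:
    """Degeneracy tolerance: rel x cloud diameter (falls back to absolute)."""
    if points is None:
        return 1e-12
    lo, hi = points.min(axis=0), points.max(axis=0)
    diam = float(np.linalg.norm(hi - lo))
    return max(rel * diam, 1e-300)


def _kmeans2(points: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(points)
    return labels, km.cluster_centers_


def split_endplates(
    endplate_points: PointCloud, seed: int = 0
) -> tuple[PointCloud, PointCloud, EndplateCenters]:
    """Partition an endplate cloud into upper/lower caps.

    K-means with k=2; "upper" is the cluster whose center projects further
    along the inter-center axis oriented toward positive global Z (falling
    back to Y then X if the axis is exactly transverse).
    """
    pts = endplate_points.points
    if pts.shape[0] < 2:
        raise DegenerateGeometryError("need at least 2 endplate points to split")
    labels, centers = _kmeans2(pts, seed)
    axis = centers[0] - centers[1]
    tol = _tolerance(pts)
    if np.linalg.norm(axis) <= tol:
        raise DegenerateGeometryError("endplate clusters are not separable")
    # orient the axis toward +Z (tie-break +Y, then +X)
    for comp in (2, 1, 0):
        if abs(axis[comp]) > tol:
            if axis[comp] < 0:
                axis = -axis
            break
    proj = centers @ axis
    upper_cluster = int(np.argmax(proj))
    upper_mask = labels == upper_cluster
    upper = PointCloud(pts[upper_mask], name=endplate_points.name)
    lower = PointCloud(pts[~upper_mask], name=endplate_points.name)
    ep = EndplateCenters(
        upper=pts[upper_mask].mean(axis=0), lower=pts[~upper_mask].mean(axis=0)
    )
    return upper, lower, ep


def pedicle_centers(pedicle_points: PointCloud, seed: int = 0) -> PedicleCenters:
    """Left/right pedicle centers by k-means (k=2), seeded.

    "Left" is the center with the smaller projection on global X (tie-break
    by Y, then Z).
    """
    pts = pedicle_points.points
    if pts.shape[0] < 2:
        raise DegenerateGeometryError("need at least 2 pedicle points")
    tol = _tolerance(pts)
    if np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)) <= tol:
        raise DegenerateGeometryError("all pedicle points coincide")
    _, centers = _kmeans2(pts, seed)
    order = np.lexsort((centers[:, 2], centers[:, 1], centers[:, 0]))
    left, right = centers[order[0]], centers[order[1]]
    return PedicleCenters(left=left, right=right)


def vertebral_centroid(ep: EndplateCenters) -> np.ndarray:
    """Midpoint of the upper and lower endplate centers."""
    return 0.5 * (np.asarray(ep.upper, float) + np.asarray(ep.lower, float))


def transverse_plane(ep: EndplateCenters, tol: float | None = None) -> Plane:
    """Plane through the vertebral centroid, normal along the endplate axis."""
    axis = ep.axis()
    tol = 1e-12 if tol is None else tol
    normal = _unit(axis, "endplate axis", tol)
    return Plane(point=vertebral_centroid(ep), normal=normal)


def local_frame(ep: EndplateCenters, pc: PedicleCenters, tol: float | None = None) -> LocalFrame:
    """Anatomical frame: z = endplate axis, y = pedicle midpoint -> centroid
    (anterior), x = y x z.  All axes unit length; y and z need not be
    exactly orthogonal."""
    tol = 1e-12 if tol is None else tol
    origin = vertebral_centroid(ep)
    z = _unit(ep.axis(), "endplate axis", tol)
    y = _unit(origin - pc.midpoint(), "pedicle-to-centroid axis", tol)
    x_raw = np.cross(y, z)
    if np.linalg.norm(x_raw) <= tol:
        raise DegenerateGeometryError("y-axis is parallel to the endplate axis")
    x = x_raw / np.linalg.norm(x_raw)
    return LocalFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def _project(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return v - (v @ normal) * normal


def rotation_angle(
    frame: LocalFrame,
    global_y: np.ndarray = GLOBAL_Y,
    plane_normal: np.ndarray | None = None,
    signed: bool = False,
    tol: float = 1e-12,
) -> float:
    """Axial rotation in degrees between the in-plane projections of the
    local y-axis and the global reference axis.

    Unsigned result lies in [0, 180]; the signed variant takes its sign
    from ``(proj_global x proj_local) . normal`` (right-handed about the
    endplate axis).
    """
    normal = frame.z_axis if plane_normal is None else np.asarray(plane_normal, float)
    normal = _unit(normal, "plane normal", tol)
    pg = _project(np.asarray(global_y, float), normal)
    pl = _project(np.asarray(frame.y_axis, float), normal)
    if np.linalg.norm(pg) <= tol or np.linalg.norm(pl) <= tol:
        raise DegenerateGeometryError("projection onto the transverse plane vanishes")
    cross = np.cross(pg, pl)
    ang = np.degrees(np.arctan2(np.linalg.norm(cross), pg @ pl))
    if signed:
        ang *= np.sign(cross @ normal) if cross @ normal != 0 else 1.0
    return float(ang)


@dataclass
class MeasurementRecord:
    """Full audit trail of one vertebra measurement."""

    angle_deg: float
    signed_angle_deg: float
    endplate_centers: EndplateCenters
    pedicle_centers: PedicleCenters
    plane: Plane
    frame: LocalFrame
    n_endplate_points: int
    n_pedicle_points: int
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "angle_deg": self.angle_deg,
            "signed_angle_deg": self.signed_angle_deg,
            "endplate_upper": list(map(float, self.endplate_centers.upper)),
            "endplate_lower": list(map(float, self.endplate_centers.lower)),
            "pedicle_left": list(map(float, self.pedicle_centers.left)),
            "pedicle_right": list(map(float, self.pedicle_centers.right)),
            "plane_point": list(map(float, self.plane.point)),
            "plane_normal": list(map(float, self.plane.normal)),
            "frame_x": list(map(float, self.frame.x_axis)),
            "frame_y": list(map(float, self.frame.y_axis)),
            "frame_z": list(map(float, self.frame.z_axis)),
            "n_endplate_points": self.n_endplate_points,
            "n_pedicle_points": self.n_pedicle_points,
            **self.details,
        }


def _structure_points(cloud: PointCloud, labels_or_model, what: str) -> PointCloud:
    if hasattr(labels_or_model, "predict"):
        labels = labels_or_model.predict(cloud)
    else:
        labels = np.asarray(labels_or_model)
        if labels.shape[0] != len(cloud):
            raise ValueError(f"{what} labels length mismatch")
    pts = cloud.points[labels == 1]
    if pts.shape[0] < 2:
        raise DegenerateGeometryError(f"{what} prediction selected fewer than 2 points")
    return PointCloud(pts, name=cloud.name)


def measure_vertebra(
    cloud: PointCloud,
    endplate: "np.ndarray | object",
    pedicle: "np.ndarray | object",
    global_y: np.ndarray = GLOBAL_Y,
    seed: int = 0,
) -> MeasurementRecord:
    """End-to-end measurement of one vertebral cloud.

    ``endplate`` and ``pedicle`` are either per-point 0/1 label vectors or
    trained segmentation models (anything with ``predict(cloud)``).
    """
    ep_pts = _structure_points(cloud, endplate, "endplate")
    pd_pts = _structure_points(cloud, pedicle, "pedicle")
    _, _, ep = split_endplates(ep_pts, seed=seed)
    pc = pedicle_centers(pd_pts, seed=seed)
    tol = _tolerance(cloud.points)
    plane = transverse_plane(ep, tol=tol)
    frame = local_frame(ep, pc, tol=tol)
    ang = rotation_angle(frame, global_y=global_y, plane_normal=plane.normal, tol=tol)
    sang = rotation_angle(frame, global_y=global_y, plane_normal=plane.normal, signed=True, tol=tol)
    return MeasurementRecord(
        angle_deg=ang,
        signed_angle_deg=sang,
        endplate_centers=ep,
        pedicle_centers=pc,
        plane=plane,
        frame=frame,
        n_endplate_points=len(ep_pts),
        n_pedicle_points=len(pd_pts),
    )


def center_offset(pred: PedicleCenters, ref: PedicleCenters) -> tuple[float, float]:
    """Euclidean displacement (mm) of predicted vs reference pedicle
    centers, per side."""
    left = float(np.linalg.norm(np.asarray(pred.left, float) - np.asarray(ref.left, float)))
    right = float(np.linalg.norm(np.asarray(pred.right, float) - np.asarray(ref.right, float)))
    return left, right
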