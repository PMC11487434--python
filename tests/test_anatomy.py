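import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vertrot.anatomy import (
    DegenerateGeometryError,
    EndplateCenters,
    LocalFrame,
    PedicleCenters,
    center_offset,
    local_frame,
    measure_vertebra,
    pedicle_centers,
    rotation_angle,
    split_endplates,
    transverse_plane,
    vertebral_centroid,
)
from vertrot.io import PointCloud
from vertrot.phantom import PhantomConfig, generate_vertebra


def _disk(center, radius, n, rng):
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * np.pi, n)
    return center + np.column_stack([r * np.cos(phi), r * np.sin(phi), np.zeros(n)])


class TestSplitEndplates:
    def test_two_parallel_disks(self, rng):
        pts = np.vstack(
            [_disk(np.array([0.0, 0, 10]), 5, 300, rng), _disk(np.array([0.0, 0, -10]), 5, 300, rng)]
        )
        upper, lower, ep = split_endplates(PointCloud(pts), seed=0)
        np.testing.assert_allclose(ep.upper, [0, 0, 10], atol=0.5)
        np.testing.assert_allclose(ep.lower, [0, 0, -10], atol=0.5)
        assert ep.upper[2] == pytest.approx(10.0, abs=0.1)
        assert ep.lower[2] == pytest.approx(-10.0, abs=0.1)
        assert len(upper) == len(lower) == 300

    def test_two_points(self):
        _, _, ep = split_endplates(PointCloud([[0, 0, 1], [0, 0, -1]]), seed=0)
        np.testing.assert_allclose(ep.upper, [0, 0, 1])
        np.testing.assert_allclose(ep.lower, [0, 0, -1])

    def test_same_seed_same_partition(self, rng):
        pts = rng.normal(size=(50, 3))
        pts[:25, 2] += 10.0
        u1, l1, _ = split_endplates(PointCloud(pts), seed=4)
        u2, l2, _ = split_endplates(PointCloud(pts), seed=4)
        np.testing.assert_array_equal(u1.points, u2.points)
        np.testing.assert_array_equal(l1.points, l2.points)

    def test_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            split_endplates(PointCloud([[0, 0, 0]]))


class TestPedicleCenters:
    def test_two_blobs(self, rng):
        left = np.array([-15.0, -20.0, 0.0]) + rng.normal(scale=1.0, size=(50, 3))
        right = np.array([15.0, -20.0, 0.0]) + rng.normal(scale=1.0, size=(50, 3))
        pc = pedicle_centers(PointCloud(np.vstack([left, right])), seed=0)
        np.testing.assert_allclose(pc.left, left.mean(axis=0), atol=0.5)
        np.testing.assert_allclose(pc.right, right.mean(axis=0), atol=0.5)
        assert pc.left[0] < pc.right[0]

    def test_two_points(self):
        pc = pedicle_centers(PointCloud([[1.0, 0, 0], [-1.0, 0, 0]]), seed=0)
        np.testing.assert_allclose(pc.left, [-1, 0, 0])
        np.testing.assert_allclose(pc.right, [1, 0, 0])

    def test_kmeans_objective_matches_exhaustive_best(self, rng):
        pts = rng.normal(size=(8, 3)) * 3.0

        def inertia(mask):
            cost = 0.0
            for side in (pts[mask], pts[~mask]):
                cost += ((side - side.mean(axis=0)) ** 2).sum()
            return cost

        best = min(
            inertia(np.array(m, dtype=bool))
            for m in itertools.product([0, 1], repeat=8)
            if 0 < sum(m) < 8
        )
        pc = pedicle_centers(PointCloud(pts), seed=0)
        got = 0.0
        for p in pts:
            got += min(
                np.sum((p - pc.left) ** 2), np.sum((p - pc.right) ** 2)
            )
        assert got == pytest.approx(best, rel=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            pedicle_centers(PointCloud(np.zeros((10, 3))))


class TestFrameConstruction:
    def test_centroid_examples(self):
        np.testing.assert_allclose(
            vertebral_centroid(EndplateCenters([0, 0, 1], [0, 0, -1])), [0, 0, 0]
        )
        np.testing.assert_allclose(
            vertebral_centroid(EndplateCenters([2, 4, 6], [0, 0, 0])), [1, 2, 3]
        )
        a = vertebral_centroid(EndplateCenters([2, 4, 6], [0, 0, 0]))
        b = vertebral_centroid(EndplateCenters([0, 0, 0], [2, 4, 6]))
        np.testing.assert_allclose(a, b)

    def test_transverse_plane(self):
        plane = transverse_plane(EndplateCenters([0, 0, 5], [0, 0, -5]))
        np.testing.assert_allclose(plane.normal, [0, 0, 1])
        np.testing.assert_allclose(plane.point, [0, 0, 0])
        tilted = transverse_plane(EndplateCenters([1, 1, 1], [0, 0, 0]))
        np.testing.assert_allclose(tilted.normal, np.ones(3) / np.sqrt(3))
        # scale invariance of the normal
        scaled = transverse_plane(EndplateCenters([10, 10, 10], [0, 0, 0]))
        np.testing.assert_allclose(scaled.normal, tilted.normal)

    def test_identity_configuration(self):
        ep = EndplateCenters([0, 0, 14], [0, 0, -14])
        pc = PedicleCenters([-15, -20, 0], [15, -20, 0])
        frame = local_frame(ep, pc)
        np.testing.assert_allclose(frame.origin, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(frame.x_axis, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(frame.y_axis, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(frame.z_axis, [0, 0, 1], atol=1e-12)

    def test_rotation_equivariance_of_axes(self):
        rot = Rotation.from_euler("xyz", [20, 0, 0], degrees=True).as_matrix()
        ep = EndplateCenters([0, 0, 14], [0, 0, -14])
        pc = PedicleCenters([-15, -20, 0], [15, -20, 0])
        base = local_frame(ep, pc)
        ep_r = EndplateCenters(rot @ np.array([0.0, 0, 14]), rot @ np.array([0.0, 0, -14]))
        pc_r = PedicleCenters(rot @ np.array([-15.0, -20, 0]), rot @ np.array([15.0, -20, 0]))
        moved = local_frame(ep_r, pc_r)
        for axis in ("x_axis", "y_axis", "z_axis"):
            np.testing.assert_allclose(
                getattr(moved, axis), rot @ getattr(base, axis), atol=1e-12
            )
            assert np.linalg.norm(getattr(moved, axis)) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_parallel_axes(self):
        ep = EndplateCenters([0, 0, 1], [0, 0, -1])
        pc = PedicleCenters([0, 0, -3], [0, 0, -5])  # midpoint below centroid on z
        with pytest.raises(DegenerateGeometryError):
            local_frame(ep, pc)


def _rotated_frame(theta_deg: float) -> LocalFrame:
    rot = Rotation.from_euler("z", theta_deg, degrees=True).as_matrix()
    return LocalFrame(
        origin=np.zeros(3),
        x_axis=rot @ np.array([1.0, 0, 0]),
        y_axis=rot @ np.array([0.0, 1, 0]),
        z_axis=np.array([0.0, 0, 1]),
    )


class TestRotationAngle:
    def test_aligned_is_zero(self):
        assert rotation_angle(_rotated_frame(0.0)) == pytest.approx(0.0, abs=1e-9)

    def test_seven_degrees_exact(self):
        assert rotation_angle(_rotated_frame(7.0)) == pytest.approx(7.0, abs=1e-6)

    def test_signed_variant(self):
        assert rotation_angle(_rotated_frame(-7.0)) == pytest.approx(7.0, abs=1e-6)
        assert rotation_angle(_rotated_frame(-7.0), signed=True) == pytest.approx(
            -7.0, abs=1e-6
        )
        assert rotation_angle(_rotated_frame(7.0), signed=True) == pytest.approx(
            7.0, abs=1e-6
        )

    def test_degenerate_projection(self):
        frame = LocalFrame(
            origin=np.zeros(3),
            x_axis=np.array([1.0, 0, 0]),
            y_axis=np.array([0.0, 0, 1]),  # parallel to the normal
            z_axis=np.array([0.0, 0, 1]),
        )
        with pytest.raises(DegenerateGeometryError):
            rotation_angle(frame)


class TestMeasureVertebra:
    def test_phantom_12_degrees(self, phantom_12deg):
        ep, pd, truth = phantom_12deg
        rec = measure_vertebra(ep.cloud, ep.labels, pd.labels, seed=0)
        assert rec.angle_deg == pytest.approx(12.0, abs=1e-6)
        assert rec.angle_deg == pytest.approx(truth.theta_true, abs=1e-6)

    def test_translation_and_scale_invariance(self, phantom_12deg):
        ep, pd, _ = phantom_12deg
        base = measure_vertebra(ep.cloud, ep.labels, pd.labels, seed=0).angle_deg
        shifted = PointCloud(ep.cloud.points + np.array([100.0, -50.0, 30.0]))
        assert measure_vertebra(shifted, ep.labels, pd.labels, seed=0).angle_deg == pytest.approx(
            base, abs=1e-9
        )
        scaled = PointCloud(ep.cloud.points * 3.7)
        assert measure_vertebra(scaled, ep.labels, pd.labels, seed=0).angle_deg == pytest.approx(
            base, abs=1e-9
        )

    def test_axial_rotation_equivariance(self, phantom_12deg):
        ep, pd, _ = phantom_12deg
        base = measure_vertebra(ep.cloud, ep.labels, pd.labels, seed=0).signed_angle_deg
        alpha = 5.0
        rot = Rotation.from_euler("z", alpha, degrees=True).as_matrix()
        moved = PointCloud(ep.cloud.points @ rot.T)
        got = measure_vertebra(moved, ep.labels, pd.labels, seed=0).signed_angle_deg
        assert got == pytest.approx(base + alpha, abs=1e-6)

    def test_swapped_endplate_halves_leave_unsigned_angle(self, phantom_12deg):
        # flipping the cloud upside down flips z but not the unsigned angle
        ep, pd, _ = phantom_12deg
        base = measure_vertebra(ep.cloud, ep.labels, pd.labels, seed=0).angle_deg
        flipped = ep.cloud.points.copy()
        flipped[:, 2] *= -1.0
        got = measure_vertebra(PointCloud(flipped), ep.labels, pd.labels, seed=0).angle_deg
        assert got == pytest.approx(base, abs=1e-6)

    def test_empty_structure_rejected(self, phantom_12deg):
        ep, pd, _ = phantom_12deg
        with pytest.raises(DegenerateGeometryError, match="endplate"):
            measure_vertebra(ep.cloud, np.zeros(len(ep), dtype=int), pd.labels)


class TestCenterOffset:
    def test_examples(self, rng):
        a = PedicleCenters([0, 0, 0], [1, 1, 1])
        assert center_offset(a, a) == (0.0, 0.0)
        b = PedicleCenters([3, 4, 0], [1, 1, 1])
        assert center_offset(b, a) == (pytest.approx(5.0), 0.0)
        for _ in range(10):
            l1, r1, l2, r2 = rng.normal(size=(4, 3))
            got = center_offset(PedicleCenters(l1, r1), PedicleCenters(l2, r2))
            assert got[0] == pytest.approx(np.linalg.norm(l1 - l2))
            assert got[1] == pytest.approx(np.linalg.norm(r1 - r2))


def test_noiseless_recovery_small_batch():
    rng = np.random.default_rng(21)
    for _ in range(10):
        theta = rng.uniform(0, 25)
        ep, pd, truth = generate_vertebra(
            PhantomConfig(theta_deg=theta, seed=int(rng.integers(0, 2**31)))
        )
        rec = measure_vertebra(ep.cloud, ep.labels, pd.labels, seed=0)
        assert rec.angle_deg == pytest.approx(theta, abs=1e-6)
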