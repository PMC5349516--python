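"""Local frames and orthogonal resampling: orthonormality, round trips,
and recovery of circular cross-sections from tilted tubes."""

import numpy as np
import pytest

from osteotrace.bone_tracker import SeedAnnotation, track_bone
from osteotrace.cortical_metrics import outer_radii
from osteotrace.orthogonal_resampler import (
    arc_length_positions,
    build_frame,
    local_tangent,
    orthogonal_stack,
    resample_orthogonal,
    smooth_centerline,
)
from osteotrace.phantom import PhantomSpec, generate_phantom


class TestLocalTangent:
    def test_straight_vertical(self):
        pts = np.column_stack([np.full(20, 5.0), np.full(20, 7.0), np.arange(20)])
        assert np.allclose(local_tangent(pts, 10), [0, 0, 1])

    def test_diagonal_45deg(self):
        i = np.arange(30, dtype=float)
        pts = np.column_stack([i, i, i])
        t = local_tangent(pts, 15, window=5)
        assert np.abs(t - 1 / np.sqrt(3)).max() < 1e-12

    def test_unit_norm_and_end_clamping(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.normal(0, 2, 40), rng.normal(0, 2, 40), np.arange(40)])
        for i in [0, 1, 20, 38, 39]:
            assert abs(np.linalg.norm(local_tangent(pts, i)) - 1) < 1e-12

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            local_tangent(np.array([[0.0, 0.0, 0.0]]), 0)


class TestBuildFrame:
    def test_parallel_tangent_gives_identity(self):
        f = build_frame(np.array([0.0, 0.0, 1.0]))
        assert np.array_equal(f.forward, np.eye(3))

    def test_tilted_15deg_hand_computed(self):
        s, c = np.sin(np.deg2rad(15)), np.cos(np.deg2rad(15))
        f = build_frame(np.array([s, 0.0, c]))
        # rotation axis e_z x e_z' = (0, s, 0) -> e_y' = (0, 1, 0)
        assert np.allclose(f.e_y, [0, 1, 0], atol=1e-12)
        # e_x' = e_y' x e_z' = (c, 0, -s)
        assert np.allclose(f.e_x, [c, 0, -s], atol=1e-12)

    def test_random_tangents_orthonormal_proper(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            v = rng.normal(size=3)
            f = build_frame(v / np.linalg.norm(v))
            basis = f.forward
            assert np.abs(basis @ basis.T - np.eye(3)).max() < 1e-10
            assert abs(np.linalg.det(basis) - 1) < 1e-10
            assert np.abs(f.forward @ f.inverse - np.eye(3)).max() < 1e-10

    def test_roundtrip_scanner_bone_scanner(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=3)
        f = build_frame(v / np.linalg.norm(v), origin=np.array([10.0, 20.0, 30.0]))
        pts = rng.uniform(-50, 50, size=(100, 3))
        back = f.to_scanner(f.to_bone(pts))
        assert np.abs(back - pts).max() < 1e-10


class TestResample:
    def test_identity_frame_reproduces_slice_window(self):
        rng = np.random.default_rng(5)
        vol = rng.normal(size=(9, 41, 41))
        f = build_frame(np.array([0.0, 0.0, 1.0]), origin=np.array([20.0, 20.0, 4.0]))
        out = resample_orthogonal(vol, f, half_extent=10)
        assert np.abs(out - vol[4, 10:31, 10:31]).max() < 1e-12

    def test_constant_volume_constant_output(self):
        vol = np.full((9, 31, 31), 3.7)
        f = build_frame(np.array([0.3, 0.2, 0.93]), origin=np.array([15.0, 15.0, 4.0]))
        out = resample_orthogonal(vol, f, half_extent=4)
        assert np.allclose(out, 3.7)

    def test_origin_outside_volume_rejected(self):
        f = build_frame(np.array([0.0, 0.0, 1.0]), origin=np.array([50.0, 5.0, 5.0]))
        with pytest.raises(ValueError, match="outside"):
            resample_orthogonal(np.zeros((10, 10, 10)), f, half_extent=2)


@pytest.fixture(scope="module")
def tilted20_cylinder():
    """Solid cylinder of radius 12 px tilted 20 deg, clean partial-volume edges."""
    spec = PhantomSpec(
        n_slices=80,
        slice_shape=(48, 96),
        joint_z=4,
        center_xy=(20.0, 24.0),
        centerline_kind="tilted",
        tilt_deg=20.0,
        r_out_joint_mm=12 * 0.014599,
        r_in_joint_mm=0.0,
        noise_sigma=0.0,
        blur_sigma=0.0,
    )
    return spec, generate_phantom(spec)


class TestOrthogonality:
    def test_tilted_cylinder_circular_after_resampling(self, tilted20_cylinder):
        """In-plane sections are ellipses; orthogonal sections are circles."""
        spec, (stack, truth) = tilted20_cylinder
        occupancy = (stack.voxels - 20.0) / 180.0
        r_inplane, found, _ = outer_radii(occupancy[40])
        ratio_inplane = r_inplane[found].max() / r_inplane[found].min()
        assert ratio_inplane >= 1.06  # analytic 1/cos20 ~ 1.064

        seed = SeedAnnotation(
            seed_slice=40, seed_point=tuple(truth.centerline[40][:2]), joint_z=4
        )
        cl = track_bone(truth.mask, seed, range_mm=(0.15, 1.05), voxel_size_um=spec.voxel_size_um)
        ortho = orthogonal_stack(occupancy, cl, joint_z=4, half_extent=20.0)
        mid = ortho[len(ortho) // 2].pixels
        r_ortho, found_o, _ = outer_radii(mid)
        assert (r_ortho[found_o].max() / r_ortho[found_o].min()) < 1.05

    def test_cross_section_area_recovered(self, tilted20_cylinder):
        """Orthogonal area ~ pi r^2; in-plane area carries the 1/cos factor."""
        spec, (stack, truth) = tilted20_cylinder
        occupancy = (stack.voxels - 20.0) / 180.0
        true_area = np.pi * 12**2
        inplane_area = occupancy[40].sum()
        assert inplane_area / true_area == pytest.approx(1 / np.cos(np.deg2rad(20)), rel=0.03)
        seed = SeedAnnotation(
            seed_slice=40, seed_point=tuple(truth.centerline[40][:2]), joint_z=4
        )
        cl = track_bone(truth.mask, seed, range_mm=(0.15, 1.05), voxel_size_um=spec.voxel_size_um)
        ortho = orthogonal_stack(occupancy, cl, joint_z=4, half_extent=20.0)
        ortho_area = ortho[len(ortho) // 2].pixels.sum()
        assert ortho_area == pytest.approx(true_area, rel=0.03)


class TestAlongBone:
    def test_frames_vary_smoothly_on_curved_centerline(self):
        z = np.arange(200, dtype=float)
        pts = np.column_stack([40 + 8 * np.sin(2 * np.pi * z / 500), np.full(200, 40.0), z])
        sm = smooth_centerline(pts)
        tangents = [local_tangent(sm, i) for i in range(200)]
        angles = [
            np.degrees(np.arccos(np.clip(np.dot(a, b), -1, 1)))
            for a, b in zip(tangents[:-1], tangents[1:])
        ]
        assert max(angles) < 1.0

    def test_arc_length_monotone_and_anchored(self):
        pts = np.column_stack([np.full(50, 10.0), np.full(50, 10.0), np.arange(50, 100)])
        xi = arc_length_positions(pts, joint_z=40, voxel_size_um=1000.0)
        assert np.all(np.diff(xi) > 0)
        # straight vertical line, 1 mm voxels: xi = (z - joint) mm exactly
        assert np.abs(xi - (np.arange(50, 100) - 40)).max() < 1e-12
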