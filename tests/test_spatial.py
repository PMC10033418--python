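"""Point-to-ellipse quartic solver and 3D nucleus distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitomap.grids import VolumeGrid
from mitomap.spatial import (Ellipse, fit_nucleus_ellipse, mito_nucleus_distances_3d,
                             point_to_ellipse_distance)
from mitomap.synthetic import (MitoShapeParams, NucleusSpec, SceneSpec,
                               generate_cell_volume)

from conftest import dense_ellipse_oracle


def _raster_ellipse(a, b, theta=0.0, size=141):
    c = (size - 1) / 2
    yy, xx = np.mgrid[:size, :size]
    x, y = xx - c, yy - c
    ct, stn = np.cos(theta), np.sin(theta)
    u = ct * x + stn * y
    v = -stn * x + ct * y
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


class TestEllipseFit:
    def test_axis_aligned_ellipse_recovered_within_2pct(self):
        mask = _raster_ellipse(50, 30)
        e = fit_nucleus_ellipse(mask)
        assert e.a == pytest.approx(50, rel=0.02)
        assert e.b == pytest.approx(30, rel=0.02)
        assert min(e.theta, np.pi - e.theta) < 0.02

    def test_disk_gives_equal_axes(self):
        e = fit_nucleus_ellipse(_raster_ellipse(40, 40))
        assert e.a == pytest.approx(e.b, rel=0.01)
        assert 0.0 <= e.theta < np.pi

    def test_rotation_angle_recovered_within_1deg(self):
        theta = np.deg2rad(30)
        e = fit_nucleus_ellipse(_raster_ellipse(50, 30, theta))
        assert abs(e.theta - theta) < np.deg2rad(1.0)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            fit_nucleus_ellipse(np.zeros((10, 10), bool))


class TestPointToEllipse:
    def test_boundary_point_has_zero_distance(self):
        e = Ellipse((2.0, 3.0), 2.0, 1.0, 0.3)
        p = e.from_standard(np.array([[2 * np.cos(0.8), np.sin(0.8)]]))[0]
        res = point_to_ellipse_distance(p, e)
        assert res.distance < 1e-9
        assert np.allclose(res.closest_point, p, atol=1e-8)

    def test_circle_reduces_to_radial_distance(self, rng):
        e = Ellipse((1.0, -2.0), 3.0, 3.0)
        for _ in range(50):
            p = rng.uniform(-8, 8, 2)
            if np.allclose(p, e.center):
                continue
            expected = abs(np.hypot(p[0] - 1.0, p[1] + 2.0) - 3.0)
            assert point_to_ellipse_distance(p, e).distance == pytest.approx(
                expected, abs=1e-9)

    def test_reference_point_matches_dense_oracle(self):
        e = Ellipse((0.0, 0.0), 2.0, 1.0, 0.0)
        res = point_to_ellipse_distance((2.0, 1.0), e)
        oracle = dense_ellipse_oracle((2.0, 1.0), e)
        assert res.distance == pytest.approx(oracle, rel=1e-6)

    def test_center_returns_minor_axis_distance(self):
        e = Ellipse((5.0, 5.0), 4.0, 2.0, 0.0)
        res = point_to_ellipse_distance((5.0, 5.0), e)
        assert res.distance == pytest.approx(2.0, abs=1e-12)

    def test_candidate_count_bounded_by_four(self, rng):
        for _ in range(200):
            a = rng.uniform(0.5, 5.0)
            e = Ellipse((rng.uniform(-5, 5), rng.uniform(-5, 5)), a,
                        rng.uniform(0.1, a), rng.uniform(0, np.pi))
            res = point_to_ellipse_distance(rng.uniform(-8, 8, 2), e)
            assert res.n_candidates <= 4
            assert np.abs(e.implicit(np.array([res.closest_point]))[0]) < 1e-9

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(-6, 6), st.floats(-6, 6), st.floats(0.5, 4), st.floats(0.1, 0.5),
           st.floats(0, 3), st.floats(-4, 4), st.floats(-4, 4))
    def test_rigid_invariance(self, cx, cy, a, b_frac, theta, px, py):
        """Translating and rotating point and ellipse together preserves distance."""
        b = a * max(b_frac, 0.05)
        e = Ellipse((cx, cy), a, b, theta % np.pi)
        d0 = point_to_ellipse_distance((px, py), e).distance
        dx, dy, phi = 1.7, -0.9, 0.6
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        c2 = rot @ np.array([cx, cy]) + (dx, dy)
        p2 = rot @ np.array([px, py]) + (dx, dy)
        e2 = Ellipse(tuple(c2), a, b, (theta + phi) % np.pi)
        d1 = point_to_ellipse_distance(tuple(p2), e2).distance
        assert d1 == pytest.approx(d0, abs=1e-9, rel=1e-9)


class TestNucleusDistances3D:
    def test_face_adjacent_voxel_is_one_step_away(self):
        nuc = np.zeros((3, 3, 5), bool)
        nuc[:, :, :2] = True
        inst = np.zeros((3, 3, 5), np.int32)
        inst[1, 1, 2] = 1
        d = mito_nucleus_distances_3d(VolumeGrid(inst, (50, 5, 5)),
                                      VolumeGrid(nuc, (50, 5, 5)))
        assert d[1] == pytest.approx(5.0 / 1000.0)

    def test_spherical_nucleus_matches_analytic_offset(self):
        shape = (40, 40, 40)
        zz, yy, xx = np.ogrid[:40, :40, :40]
        center = 19.5
        r = 10
        nuc = (zz - center) ** 2 + (yy - center) ** 2 + (xx - center) ** 2 <= r**2
        inst = np.zeros(shape, np.int32)
        inst[20, 20, 36] = 1  # about 16.5 voxels from the center
        vs = (10.0, 10.0, 10.0)
        d = mito_nucleus_distances_3d(VolumeGrid(inst, vs), VolumeGrid(nuc, vs))
        dist_vox = np.sqrt(0.25 + 0.25 + 16.5**2)
        expected = (dist_vox - r) * 10.0 / 1000.0
        assert d[1] == pytest.approx(expected, abs=np.sqrt(3) * 10.0 / 1000.0)

    def test_small_grid_transform_equals_brute_force(self, rng):
        nuc = rng.random((12, 12, 12)) < 0.05
        nuc[6, 6, 6] = True
        inst = np.zeros((12, 12, 12), np.int32)
        ids = 0
        for _ in range(5):
            k, j, i = rng.integers(0, 12, 3)
            if not nuc[k, j, i] and inst[k, j, i] == 0:
                ids += 1
                inst[k, j, i] = ids
        vs = (50.0, 5.0, 5.0)
        d = mito_nucleus_distances_3d(VolumeGrid(inst, vs), VolumeGrid(nuc, vs))
        nuc_idx = np.argwhere(nuc) * np.asarray(vs)
        for inst_id, got in d.items():
            p = np.argwhere(inst == inst_id)[0] * np.asarray(vs)
            brute = np.sqrt(((nuc_idx - p) ** 2).sum(axis=1)).min() / 1000.0
            assert got == pytest.approx(brute, abs=1e-9)

    def test_perinuclear_scenes_sit_closer_than_dispersed(self):
        kw = dict(grid_shape=(32, 280, 280), voxel_size=(50, 10, 10),
                  nucleus=NucleusSpec(semi_axes=(350, 450, 450), center=(800, 1400, 1400)),
                  n_mitochondria=10,
                  mito_shape=MitoShapeParams(radius_nm=70, length_mean_um=0.3,
                                             length_sd_um=0.0),
                  n_lipid_droplets=0, seed=21)
        medians = {}
        for mode in ("perinuclear", "dispersed"):
            _, truth = generate_cell_volume(SceneSpec(placement_mode=mode, **kw))
            nuc = truth.class_volume.like(np.asarray(truth.class_volume.data) == 1)
            d = mito_nucleus_distances_3d(truth.instance_volume, nuc, mode="centroid")
            mito_ids = truth.instance_table.query("class_id == 2").instance_id
            medians[mode] = np.median([d[i] for i in mito_ids])
        assert medians["perinuclear"] < medians["dispersed"]

    def test_empty_nucleus_is_an_error(self):
        inst = VolumeGrid(np.ones((4, 4, 4), np.int32))
        with pytest.raises(ValueError, match="empty"):
            mito_nucleus_distances_3d(inst, VolumeGrid(np.zeros((4, 4, 4))))
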