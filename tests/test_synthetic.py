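"""Synthetic scene and motility-series generators: oracles and invariants."""

import numpy as np
import pytest

from mitomap.grids import voxel_volume_um3
from mitomap.spatial import Ellipse, sample_ellipse_boundary
from mitomap.synthetic import (MitoShapeParams, NucleusSpec, PlacementError, SceneSpec,
                               generate_cell_volume, generate_motility_series)


def _capsule_spec(seed, n=10):
    return SceneSpec(
        grid_shape=(40, 320, 320), voxel_size=(50, 5, 5),
        nucleus=NucleusSpec(semi_axes=(300, 300, 300), center=(1000, 450, 450)),
        n_mitochondria=n,
        mito_shape=MitoShapeParams(radius_nm=100, length_mean_um=1.0, length_sd_um=0.0),
        n_lipid_droplets=0, seed=seed)


class TestCellVolume:
    def test_empty_scene_contains_only_the_nucleus(self):
        spec = SceneSpec(grid_shape=(16, 64, 64), voxel_size=(50, 20, 20),
                         nucleus=NucleusSpec(semi_axes=(250, 400, 400),
                                             center=(400, 640, 640)),
                         n_mitochondria=0, n_lipid_droplets=0, seed=0)
        _, truth = generate_cell_volume(spec)
        assert len(truth.instance_table) == 1
        assert truth.instance_table.class_id.tolist() == [1]
        assert set(np.unique(truth.instance_volume.data)) == {0, 1}

    def test_same_seed_is_bit_identical(self):
        g1, t1 = generate_cell_volume(_capsule_spec(11, n=3))
        g2, t2 = generate_cell_volume(_capsule_spec(11, n=3))
        assert np.array_equal(g1.data, g2.data)
        assert np.array_equal(t1.instance_volume.data, t2.instance_volume.data)
        assert t1.instance_table.equals(t2.instance_table)

    def test_capsule_volumes_match_analytic_form(self):
        """Rasterized capsule volume vs pi r^2 L + 4/3 pi r^3, within 10%."""
        _, truth = generate_cell_volume(_capsule_spec(42))
        mito = truth.instance_table.query("class_id == 2")
        assert len(mito) == 10
        r, length = 100.0, 1000.0
        analytic = (np.pi * r**2 * length + 4.0 / 3.0 * np.pi * r**3) / 1e9
        rel = np.abs(mito.true_volume_um3 - analytic) / analytic
        assert rel.max() < 0.10

    def test_instance_table_volume_is_exact_voxel_count(self, small_scene):
        spec, _, truth = small_scene
        vox = voxel_volume_um3(spec.voxel_size)
        t = truth.instance_table
        assert np.allclose(t.true_volume_um3, t.voxel_count * vox, rtol=0, atol=0)

    def test_class_and_instance_volumes_are_consistent(self, small_scene):
        _, _, truth = small_scene
        inst = np.asarray(truth.instance_volume.data)
        cls = np.asarray(truth.class_volume.data)
        assert np.count_nonzero(inst) == np.count_nonzero(cls)
        for _, row in truth.instance_table.iterrows():
            sel = inst == row.instance_id
            assert int(row.voxel_count) == int(sel.sum())
            assert (cls[sel] == row.class_id).all()

    def test_crowded_scene_fails_naming_the_class(self):
        spec = SceneSpec(grid_shape=(12, 80, 80), voxel_size=(50, 10, 10),
                         nucleus=NucleusSpec(semi_axes=(250, 350, 350),
                                             center=(300, 400, 400)),
                         n_mitochondria=200,
                         mito_shape=MitoShapeParams(radius_nm=80, length_mean_um=0.3,
                                                    length_sd_um=0.0),
                         n_lipid_droplets=0, seed=0)
        with pytest.raises(PlacementError, match="mitochondrion"):
            generate_cell_volume(spec)

    def test_invalid_specs_are_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            SceneSpec(n_mitochondria=-1)
        with pytest.raises(ValueError, match="fit"):
            SceneSpec(grid_shape=(4, 50, 50), voxel_size=(50, 5, 5))


class TestMotilitySeries:
    def test_zero_velocity_keeps_all_frames_identical(self):
        ref = np.zeros((20, 20), bool)
        ref[5:15, 5:15] = True
        series, v = generate_motility_series(ref, 0.0, n_frames=10)
        assert v == 0.0
        for f in series.frames:
            assert np.array_equal(f, series.frames[0])

    def test_translation_bookkeeping(self):
        """10x10 square at 2 px/frame: frame 3 is offset by 4 px from frame 1."""
        ref = np.zeros((30, 30), bool)
        ref[10:20, 2:12] = True
        series, _ = generate_motility_series(ref, 2.0, n_frames=3)
        expected = np.zeros((30, 30), bool)
        expected[10:20, 6:16] = True
        assert np.array_equal(series.frames[2], expected)

    def test_time_stamps_cover_180_seconds(self):
        """10 frames at 20 s: stamps 0, 20, ..., 180 s."""
        ref = np.ones((8, 8), bool)
        series, _ = generate_motility_series(ref, 0.0, n_frames=10, dt_s=20.0)
        assert np.array_equal(series.times, np.arange(10) * 20.0)
        assert series.times[-1] == 180.0

    def test_object_leaving_the_frame_is_an_error(self):
        ref = np.zeros((10, 10), bool)
        ref[4:6, 0:2] = True
        with pytest.raises(ValueError, match="out of frame"):
            generate_motility_series(ref, 5.0, n_frames=5)

    def test_blob_spec_is_seed_deterministic(self):
        spec = {"shape": (64, 64), "n_blobs": 4, "blob_radius": 5}
        s1, _ = generate_motility_series(spec, 1.0, n_frames=4, seed=9)
        s2, _ = generate_motility_series(spec, 1.0, n_frames=4, seed=9)
        assert np.array_equal(s1.frames, s2.frames)


class TestEllipseBoundarySampling:
    def test_circle_points_have_unit_norm(self):
        e = Ellipse((0.0, 0.0), 1.0, 1.0)
        pts = sample_ellipse_boundary(e, 100, seed=1)
        assert np.allclose(np.hypot(pts[:, 0], pts[:, 1]), 1.0, atol=1e-12)

    def test_cardinal_angles_hit_the_axis_endpoints(self):
        e = Ellipse((0.0, 0.0), 3.0, 2.0)
        pts = sample_ellipse_boundary(e, 4, angles=[0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert np.allclose(pts, [(3, 0), (0, 2), (-3, 0), (0, -2)], atol=1e-12)

    def test_tilted_ellipse_satisfies_the_implicit_equation(self):
        e = Ellipse((2.0, -1.0), 4.0, 1.5, 0.7)
        pts = sample_ellipse_boundary(e, 500, seed=2)
        assert np.abs(e.implicit(pts)).max() < 1e-10
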