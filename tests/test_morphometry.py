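"""3D morphometry: labeling semantics, shape measures, distributions."""

import numpy as np
import pytest

from mitomap.grids import VolumeGrid
from mitomap.morphometry import (MitoRecord, label_components, measure_components,
                                 summarize_distributions)


def _ball(radius, spacing=10.0):
    n = 2 * radius + 9
    c = (n - 1) / 2
    zz, yy, xx = np.ogrid[:n, :n, :n]
    m = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    return VolumeGrid(m.astype(np.uint8), (spacing,) * 3)


def _capsule(axis_len_vox, radius_vox, spacing=10.0):
    shape = (2 * radius_vox + 9, 2 * radius_vox + 9, axis_len_vox + 2 * radius_vox + 9)
    cz, cy = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    x0 = (shape[2] - 1) / 2 - axis_len_vox / 2
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    t = np.clip((xx - x0) / max(axis_len_vox, 1e-9), 0, 1)
    px = x0 + t * axis_len_vox
    m = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - px) ** 2 <= radius_vox**2
    return VolumeGrid(m.astype(np.uint8), (spacing,) * 3)


class TestLabeling:
    def test_two_disconnected_cubes(self):
        m = np.zeros((6, 6, 12), np.uint8)
        m[1:4, 1:4, 1:4] = 1
        m[1:4, 1:4, 7:10] = 1
        labels = label_components(VolumeGrid(m), connectivity=6)
        assert labels.data.max() == 2

    def test_corner_touching_cubes_depend_on_connectivity(self):
        m = np.zeros((6, 6, 6), np.uint8)
        m[0:3, 0:3, 0:3] = 1
        m[3:6, 3:6, 3:6] = 1
        assert label_components(VolumeGrid(m), connectivity=6).data.max() == 2
        assert label_components(VolumeGrid(m), connectivity=26).data.max() == 1

    def test_generator_scene_count_recovered(self, small_scene):
        _, _, truth = small_scene
        mito_mask = truth.class_volume.like(
            (np.asarray(truth.class_volume.data) == 2).astype(np.uint8))
        labels = label_components(mito_mask, connectivity=26)
        n_true = (truth.instance_table.class_id == 2).sum()
        assert labels.data.max() == n_true

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            label_components(VolumeGrid(np.full((3, 3, 3), 2)))

    def test_union_of_instances_is_the_foreground(self, small_scene):
        _, _, truth = small_scene
        fg = np.asarray(truth.class_volume.data) == 2
        labels = label_components(truth.class_volume.like(fg.astype(np.uint8)))
        assert np.array_equal(labels.data > 0, fg)


class TestShapeMeasures:
    def test_ball_volume_and_sphericity(self):
        rec = measure_components(label_components(_ball(20)))[0]
        r_um = 20 * 10.0 / 1000.0
        assert rec.volume == pytest.approx(4 / 3 * np.pi * r_um**3, rel=0.02)
        assert rec.sphericity >= 0.97
        assert rec.sphericity <= 1.05

    def test_capsule_length_matches_axis_plus_caps(self):
        """Straight capsule, axis 2 um, radius 0.15 um: length ~ L + 2r."""
        grid = _capsule(200, 15, spacing=10.0)
        rec = measure_components(label_components(grid))[0]
        expected = 2.0 + 2 * 0.15
        assert rec.length == pytest.approx(expected, rel=0.10)

    def test_sphericity_decreases_with_elongation(self):
        psis = []
        for L in (0, 20, 40, 80):
            rec = measure_components(label_components(_capsule(L, 15)))[0]
            psis.append(rec.sphericity)
        assert all(a > b for a, b in zip(psis, psis[1:]))

    def test_single_voxel_instance_is_total(self):
        m = np.zeros((3, 3, 3), np.uint8)
        m[1, 1, 1] = 1
        rec = measure_components(label_components(VolumeGrid(m, (50, 5, 5))))[0]
        assert rec.volume == pytest.approx(50 * 5 * 5 / 1e9)
        assert rec.length == pytest.approx(0.05)
        assert rec.surface_area > 0
        assert np.isfinite(rec.sphericity)

    def test_voxel_counts_conserve_foreground(self, small_scene):
        _, _, truth = small_scene
        labels = truth.instance_volume
        recs = measure_components(labels)
        assert sum(r.voxel_count for r in recs) == int(np.count_nonzero(labels.data))

    def test_measures_scale_with_voxel_size(self):
        base = _ball(12, spacing=10.0)
        scaled = VolumeGrid(base.data, (20.0, 20.0, 20.0))
        r0 = measure_components(label_components(base))[0]
        r1 = measure_components(label_components(scaled))[0]
        assert r1.volume == pytest.approx(8 * r0.volume, rel=1e-9)
        assert r1.surface_area == pytest.approx(4 * r0.surface_area, rel=1e-6)
        assert r1.length == pytest.approx(2 * r0.length, rel=1e-6)
        assert r1.sphericity == pytest.approx(r0.sphericity, rel=1e-6)


class TestDistributions:
    def _records(self, values):
        return [MitoRecord(i, 1, v, 1.0, v, 0.5, (0, 0, 0)) for i, v in enumerate(values)]

    def test_identical_values_collapse_to_one_bin(self):
        density, edges = summarize_distributions(self._records([2.0] * 5), "volume", 10)
        assert len(density) == 1
        assert density[0] * (edges[1] - edges[0]) == pytest.approx(1.0)

    def test_density_normalizes_to_one(self, rng):
        vals = rng.lognormal(0, 0.5, 200)
        density, edges = summarize_distributions(self._records(vals), "length", 25)
        assert float((density * np.diff(edges)).sum()) == pytest.approx(1.0, abs=1e-9)

    def test_bimodal_mixture_shows_two_modes(self, rng):
        vals = np.concatenate([rng.normal(1.0, 0.05, 300), rng.normal(3.0, 0.05, 300)])
        density, edges = summarize_distributions(self._records(vals), "length",
                                                 np.linspace(0, 4, 41))
        centers = (edges[:-1] + edges[1:]) / 2
        lo = density[(centers > 0.5) & (centers < 1.5)]
        hi = density[(centers > 2.5) & (centers < 3.5)]
        gap = density[(centers > 1.7) & (centers < 2.3)]
        assert lo.max() > 5 * max(gap.max(), 1e-12)
        assert hi.max() > 5 * max(gap.max(), 1e-12)

    def test_empty_and_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            summarize_distributions([], "volume")
        with pytest.raises(ValueError, match="metric"):
            summarize_distributions(self._records([1.0]), "mass")
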