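"""PNM / PDM / CM classification, droplet quantification, phenotyping rules."""

import numpy as np
import pandas as pd
import pytest

from mitomap.compartments import (ContactParams, TracerMeasurement, classify_compartments,
                                  classify_tracer_uptake, detect_contacts, normalize_mrc,
                                  quantify_lipid_droplets)
from mitomap.grids import VolumeGrid


def _planted_scene():
    """Nucleus slab, one droplet, three mitochondria at 20/40/300 nm from it.

    Voxel size (50, 5, 5) nm; gaps of 3, 7 and 59 empty voxels along x give
    nearest-voxel distances of exactly 20, 40 and 300 nm.
    """
    shape = (9, 40, 120)
    vs = (50.0, 5.0, 5.0)
    nuc = np.zeros(shape, bool)
    nuc[:, :, :3] = True
    ld = np.zeros(shape, np.int32)
    ld[4, 18:22, 30:34] = 1
    mito = np.zeros(shape, np.int32)
    gaps = {1: 3, 2: 7, 3: 59}
    for inst, gap in gaps.items():
        x0 = 34 + gap
        mito[4, 18:22, x0:x0 + 4] = inst
    return (VolumeGrid(mito, vs), VolumeGrid(ld, vs), VolumeGrid(nuc, vs))


class TestContacts:
    def test_planted_surface_distances_and_flags(self):
        mito, ld, nuc = _planted_scene()
        flags = detect_contacts(mito, ld, nuc, ContactParams(ld_contact_max=50.0))
        by_id = flags.set_index("instance_id")
        assert by_id.loc[1, "ld_distance_nm"] == pytest.approx(20.0)
        assert by_id.loc[2, "ld_distance_nm"] == pytest.approx(40.0)
        assert by_id.loc[3, "ld_distance_nm"] == pytest.approx(300.0)
        assert by_id.ld_contact.tolist() == [True, True, False]

    def test_no_droplets_means_no_contacts(self):
        mito, ld, nuc = _planted_scene()
        empty = ld.like(np.zeros_like(np.asarray(ld.data)))
        flags = detect_contacts(mito, empty, nuc)
        assert not flags.ld_contact.any()
        labelled, _ = classify_compartments(flags)
        assert (labelled.compartment != "PDM").all()

    def test_voxel_adjacent_droplet_is_contact_at_one_step(self):
        shape = (3, 3, 6)
        vs = (50.0, 5.0, 5.0)
        ld = np.zeros(shape, np.int32)
        ld[1, 1, 2] = 1
        mito = np.zeros(shape, np.int32)
        mito[1, 1, 3] = 1
        nuc = np.zeros(shape, bool)
        nuc[0, 0, 0] = True
        flags = detect_contacts(VolumeGrid(mito, vs), VolumeGrid(ld, vs),
                                VolumeGrid(nuc, vs), ContactParams(ld_contact_max=5.0))
        assert bool(flags.ld_contact.iloc[0])

    def test_missing_nucleus_is_an_error(self):
        mito, ld, nuc = _planted_scene()
        with pytest.raises(ValueError, match="nucleus"):
            detect_contacts(mito, ld, nuc.like(np.zeros_like(np.asarray(nuc.data))))


class TestClassification:
    def _flags(self, rows):
        return pd.DataFrame([dict(instance_id=i + 1, nucleus_distance_nm=0.0,
                                  ld_distance_nm=0.0, nucleus_near=nn, ld_contact=lc)
                             for i, (nn, lc) in enumerate(rows)])

    def test_lacking_both_contacts_is_cytoplasmic(self):
        labelled, _ = classify_compartments(self._flags([(False, False)]))
        assert labelled.compartment.tolist() == ["CM"]

    def test_droplet_contact_wins_over_nucleus_proximity(self):
        labelled, _ = classify_compartments(self._flags([(True, True)]))
        assert labelled.compartment.tolist() == ["PDM"]

    def test_percentages_partition_to_100(self):
        rows = [(False, True)] * 2 + [(True, False)] * 3 + [(False, False)] * 5
        labelled, pct = classify_compartments(self._flags(rows))
        assert pct == {"PNM": 30.0, "PDM": 20.0, "CM": 50.0}
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)
        assert labelled.compartment.notna().all()

    def test_growing_contact_cutoff_never_loses_pdm(self):
        mito, ld, nuc = _planted_scene()
        counts = []
        for cutoff in (10.0, 25.0, 50.0, 100.0, 400.0):
            flags = detect_contacts(mito, ld, nuc, ContactParams(ld_contact_max=cutoff))
            labelled, _ = classify_compartments(flags)
            counts.append((labelled.compartment == "PDM").sum())
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_precedence_must_cover_all_labels(self):
        with pytest.raises(ValueError, match="precedence"):
            ContactParams(precedence=("PDM", "PDM", "CM"))


class TestDroplets:
    def test_empty_labeling_gives_zero_totals(self):
        records, totals = quantify_lipid_droplets(VolumeGrid(np.zeros((4, 4, 4), np.int32)))
        assert records == []
        assert totals == {"count": 0.0, "total_volume_um3": 0.0}

    def test_sphere_volumes_match_analytic(self, small_scene):
        _, _, truth = small_scene
        cls = np.asarray(truth.class_volume.data)
        inst = np.asarray(truth.instance_volume.data)
        ld_labels = truth.class_volume.like(np.where(cls == 3, inst, 0))
        records, totals = quantify_lipid_droplets(ld_labels)
        ld_truth = truth.instance_table.query("class_id == 3")
        assert totals["count"] == len(ld_truth)
        for rec in records:
            r_nm = float(ld_truth.set_index("instance_id").loc[rec.instance_id,
                                                               "true_radius_nm"])
            analytic = 4 / 3 * np.pi * (r_nm / 1000.0) ** 3
            assert rec.volume == pytest.approx(analytic, rel=0.05)

    def test_splitting_a_label_conserves_total_volume(self):
        ld = np.zeros((4, 8, 8), np.int32)
        ld[1:3, 2:6, 2:6] = 1
        _, before = quantify_lipid_droplets(VolumeGrid(ld, (50, 5, 5)))
        split = ld.copy()
        split[2] = np.where(split[2] == 1, 2, 0)
        _, after = quantify_lipid_droplets(VolumeGrid(split, (50, 5, 5)))
        assert after["count"] == before["count"] + 1
        assert after["total_volume_um3"] == pytest.approx(before["total_volume_um3"],
                                                          abs=0)


class TestPhenotyping:
    @pytest.mark.parametrize("tracer,ratio,expected", [
        ("FBnTP", 0.50, "HI"),   # boundary inclusive
        ("FBnTP", 0.49, "LO"),
        ("FBnTP", 0.51, "HI"),
        ("FDG", 0.20, "HI"),     # boundary inclusive
        ("FDG", 0.19, "LO"),
        ("FDG", 0.21, "HI"),
    ])
    def test_uptake_ratio_thresholds(self, tracer, ratio, expected):
        m = TracerMeasurement(tracer, tumour_uptake=ratio * 10.0, heart_uptake=10.0)
        assert classify_tracer_uptake(m) == expected

    def test_invalid_measurements_rejected(self):
        with pytest.raises(ValueError, match="uptake"):
            TracerMeasurement("FDG", 0.0, 1.0)
        with pytest.raises(ValueError, match="tracer"):
            TracerMeasurement("XYZ", 1.0, 1.0)

    def test_mrc_normalization(self):
        assert normalize_mrc(100.0, 2.0) == 50.0
        assert normalize_mrc(7.3, 1.0) == 7.3
        ocr = pd.Series([120.0, 90.0, 60.0])
        content = pd.Series([2.0, 3.0, 1.5])
        assert np.allclose(normalize_mrc(ocr, content), [60.0, 30.0, 40.0])
        with pytest.raises(ValueError, match="positive"):
            normalize_mrc(10.0, 0.0)
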