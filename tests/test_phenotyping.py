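from __future__ import annotations

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings, strategies as st
from skimage.draw import disk

import mifprep.io as mio
from mifprep.model import ImagePlane, ValidationError
from mifprep.phenotyping import (
    LabelMap,
    assign_identity,
    export_labelmap,
    import_labelmap,
    marker_mask,
    overlap_fractions,
    quantify,
    segment_nuclei,
)
from mifprep.synthetic import make_scene, render_clean_plane
from _oracles import otsu_scan_oracle, overlap_fraction_oracle
from conftest import small_manifest


def _disk_image(centers, radius=8, shape=(96, 96), amplitude=4000):
    arr = np.zeros(shape, dtype=np.uint16)
    for c in centers:
        rr, cc = disk(c, radius, shape=shape)
        arr[rr, cc] = amplitude
    return ImagePlane(arr)


class TestSegmentNuclei:
    def test_single_disk_one_cell_area_within_10pct(self):
        labels = segment_nuclei(_disk_image([(48, 48)]), min_area=30, max_area=2000)
        assert labels.n_cells == 1
        area = (labels.labels == 1).sum()
        assert abs(area - np.pi * 8**2) / (np.pi * 8**2) <= 0.10

    def test_touching_disks_split_by_watershed(self):
        # centers 1.7 radii apart: ~30% of a radius of overlap
        labels = segment_nuclei(_disk_image([(48, 40), (48, 54)], radius=8), min_area=30)
        assert labels.n_cells == 2

    def test_population_recall_precision(self):
        truth = make_scene(n_cells=200, seed=31, n_cycles=1)
        arr = render_clean_plane(truth, 1, truth.manifest[0])
        plane = ImagePlane(np.floor(arr + 0.5).astype(np.uint16))
        labels = segment_nuclei(plane)
        from skimage.measure import regionprops
        from scipy.spatial import cKDTree

        centroids = np.array([p.centroid for p in regionprops(labels.labels)])
        tree = cKDTree(centroids)
        d, _ = tree.query(truth.centroids)
        recall = float((d <= 5).mean())
        d2, _ = cKDTree(truth.centroids).query(centroids)
        precision = float((d2 <= 5).mean())
        assert recall >= 0.95 and precision >= 0.95

    def test_constant_plane_rejected(self):
        with pytest.raises(ValidationError):
            segment_nuclei(ImagePlane(np.full((32, 32), 9, dtype=np.uint16)))


class TestLabelMapIO:
    def test_export_import_round_trip(self, tmp_path):
        labels = segment_nuclei(_disk_image([(30, 30), (70, 70)]))
        export_labelmap(labels, tmp_path / "lab.tif")
        back = import_labelmap(tmp_path / "lab.tif", labels.shape)
        assert np.array_equal(back.labels, labels.labels)

    def test_sparse_labels_made_contiguous(self, tmp_path):
        arr = np.zeros((16, 16), dtype=np.uint16)
        arr[2:5, 2:5] = 3
        arr[10:13, 10:13] = 7
        tifffile.imwrite(tmp_path / "sparse.tif", arr)
        back = import_labelmap(tmp_path / "sparse.tif", (16, 16))
        assert sorted(np.unique(back.labels)) == [0, 1, 2]
        assert back.labels[3, 3] != back.labels[11, 11]

    def test_float_file_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "f.tif", np.zeros((8, 8), dtype=np.float32))
        with pytest.raises(ValidationError, match="integer"):
            import_labelmap(tmp_path / "f.tif", (8, 8))

    def test_shape_mismatch_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "s.tif", np.zeros((8, 8), dtype=np.uint16))
        with pytest.raises(ValidationError, match="shape"):
            import_labelmap(tmp_path / "s.tif", (9, 9))


class TestMarkerMask:
    def test_otsu_threshold_between_bimodal_modes(self, rng):
        lo = rng.normal(500, 40, 3000)
        hi = rng.normal(4000, 200, 1000)
        vals = np.clip(np.concatenate([lo, hi]), 0, 65535)
        plane = ImagePlane(np.floor(vals + 0.5).astype(np.uint16).reshape(80, 50))
        mask = marker_mask(plane, method="otsu")
        # the exhaustive scan oracle places the cut between the modes, and
        # the implementation separates the two populations the same way
        t_oracle = otsu_scan_oracle(plane.astype_float())
        assert 600 < t_oracle < 3500
        vals = plane.astype_float()
        assert mask[vals >= 3500].all()
        assert not mask[vals <= 600].any()

    def test_fixed_zero_threshold_all_true(self, rng):
        plane = ImagePlane(rng.integers(1, 100, (16, 16)).astype(np.uint16))
        assert marker_mask(plane, method="fixed", fixed_threshold=0).all()

    def test_fixed_threshold_above_max_gives_empty_mask(self, rng):
        plane = ImagePlane(rng.integers(0, 100, (16, 16)).astype(np.uint16))
        assert not marker_mask(plane, method="fixed", fixed_threshold=65535).any()

    def test_otsu_on_constant_rejected(self):
        with pytest.raises(ValidationError):
            marker_mask(ImagePlane(np.full((8, 8), 7, dtype=np.uint16)))


class TestOverlapFractions:
    def _labels(self):
        arr = np.zeros((32, 32), dtype=np.int32)
        arr[2:12, 2:12] = 1  # 10x10 square cell
        arr[20:26, 20:26] = 2
        return LabelMap(arr)

    def test_full_and_empty_masks(self):
        labels = self._labels()
        assert np.allclose(overlap_fractions(labels, np.ones((32, 32), bool)), 1.0)
        assert np.allclose(overlap_fractions(labels, np.zeros((32, 32), bool)), 0.0)

    def test_partial_overlap_exact_count(self):
        labels = self._labels()
        mask = np.zeros((32, 32), dtype=bool)
        flat = [(r, c) for r in range(2, 12) for c in range(2, 12)][:55]
        for r, c in flat:
            mask[r, c] = True
        fracs = overlap_fractions(labels, mask)
        assert fracs[0] == 0.55

    def test_matches_counting_oracle_on_random_instance(self, rng):
        from scipy import ndimage as ndi

        blobs = rng.random((64, 64)) > 0.7
        labels_arr, _ = ndi.label(blobs)
        labels = LabelMap(labels_arr.astype(np.int32))
        mask = rng.random((64, 64)) > 0.5
        fracs = overlap_fractions(labels, mask)
        oracle = overlap_fraction_oracle(labels.labels, mask)
        for lab, frac in oracle.items():
            assert np.isclose(fracs[lab - 1], frac)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            overlap_fractions(self._labels(), np.ones((8, 8), bool))


class TestAssignIdentity:
    def test_below_threshold_unassigned(self):
        ident, tie = assign_identity({"IBA1": 0.59, "LYVE-1": 0.10}, threshold=0.60)
        assert ident == "unassigned" and not tie

    def test_single_full_overlap(self):
        assert assign_identity({"IBA1": 1.0}) == ("IBA1", False)

    def test_exclusive_argmax(self):
        ident, tie = assign_identity({"IBA1": 0.70, "LYVE-1": 0.90}, exclusive=True)
        assert ident == "LYVE-1" and not tie

    def test_near_tie_flagged_unassigned(self):
        ident, tie = assign_identity({"A": 0.85, "B": 0.845}, exclusive=True)
        assert ident == "unassigned" and tie

    def test_non_exclusive_lists_all(self):
        ident, tie = assign_identity({"A": 0.9, "B": 0.8, "C": 0.1}, exclusive=False)
        assert ident == "A+B" and not tie

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        fracs=st.dictionaries(
            st.sampled_from(["m1", "m2", "m3"]),
            st.floats(0, 1, allow_nan=False),
            min_size=1,
        ),
        t1=st.floats(0.05, 0.95),
        t2=st.floats(0.05, 0.95),
    )
    def test_monotone_in_threshold(self, fracs, t1, t2):
        """Raising the threshold never turns an unassigned cell assigned."""
        lo, hi = sorted((t1, t2))
        ident_lo, _ = assign_identity(fracs, threshold=lo)
        ident_hi, _ = assign_identity(fracs, threshold=hi)
        if ident_lo == "unassigned":
            assert ident_hi == "unassigned"


class TestQuantify:
    def _registered_stack(self, planes_by_cycle, markers_per_cycle=1):
        manifest = small_manifest(len(planes_by_cycle), markers_per_cycle)
        stack = mio.assemble_hyperstack(
            [(c, ps) for c, ps in enumerate(planes_by_cycle, start=1)], manifest
        )
        stack.registered = True
        return stack

    def test_empty_labelmap_gives_empty_table(self, rng):
        nuc = ImagePlane(rng.integers(0, 100, (32, 32)).astype(np.uint16))
        mk = ImagePlane(rng.integers(0, 100, (32, 32)).astype(np.uint16))
        stack = self._registered_stack([[nuc, mk]])
        table = quantify(stack, LabelMap(np.zeros((32, 32), np.int32)), {"M1_0": np.ones((32, 32), bool)})
        assert len(table) == 0
        df = table.to_dataframe()
        assert list(df.columns)[:4] == ["cell_id", "centroid_row", "centroid_col", "area_px"]

    def test_row_count_and_area_conservation(self):
        nuc = _disk_image([(20, 20), (60, 60), (30, 70)])
        labels = segment_nuclei(nuc)
        stack = self._registered_stack([[nuc, nuc]])
        table = quantify(stack, labels, {"M1_0": nuc.pixels > 0})
        assert len(table) == labels.n_cells
        assert sum(c.area_px for c in table.cells) == (labels.labels > 0).sum()

    def test_known_memberships_recovered(self):
        """Two marker classes rendered over member cells' footprints."""
        truth = make_scene(n_cells=200, seed=41, n_cycles=2)
        nuc = ImagePlane(np.floor(render_clean_plane(truth, 1, truth.manifest[0]) + 0.5).astype(np.uint16))
        mA = ImagePlane(np.floor(render_clean_plane(truth, 1, truth.manifest[1]) + 0.5).astype(np.uint16))
        mB = ImagePlane(np.floor(render_clean_plane(truth, 2, truth.manifest[3]) + 0.5).astype(np.uint16))
        # cycle-2 render drifts; undo the drift to emulate a registered stack
        from mifprep.registration import RigidShift, apply_shift

        dy, dx = truth.drifts[2]
        mB = apply_shift(mB, RigidShift(dy, dx))
        labels = segment_nuclei(nuc)
        manifest = small_manifest(1, 2)
        stack = mio.assemble_hyperstack([(1, [nuc, mA, mB])], manifest)
        stack.registered = True
        masks = {"memA": marker_mask(mA), "memB": marker_mask(mB)}
        table = quantify(stack, labels, masks)
        from scipy.spatial import cKDTree

        centroids = np.array([c.centroid for c in table.cells])
        d, idx = cKDTree(centroids).query(truth.centroids)
        ok = 0
        for t_i, (dist, c_i) in enumerate(zip(d, idx)):
            if dist <= 5 and table.cells[c_i].assigned_identity == f"mem{truth.class_of(t_i)}":
                ok += 1
        assert ok / truth.n_cells >= 0.95

    def test_validity_flags_mark_foreign_markers(self):
        nuc = _disk_image([(48, 48)])
        stack = self._registered_stack([[nuc, nuc]])
        labels = segment_nuclei(nuc)
        masks = {"M1_0": nuc.pixels > 0, "other": np.zeros(nuc.shape, bool)}
        table = quantify(stack, labels, masks)
        cell = table.cells[0]
        assert cell.assigned_identity == "M1_0"
        assert cell.valid["M1_0"] and not cell.valid["other"]
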