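from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import shift as ndi_shift

import mifprep.io as mio
from mifprep.model import ImagePlane, ValidationError
from mifprep.registration import (
    RigidShift,
    apply_shift,
    dapi_retention_qc,
    estimate_shift,
    register_cycles,
)
from mifprep.synthetic import make_scene, render_clean_plane
from conftest import small_manifest, textured_plane


def _nuclei(seed=5, n=120):
    truth = make_scene(n_cells=n, seed=seed, n_cycles=1)
    arr = render_clean_plane(truth, 1, truth.manifest[0])
    return ImagePlane(np.clip(np.floor(arr + 0.5), 0, 65535).astype(np.uint16))


class TestEstimateShift:
    def test_self_registration_identity(self):
        plane = _nuclei()
        s = estimate_shift(plane, plane)
        assert abs(s.dy) < 0.05 and abs(s.dx) < 0.05

    def test_integer_roll_recovered(self):
        plane = _nuclei()
        moved = ImagePlane(np.roll(plane.pixels, (7, -4), axis=(0, 1)))
        s = estimate_shift(plane, moved)
        assert abs(s.dy - 7) <= 0.5 and abs(s.dx + 4) <= 0.5

    def test_subpixel_shift_recovered(self):
        plane = _nuclei()
        moved = ndi_shift(plane.astype_float(), (2.5, 0.0), order=1, mode="nearest")
        s = estimate_shift(plane, ImagePlane(np.floor(moved + 0.5).astype(np.uint16)), upsample=10)
        assert 2.3 <= s.dy <= 2.7
        assert abs(s.dx) <= 0.2

    def test_constant_input_rejected(self):
        flat = ImagePlane(np.full((32, 32), 5, dtype=np.uint16))
        with pytest.raises(ValidationError):
            estimate_shift(flat, flat)

    def test_beyond_max_shift_flagged_zero(self):
        plane = _nuclei()
        moved = ImagePlane(np.roll(plane.pixels, (60, 0), axis=(0, 1)))
        s = estimate_shift(plane, moved, max_shift=20)
        assert s.flagged and s.dy == 0 and s.dx == 0


class TestApplyShift:
    def test_zero_shift_identity(self):
        plane = textured_plane(seed=2)
        assert apply_shift(plane, RigidShift(0, 0)) == plane

    def test_integer_shift_inverse_restores_interior(self):
        plane = textured_plane(seed=3)
        out = apply_shift(apply_shift(plane, RigidShift(3, 0)), RigidShift(-3, 0))
        assert np.array_equal(out.pixels[3:-3], plane.pixels[3:-3])

    def test_closure_residual_below_half_pixel(self):
        ref = _nuclei(seed=8)
        moved = ImagePlane(np.roll(ref.pixels, (5, -7), axis=(0, 1)))
        est = estimate_shift(ref, moved)
        back = apply_shift(moved, est)
        resid = estimate_shift(ref, back)
        assert resid.magnitude < 0.5


class TestRegisterCycles:
    def _drifted_stack(self, drifts):
        """Stack of len(drifts) cycles; each cycle = rolled nuclear + marker."""
        base = _nuclei(seed=12, n=150)
        marker = textured_plane(shape=base.shape, seed=13)
        manifest = small_manifest(n_cycles=len(drifts), markers_per_cycle=1)
        per_cycle = []
        for cyc, (dy, dx) in enumerate(drifts, start=1):
            nuc = ImagePlane(np.roll(base.pixels, (dy, dx), axis=(0, 1)))
            mk = ImagePlane(np.roll(marker.pixels, (dy, dx), axis=(0, 1)))
            per_cycle.append((cyc, [nuc, mk]))
        return mio.assemble_hyperstack(per_cycle, manifest), base

    def test_single_cycle_unchanged(self):
        stack, _ = self._drifted_stack([(0, 0)])
        registered, shifts = register_cycles(stack)
        assert shifts == []
        assert registered.registered
        assert np.array_equal(registered.planes[0].pixels, stack.planes[0].pixels)

    def test_injected_drifts_recovered_and_channels_coshifted(self):
        drifts = [(0, 0), (5, -2), (-3, 8)]
        stack, base = self._drifted_stack(drifts)
        registered, shifts = register_cycles(stack)
        for s, (dy, dx) in zip(shifts, drifts[1:]):
            assert abs(s.dy - dy) <= 0.5 and abs(s.dx - dx) <= 0.5
        # marker planes must land back on the cycle-1 marker frame
        ref_marker = registered.planes[1].astype_float()
        for cyc in (2, 3):
            mk = registered.find(cyc, f"M{cyc}_0").astype_float()
            inner = (slice(12, -12),) * 2
            assert np.corrcoef(ref_marker[inner].ravel(), mk[inner].ravel())[0, 1] > 0.99

    def test_post_registration_residual_below_half_pixel(self):
        stack, _ = self._drifted_stack([(0, 0), (6, 3), (-4, -5)])
        registered, _ = register_cycles(stack)
        ref = registered.nuclear_plane(1)
        for cyc in (2, 3):
            resid = estimate_shift(ref, registered.nuclear_plane(cyc))
            assert resid.magnitude < 0.5

    def test_missing_nuclear_plane_names_cycle(self):
        from mifprep.model import HyperStack

        recs = [r for r in small_manifest(1, 1) if r.role != "nuclear"]
        stack = HyperStack(planes=[textured_plane()], records=recs, registered=False)
        with pytest.raises(ValidationError, match="cycle 1"):
            register_cycles(stack)


def _two_cycle_stack(nuc1: ImagePlane, nuc2: ImagePlane, registered=True):
    manifest = small_manifest(n_cycles=2, markers_per_cycle=0)
    stack = mio.assemble_hyperstack([(1, [nuc1]), (2, [nuc2])], manifest)
    stack.registered = registered
    return stack


class TestRetentionQC:
    def test_identical_cycles_score_one(self):
        plane = _nuclei(seed=20)
        report = dapi_retention_qc(_two_cycle_stack(plane, plane))
        assert [r.dice for r in report.rows] == [1.0, 1.0]
        assert report.rows[1].pearson > 0.999

    def test_twenty_percent_loss_matches_analytic_dice(self):
        truth = make_scene(n_cells=300, seed=21, n_cycles=1)
        full = render_clean_plane(truth, 1, truth.manifest[0])
        r = np.random.default_rng(0)
        lost = r.choice(truth.n_cells, size=truth.n_cells // 5, replace=False)
        keep = np.ones(truth.n_cells, dtype=bool)
        keep[lost] = False
        import mifprep.synthetic as syn

        partial = np.zeros(truth.image_shape)
        syn._paint_blobs(partial, truth.centroids[keep], truth.radii[keep],
                         syn.NUCLEAR_AMPLITUDE, (0.0, 0.0))
        partial += syn._haze(truth)
        stack = _two_cycle_stack(
            ImagePlane(np.floor(full + 0.5).astype(np.uint16)),
            ImagePlane(np.floor(partial + 0.5).astype(np.uint16)),
        )
        report = dapi_retention_qc(stack)
        assert abs(report.rows[1].dice - 2 * 0.8 / 1.8) <= 0.03

    def test_dice_monotone_in_tissue_loss(self):
        truth = make_scene(n_cells=300, seed=22, n_cycles=1)
        import mifprep.synthetic as syn

        def render_fraction(frac_lost):
            r = np.random.default_rng(1)
            lost = r.choice(truth.n_cells, size=int(truth.n_cells * frac_lost), replace=False)
            keep = np.ones(truth.n_cells, dtype=bool)
            keep[lost] = False
            arr = np.zeros(truth.image_shape)
            syn._paint_blobs(arr, truth.centroids[keep], truth.radii[keep],
                             syn.NUCLEAR_AMPLITUDE, (0.0, 0.0))
            arr += syn._haze(truth)
            return ImagePlane(np.floor(arr + 0.5).astype(np.uint16))

        full = render_fraction(0.0)
        dices = []
        for loss in (0.0, 0.1, 0.2, 0.4):
            report = dapi_retention_qc(_two_cycle_stack(full, render_fraction(loss)))
            dices.append(report.rows[1].dice)
        assert all(a > b for a, b in zip(dices, dices[1:])) or dices[0] == 1.0
        assert dices == sorted(dices, reverse=True)

    def test_blank_cycle_scores_zero_and_flagged(self):
        plane = _nuclei(seed=23)
        blank = ImagePlane(np.zeros(plane.shape, dtype=np.uint16))
        report = dapi_retention_qc(_two_cycle_stack(plane, blank))
        assert report.rows[1].dice == 0.0 and report.rows[1].flagged

    def test_unregistered_stack_rejected(self):
        plane = _nuclei(seed=24)
        with pytest.raises(ValidationError, match="register"):
            dapi_retention_qc(_two_cycle_stack(plane, plane, registered=False))
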