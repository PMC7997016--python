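"""Segmentation chain: contour, erosion, shell, spillover, partition."""

import numpy as np
import pytest

from skinsuv import phantom, segmentation
from skinsuv.core import Landmarks, Mask, Plane, Region, SegmentationError, Volume
from conftest import brute_force_erode

SPACING = (3.125, 3.125, 2.809)


def box_mask(shape=(26, 26, 26), lo=3, hi=23) -> Mask:
    data = np.zeros(shape, dtype=bool)
    data[lo:hi, lo:hi, lo:hi] = True
    return Mask(data, SPACING)


class TestBodyContour:
    def test_recovers_phantom_body_exactly(self, noisefree_phantom):
        _, pifa, truth, _ = noisefree_phantom
        mask = segmentation.body_contour_mask(pifa, threshold=0.0)
        assert np.array_equal(mask.data, truth.body.data)

    def test_internal_air_pocket_filled(self):
        data = np.zeros((20, 20, 20))
        data[4:16, 4:16, 4:16] = 0.096
        data[9:11, 9:11, 9:11] = 0.0  # air pocket
        vol = Volume(data, SPACING, kind="attenuation")
        mask = segmentation.body_contour_mask(vol)
        # flood-fill-from-border oracle: the pocket is unreachable from outside
        assert mask.data[10, 10, 10]
        assert mask.count == 12**3

    def test_two_bodies_keeps_larger_with_warning(self, caplog):
        data = np.zeros((30, 16, 16))
        data[2:12, 4:12, 4:12] = 1.0   # 10x8x8 = 640
        data[18:23, 4:9, 4:9] = 1.0    # 5x5x5 = 125
        vol = Volume(data, SPACING, kind="attenuation")
        with caplog.at_level("WARNING"):
            mask = segmentation.body_contour_mask(vol)
        assert mask.count == 640
        assert not mask.data[20, 6, 6]
        assert any("disjoint" in r.message for r in caplog.records)

    def test_empty_threshold_raises(self):
        vol = Volume(np.zeros((5, 5, 5)), SPACING, kind="attenuation")
        with pytest.raises(SegmentationError, match="no body"):
            segmentation.body_contour_mask(vol)


class TestErosion:
    def test_identity_at_zero(self):
        mask = box_mask()
        out = segmentation.erode_mask(mask, 0)
        assert np.array_equal(out.data, mask.data)

    def test_box_erosion_count(self):
        # 20^3 box eroded 3x with the 6-connected cross -> 14^3 interior
        interior = segmentation.erode_mask(box_mask(), 3)
        assert interior.count == 14**3
        expected = np.zeros((26, 26, 26), dtype=bool)
        expected[6:20, 6:20, 6:20] = True
        assert np.array_equal(interior.data, expected)

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_digital_sphere_matches_brute_force(self, n):
        x, y, z = np.ogrid[:23, :23, :23]
        sphere = ((x - 11) ** 2 + (y - 11) ** 2 + (z - 11) ** 2) <= 10**2
        ours = segmentation.erode_mask(Mask(sphere, SPACING), n)
        oracle = brute_force_erode(sphere, n)
        assert np.array_equal(ours.data, oracle)

    def test_iterated_composition(self, rng):
        blob = rng.random((18, 18, 18)) > 0.35
        mask = Mask(blob, SPACING)
        lhs = segmentation.erode_mask(mask, 3)
        rhs = segmentation.erode_mask(segmentation.erode_mask(mask, 2), 1)
        assert np.array_equal(lhs.data, rhs.data)

    def test_full_erosion_to_empty_is_legal(self):
        mask = box_mask(lo=10, hi=14)
        assert segmentation.erode_mask(mask, 5).count == 0


class TestSkinShell:
    def test_box_shell_count(self):
        shell = segmentation.skin_shell(box_mask(), 3)
        assert shell.count == 20**3 - 14**3  # 5256

    def test_shell_interior_set_identity(self):
        body = box_mask()
        shell = segmentation.skin_shell(body, 3)
        interior = segmentation.erode_mask(body, 3)
        assert not (shell.data & interior.data).any()
        assert np.array_equal(shell.data | interior.data, body.data)

    def test_shell_monotone_in_depth(self, noisefree_phantom):
        _, _, truth, _ = noisefree_phantom
        s2 = segmentation.skin_shell(truth.body, 2)
        s3 = segmentation.skin_shell(truth.body, 3)
        assert not (s2.data & ~s3.data).any()

    def test_nominal_depth_mm(self):
        assert segmentation.shell_depth_mm(3, 3.125) == pytest.approx(9.375)

    def test_thin_body_raises(self):
        with pytest.raises(SegmentationError, match="empty"):
            segmentation.skin_shell(box_mask(lo=10, hi=13), 3)


class TestSpilloverExclusion:
    def test_no_nearby_organ_is_identity(self, noisefree_phantom):
        _, _, truth, pet = noisefree_phantom
        shell = truth.shell
        cleaned, report = segmentation.exclude_organ_spillover(
            shell, pet, truth.interior, truth.meta)
        assert report.removed_voxels == 0
        assert np.array_equal(cleaned.data, shell.data)

    def test_infinite_threshold_is_identity(self, noisefree_phantom):
        _, _, truth, pet = noisefree_phantom
        cleaned, report = segmentation.exclude_organ_spillover(
            truth.shell, pet, truth.interior, truth.meta,
            suv_threshold=float("inf"))
        assert report.removed_voxels == 0

    def test_protruding_brain_recovery(self, small_spec):
        spec = phantom._subject_spec(small_spec, 1.0, 1.0, spillover=True, seed=0)
        pifa, truth = phantom.make_body_phantom(spec)
        pet = phantom.make_pet_volume(truth, spec)
        body = segmentation.body_contour_mask(pifa)
        interior = segmentation.erode_mask(body, 3)
        shell = segmentation.skin_shell(body, 3)
        face = truth.shell_labels.region_mask_by_name("face")
        dirty_max = pet.data[shell.data & face].max() * truth.meta.weight_g \
            / truth.meta.dose_bq
        assert dirty_max > 5  # contaminated by brain uptake
        cleaned, report = segmentation.exclude_organ_spillover(
            shell, pet, interior, truth.meta)
        assert report.removed_voxels > 0
        clean_max = pet.data[cleaned.data & face].max() * truth.meta.weight_g \
            / truth.meta.dose_bq
        assert clean_max == pytest.approx(truth.true_region_suv["face"], rel=1e-9)


class TestPartition:
    def test_labels_partition_shell(self, noisefree_phantom):
        _, _, truth, _ = noisefree_phantom
        shell = truth.shell
        labels = segmentation.partition_regions(shell, truth.landmarks)
        assert np.array_equal(labels.shell_mask, shell.data)
        per_region = sum(labels.counts().values())
        assert per_region == shell.count

    def test_matches_brute_force_plane_classification(self, noisefree_phantom):
        spec, _, truth, _ = noisefree_phantom
        shell = truth.shell
        labels = segmentation.partition_regions(shell, truth.landmarks)
        lm = truth.landmarks
        sx, sy, sz = spec.spacing
        for idx in np.argwhere(shell.data):
            i, j, k = idx
            y, z = j * sy, k * sz
            if z > lm.neck.offset_mm:
                want = Region.FACE if y >= lm.ear_canal.offset_mm else Region.SCALP
            elif y < lm.mid_arm.offset_mm:
                want = Region.BACK
            elif z >= lm.t12.offset_mm:
                want = Region.CHEST
            else:
                want = Region.ABDOMEN
            assert labels.labels[i, j, k] == int(want)

    def test_t12_shift_transfers_anterior_trunk_slices(self, noisefree_phantom):
        spec, _, truth, _ = noisefree_phantom
        shell = truth.shell
        lm = truth.landmarks
        base = segmentation.partition_regions(shell, lm)
        k_slices = 2
        shifted_lm = Landmarks(lm.ear_canal, lm.mid_arm,
                               Plane("z", lm.t12.offset_mm - k_slices * spec.spacing[2]),
                               lm.neck)
        shifted = segmentation.partition_regions(shell, shifted_lm)
        gained = int((shifted.labels == int(Region.CHEST)).sum()
                     - (base.labels == int(Region.CHEST)).sum())
        lost = int((base.labels == int(Region.ABDOMEN)).sum()
                   - (shifted.labels == int(Region.ABDOMEN)).sum())
        assert gained == lost > 0
        # exactly the anterior-trunk shell voxels of the transferred slices
        cz = shell.axis_coords(2)
        cy = shell.axis_coords(1)
        in_band = (cz[None, None, :] >= shifted_lm.t12.offset_mm) \
            & (cz[None, None, :] < lm.t12.offset_mm)
        anterior_trunk = (cy[None, :, None] >= lm.mid_arm.offset_mm) \
            & (cz[None, None, :] <= lm.neck.offset_mm)
        expected = int((shell.data & in_band & anterior_trunk).sum())
        assert gained == expected

    def test_plane_outside_volume_raises(self, noisefree_phantom):
        _, _, truth, _ = noisefree_phantom
        lm = truth.landmarks
        bad = Landmarks(lm.ear_canal, lm.mid_arm, Plane("z", 1e4), Plane("z", 2e4))
        with pytest.raises(SegmentationError, match="t12|neck"):
            segmentation.partition_regions(truth.shell, bad)

    def test_full_chain_reproduces_truth_labels(self, noisefree_phantom):
        _, pifa, truth, _ = noisefree_phantom
        body = segmentation.body_contour_mask(pifa)
        shell = segmentation.skin_shell(body, 3)
        labels = segmentation.partition_regions(shell, truth.landmarks)
        assert np.array_equal(labels.labels, truth.shell_labels.labels)
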