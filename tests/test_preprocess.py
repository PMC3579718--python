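"""Masking, denoising, registration and label propagation."""

import numpy as np
import pytest

import memrimap as mm
from memrimap import (
    AffineTransform,
    BrainMask,
    LabelEdit,
    RegistrationOptions,
    VolumeImage,
    adjust_labels,
    apply_brain_mask,
    compute_brain_mask,
    denoise,
    register_affine,
    warp_labels,
)
from memrimap.image import GridMismatchError

from conftest import dice


AFF = np.diag([0.2, 0.2, 0.3, 1.0])


class TestBrainMask:
    def test_full_mask_leaves_image_unchanged(self, rng):
        img = VolumeImage(values=rng.normal(size=(8, 8, 8)), affine=AFF)
        mask = BrainMask(mask=np.ones((8, 8, 8), bool), affine=AFF)
        np.testing.assert_array_equal(apply_brain_mask(img, mask).values, img.values)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            BrainMask(mask=np.zeros((8, 8, 8), bool), affine=AFF)

    def test_half_mask_zeroes_exactly_the_outside(self):
        img = VolumeImage(values=np.full((8, 8, 8), 5.0), affine=AFF)
        half = np.zeros((8, 8, 8), bool)
        half[:4] = True
        out = apply_brain_mask(img, BrainMask(mask=half, affine=AFF))
        assert (out.values[:4] == 5.0).all() and (out.values[4:] == 0.0).all()

    def test_grid_mismatch_rejected(self, rng):
        img = VolumeImage(values=rng.normal(size=(8, 8, 8)), affine=AFF)
        mask = BrainMask(mask=np.ones((8, 8, 8), bool), affine=np.eye(4))
        with pytest.raises(GridMismatchError):
            apply_brain_mask(img, mask)

    def test_fallback_otsu_mask_recovers_phantom_brain(self, clean_subject):
        vol, truth, _ = clean_subject
        est = compute_brain_mask(vol)
        assert dice(est.mask, truth.labels > 0) > 0.95


class TestDenoise:
    @pytest.mark.parametrize("method", ["median3d", "aniso_diffusion"])
    def test_constant_image_unchanged(self, method):
        img = VolumeImage(values=np.full((10, 10, 10), 3.0), affine=AFF)
        np.testing.assert_allclose(denoise(img, method).values, 3.0, atol=1e-6)

    def test_median_removes_single_impulse(self):
        data = np.full((9, 9, 9), 2.0)
        data[4, 4, 4] = 100.0
        out = denoise(VolumeImage(values=data, affine=AFF), "median3d", radius=1)
        assert out.values[4, 4, 4] == 2.0

    def test_median_reduces_noise_sd(self, rng):
        truth = np.full((24, 24, 24), 50.0)
        noisy = truth + rng.normal(0, 5, size=truth.shape)
        out = denoise(VolumeImage(values=noisy, affine=AFF), "median3d", radius=1)
        inner = (slice(2, -2),) * 3
        assert (out.values[inner] - 50.0).std() < (noisy[inner] - 50.0).std()

    def test_grid_preserved_and_masked_zeros_stay_zero(self, clean_subject):
        vol, truth, mask = clean_subject
        out = denoise(apply_brain_mask(vol, mask), "median3d", mask=mask)
        assert out.shape == vol.shape
        assert (out.values[~mask.mask] == 0).all()

    def test_unknown_method_and_bad_radius_rejected(self, rng):
        img = VolumeImage(values=rng.normal(size=(8, 8, 8)), affine=AFF)
        with pytest.raises(ValueError, match="unknown"):
            denoise(img, "boxcar")
        with pytest.raises(ValueError, match="radius"):
            denoise(img, "median3d", radius=0)


class TestWarpLabels:
    def test_identity_transform_same_grid_unchanged(self, atlas):
        out = warp_labels(atlas.labels, AffineTransform.identity(), atlas.template)
        np.testing.assert_array_equal(out.labels, atlas.labels.labels)

    def test_one_voxel_pitch_translation_shifts_by_one_index(self, atlas):
        dy = atlas.template.spacing[1]
        t = AffineTransform.from_params(translation_mm=(0.0, dy, 0.0))
        out = warp_labels(atlas.labels, t, atlas.template)
        np.testing.assert_array_equal(out.labels[:, 1:, :], atlas.labels.labels[:, :-1, :])

    def test_random_affine_round_trip_high_dice(self, atlas, rng):
        t = mm.random_misalignment(rng, center_mm=atlas.center_mm)
        fwd = warp_labels(atlas.labels, t, atlas.template)
        back = warp_labels(fwd, t.inverse(), atlas.template)
        for roi in ("hippocampus", "cerebellum", "thalamus"):
            d = dice(back.mask(roi), atlas.labels.mask(roi))
            assert d >= 0.93, (roi, d)

    def test_no_new_label_ids_introduced(self, atlas, rng):
        t = mm.random_misalignment(rng, center_mm=atlas.center_mm)
        out = warp_labels(atlas.labels, t, atlas.template)
        assert set(np.unique(out.labels)) <= set(np.unique(atlas.labels.labels))


class TestRegistration:
    def test_self_registration_recovers_identity(self, clean_subject):
        vol, _, _ = clean_subject
        res = register_affine(vol, vol, RegistrationOptions(seed=1, restarts=1))
        t = res.transform
        assert np.abs(t.translation).max() < 0.05  # mm
        # linear part within ~0.5 degree / 0.5% of identity
        assert np.abs(t.linear - np.eye(3)).max() < 0.01

    def test_known_translation_recovered(self, clean_subject):
        vol, _, _ = clean_subject
        shift = AffineTransform.from_params(translation_mm=(0.4, 0.0, 0.0))
        from scipy import ndimage

        A = vol.affine
        voxmap = np.linalg.inv(A) @ np.linalg.inv(shift.matrix) @ A
        shifted = ndimage.affine_transform(
            vol.values, voxmap[:3, :3], offset=voxmap[:3, 3], order=1
        )
        res = register_affine(
            vol, VolumeImage(values=shifted, affine=A),
            RegistrationOptions(seed=2, restarts=1),
        )
        # moving -> fixed transform should report the +0.4 mm x shift
        assert abs(res.transform.translation[0] - 0.4) < 0.1
        assert np.abs(res.transform.translation[1:]).max() < 0.1

    def test_phantom_misalignment_recovered_dice(self, atlas):
        rng = np.random.default_rng(77)
        mis = mm.random_misalignment(rng, center_mm=atlas.center_mm)
        spec = mm.default_control_spec(misalignment=mis, seed=78)
        vol, truth = mm.simulate_subject(atlas, spec)
        mask = BrainMask(mask=truth.labels > 0, affine=truth.affine)
        clean = denoise(apply_brain_mask(vol, mask), mask=mask)
        res = register_affine(atlas.template, clean, RegistrationOptions(seed=79))
        warped = warp_labels(atlas.labels, res.transform, clean)
        assert dice(warped.mask("hippocampus"), truth.mask("hippocampus")) >= 0.90

    def test_empty_image_rejected(self, rng):
        z = VolumeImage(values=np.zeros((16, 16, 16)), affine=AFF)
        v = VolumeImage(values=rng.random(size=(16, 16, 16)), affine=AFF)
        with pytest.raises(ValueError, match="empty"):
            register_affine(z, v)


class TestAdjustLabels:
    def test_empty_edit_list_is_identity(self, atlas):
        out = adjust_labels(atlas.labels, [])
        np.testing.assert_array_equal(out.labels, atlas.labels.labels)

    def test_reassignment_conserves_counts(self, atlas):
        src = atlas.roi_table["thalamus"]
        dst = atlas.roi_table["midbrain"]
        idx = np.argwhere(atlas.labels.labels == src)[:10]
        out = adjust_labels(atlas.labels, [LabelEdit(indices=idx, new_id=dst)])
        assert (out.labels == src).sum() == (atlas.labels.labels == src).sum() - 10
        assert (out.labels == dst).sum() == (atlas.labels.labels == dst).sum() + 10
        assert len(out.edit_log) == 1

    def test_overlapping_edits_later_wins_and_logged(self, atlas):
        idx = np.argwhere(atlas.labels.labels == atlas.roi_table["thalamus"])[:5]
        e1 = LabelEdit(indices=idx, new_id=atlas.roi_table["midbrain"], note="first")
        e2 = LabelEdit(indices=idx, new_id=atlas.roi_table["brainstem"], note="second")
        out = adjust_labels(atlas.labels, [e1, e2])
        i, j, k = idx.T
        assert (out.labels[i, j, k] == atlas.roi_table["brainstem"]).all()
        assert [e["note"] for e in out.edit_log] == ["first", "second"]

    def test_unknown_target_id_rejected(self, atlas):
        idx = np.argwhere(atlas.labels.labels > 0)[:3]
        with pytest.raises(ValueError, match="absent"):
            adjust_labels(atlas.labels, [LabelEdit(indices=idx, new_id=99)])
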