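"""ROI metrics against per-voxel brute-force oracles."""

import math

import numpy as np
import pytest

from memrimap import (
    BrainMask,
    LabelVolume,
    VolumeImage,
    ca1_dg_ratio,
    group_volume_ratio,
    hippocampal_thickness,
    relative_intensity,
    roi_metrics,
    roi_metrics_table,
    segmented_volume,
)
from memrimap.zmap import ZScoreMap

AFF = np.diag([0.2, 0.2, 0.25, 1.0])
VOXVOL = 0.2 * 0.2 * 0.25


def make_instance(seed, shape=(16, 16, 16)):
    """Random z map + random 3-ROI label field on a 16^3 grid."""
    rng = np.random.default_rng(seed)
    z = rng.normal(0, 1.2, size=shape)
    labels = rng.integers(0, 4, size=shape).astype(np.int16)
    mask = rng.random(size=shape) < 0.9
    lv = LabelVolume(labels=labels, affine=AFF, roi_table={"r1": 1, "r2": 2, "r3": 3})
    zm = ZScoreMap(
        values=np.where(mask & (z >= 1.0), z, 0.0),
        mask=BrainMask(mask=mask, affine=AFF),
        affine=AFF, brain_mean=0.0, brain_sd=1.0, threshold=1.0,
    )
    return zm, lv, z, mask


def brute_force_roi(z, labels, mask, roi_id, z_t=1.0):
    """Independent per-voxel loop oracle."""
    n_total = n_supra = 0
    total = 0.0
    for i in range(z.shape[0]):
        for j in range(z.shape[1]):
            for k in range(z.shape[2]):
                if labels[i, j, k] == roi_id and mask[i, j, k]:
                    n_total += 1
                    if z[i, j, k] >= z_t:
                        n_supra += 1
                        total += z[i, j, k]
    mean = total / n_supra if n_supra else math.nan
    return n_total, n_supra, mean


@pytest.mark.parametrize("seed", range(12))
def test_roi_metrics_match_brute_force_loop(seed):
    zm, lv, z, mask = make_instance(seed, shape=(12, 12, 12))
    for roi, rid in lv.roi_table.items():
        rec = roi_metrics(zm, lv, roi)
        n_total, n_supra, mean = brute_force_roi(z, lv.labels, mask, rid)
        assert rec.n_voxels_total == n_total
        assert rec.n_voxels_suprathreshold == n_supra
        if n_supra:
            assert abs(rec.mean_supra_z - mean) < 1e-12
        else:
            assert math.isnan(rec.mean_supra_z)
        assert abs(rec.active_volume_mm3 - n_supra * VOXVOL) < 1e-12
        assert abs(rec.roi_volume_mm3 - n_total * VOXVOL) < 1e-12


def test_vectorized_table_equals_per_roi_calls():
    zm, lv, _, _ = make_instance(99)
    singles = {roi: roi_metrics(zm, lv, roi) for roi in lv.roi_table}
    for rec in roi_metrics_table(zm, lv, list(lv.roi_table)):
        s = singles[rec.roi]
        assert rec.n_voxels_suprathreshold == s.n_voxels_suprathreshold
        assert rec.n_voxels_total == s.n_voxels_total
        assert (math.isnan(rec.mean_supra_z) and math.isnan(s.mean_supra_z)) or \
            abs(rec.mean_supra_z - s.mean_supra_z) < 1e-9


def test_worked_example_three_hot_voxels():
    z = np.zeros((10, 1, 1))
    z[:3, 0, 0] = 2.0
    labels = np.ones((10, 1, 1), dtype=np.int16)
    aff = np.diag([0.2, 0.2, 0.25, 1.0])  # voxel volume 0.01 mm^3
    lv = LabelVolume(labels=labels, affine=aff, roi_table={"roi": 1})
    zm = ZScoreMap(values=z, mask=BrainMask(mask=np.ones_like(labels, bool), affine=aff),
                   affine=aff, brain_mean=0, brain_sd=1, threshold=1.0)
    rec = roi_metrics(zm, lv, "roi")
    assert rec.mean_supra_z == 2.0
    assert abs(rec.active_volume_mm3 - 0.03) < 1e-12


def test_unthresholded_map_refused():
    zm, lv, _, _ = make_instance(1)
    zm.threshold = None
    with pytest.raises(ValueError, match="threshold"):
        roi_metrics(zm, lv, "r1")


def test_disjoint_roi_active_volumes_sum():
    zm, lv, _, _ = make_instance(5)
    parts = [roi_metrics(zm, lv, r).active_volume_mm3 for r in ("r1", "r2", "r3")]
    supra = (zm.values >= 1.0) & zm.mask.mask & (lv.labels > 0)
    assert abs(sum(parts) - supra.sum() * VOXVOL) < 1e-9


class TestRelativeIntensity:
    def test_uniform_image_gives_one(self, atlas):
        img = VolumeImage(values=np.where(atlas.labels.labels > 0, 4.0, 0.0),
                          affine=atlas.template.affine)
        mask = BrainMask(mask=atlas.labels.labels > 0, affine=atlas.template.affine)
        for roi in ("hippocampus", "ca1", "cerebellum"):
            assert abs(relative_intensity(img, atlas.labels, roi, mask) - 1.0) < 1e-7

    def test_constructed_ratio_recovered_exactly(self):
        labels = np.zeros((8, 8, 8), dtype=np.int16)
        labels[:4] = 1  # half the volume ROI 1, half ROI 2
        labels[4:] = 2
        lv = LabelVolume(labels=labels, affine=AFF, roi_table={"hot": 1, "cold": 2})
        img = VolumeImage(values=np.where(labels == 1, 3.0, 1.0), affine=AFF)
        mask = BrainMask(mask=np.ones_like(labels, bool), affine=AFF)
        # brain mean = 2, ROI mean = 3 -> 1.5
        assert abs(relative_intensity(img, lv, "hot", mask) - 1.5) < 1e-6

    def test_invariant_to_global_scaling(self, atlas, clean_subject, rng):
        vol, truth, mask = clean_subject
        r1 = relative_intensity(vol, truth, "thalamus", mask)
        scaled = VolumeImage(values=vol.values * 7.3, affine=vol.affine)
        r2 = relative_intensity(scaled, truth, "thalamus", mask)
        assert abs(r1 - r2) < 1e-6


class TestCa1DgRatio:
    def test_uniform_image_gives_one(self, atlas):
        img = VolumeImage(values=np.where(atlas.labels.labels > 0, 2.0, 0.0),
                          affine=atlas.template.affine)
        mask = BrainMask(mask=atlas.labels.labels > 0, affine=atlas.template.affine)
        assert abs(ca1_dg_ratio(img, atlas.labels, mask) - 1.0) < 1e-7

    def test_constructed_enhancement_ratio(self, atlas):
        base = np.where(atlas.labels.labels > 0, 1.0, 0.0)
        ca1 = atlas.labels.labels == atlas.roi_table["ca1"]
        dg = atlas.labels.labels == atlas.roi_table["dg"]
        base[ca1] = 1.2
        base[dg] = 0.8
        img = VolumeImage(values=base, affine=atlas.template.affine)
        mask = BrainMask(mask=atlas.labels.labels > 0, affine=atlas.template.affine)
        assert abs(ca1_dg_ratio(img, atlas.labels, mask) - 1.5) < 1e-6


class TestThickness:
    def slab_labels(self, n_thick, spacing_z=0.3):
        """Synthetic hippocampal slab of known dorsoventral thickness."""
        labels = np.zeros((40, 20, 20), dtype=np.int16)
        labels[5:35, 8:12, 6:6 + n_thick] = 10
        aff = np.diag([0.2, 0.2, spacing_z, 1.0])
        aff[:3, 3] = [-4.0, -4.0, -3.0]  # midline at i=20, y=-2 at j=10
        return LabelVolume(labels=labels, affine=aff, roi_table={"hippocampus": 10})

    def test_six_voxel_slab_is_1p8_mm(self):
        lv = self.slab_labels(6)
        t = hippocampal_thickness(lv, ap_coordinate=-2.0, lateral_offset=1.5)
        assert abs(t.thickness_mm - 1.8) < 1e-9
        assert t.left_mm == t.right_mm == t.thickness_mm

    def test_asymmetric_hemispheres_averaged_with_sides_kept(self):
        lv = self.slab_labels(8)
        # thin the left hemisphere column region to 6 voxels
        left_cols = lv.labels[:20]
        left_cols[..., 12:] = 0
        lv.labels[:20] = left_cols
        lv.labels[:20, :, 6:12] = np.where(
            lv.labels[:20, :, 6:12] > 0, 10, 0
        )
        t = hippocampal_thickness(lv, ap_coordinate=-2.0, lateral_offset=1.5)
        assert abs(t.left_mm - 1.8) < 1e-9
        assert abs(t.right_mm - 2.4) < 1e-9
        assert abs(t.thickness_mm - 2.1) < 1e-9

    def test_column_missing_hippocampus_flagged_not_zero(self):
        lv = self.slab_labels(6)
        t = hippocampal_thickness(lv, ap_coordinate=-2.0, lateral_offset=30.0)
        assert math.isnan(t.thickness_mm)

    def test_phantom_sheet_thickness_recovered_within_one_pitch(self, atlas):
        hip = atlas.labels.mask("hippocampus")
        t = hippocampal_thickness(atlas.labels, ap_coordinate=-2.0, lateral_offset=1.5)
        # ground truth: longest contiguous run in the measured columns
        aff = atlas.labels.affine
        inv = np.linalg.inv(aff)
        j = int(round((inv[:3, :3] @ [0, -2.0, 0] + inv[:3, 3])[1]))
        dz = atlas.labels.spacing[2]
        for x, measured in ((-1.5, t.left_mm), (1.5, t.right_mm)):
            i = int(round((inv[:3, :3] @ [x, -2.0, 0] + inv[:3, 3])[0]))
            col = hip[i, j, :]
            runs = np.diff(np.flatnonzero(np.diff(np.r_[0, col.astype(int), 0])))
            true_mm = runs.max() * dz if runs.size else math.nan
            assert abs(measured - true_mm) <= dz + 1e-9


class TestVolumes:
    def test_thousand_voxels_at_0p01_mm3(self):
        labels = np.zeros((10, 10, 10), dtype=np.int16)
        labels.ravel()[:1000] = 1
        aff = np.diag([0.2, 0.2, 0.25, 1.0])
        lv = LabelVolume(labels=labels, affine=aff, roi_table={"roi": 1})
        assert abs(segmented_volume(lv, "roi") - 10.0) < 1e-9

    def test_exact_ratio_recovered(self):
        assert abs(group_volume_ratio([7.0, 7.0], [10.0, 10.0]) - 70.0) < 1e-12

    def test_empty_roi_rejected(self, atlas):
        lv = LabelVolume(labels=np.zeros((8, 8, 8), dtype=np.int16),
                         affine=AFF, roi_table={"roi": 1})
        with pytest.raises(ValueError, match="empty"):
            segmented_volume(lv, "roi")
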