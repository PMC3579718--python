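"""Per-subject ROI and hippocampal sub-region metrics.

Two distinct readouts coexist: thresholded Z-scale metrics (mean
suprathreshold Z and active volume per ROI) and relative-intensity
metrics on the raw scale (ROI mean divided by whole-brain mean), which
is how the CA1/DG sub-region contrast is quantified.  Volumes are always
voxel count x voxel volume in mm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image import BrainMask, LabelVolume, VolumeImage
from .zmap import ZScoreMap

__all__ = [
    "ROIRecord",
    "SubregionRecord",
    "ThicknessMeasure",
    "roi_metrics",
    "roi_metrics_table",
    "relative_intensity",
    "ca1_dg_ratio",
    "hippocampal_thickness",
    "segmented_volume",
    "group_volume_ratio",
    "subregion_metrics",
]


@dataclass
class ROIRecord:
    subject_id: str
    group: str
    roi: str
    n_voxels_total: int
    n_voxels_suprathreshold: int
    mean_supra_z: float  # NaN when no suprathreshold voxels
    active_volume_mm3: float
    roi_volume_mm3: float
    z_threshold: float


@dataclass
class SubregionRecord:
    subject_id: str
    group: str
    rel_intensity_ca1: float
    rel_intensity_dg: float
    ca1_dg_ratio: float
    hippocampal_thickness_mm: float
    hippocampus_volume_mm3: float
    ca1_volume_mm3: float
    dg_volume_mm3: float


def _require_thresholded(zmap: ZScoreMap) -> float:
    if zmap.threshold is None:
        raise ValueError("ROI metrics require a thresholded z map")
    return zmap.threshold


def roi_metrics(
    zmap: ZScoreMap,
    labels: LabelVolume,
    roi: str,
    subject_id: str = "",
    group: str = "",
) -> ROIRecord:
    """Mean suprathreshold Z and active volume (mm^3) for one ROI.

    ``mean_supra_z`` averages only voxels at or above the threshold; with
    no suprathreshold voxel it is NaN (recording 0 would drag group means
    toward the threshold) while the active volume is legitimately 0.
    """
    z_t = _require_thresholded(zmap)
    roi_mask = labels.mask(roi) & zmap.mask.mask
    n_total = int(roi_mask.sum())
    if roi_mask.size != zmap.values.size:
        raise ValueError("label grid does not match z map grid")
    vals = zmap.values[roi_mask]
    supra = vals[vals >= z_t]
    n_supra = int(supra.size)
    vv = zmap.voxel_volume
    return ROIRecord(
        subject_id=subject_id,
        group=group,
        roi=roi,
        n_voxels_total=n_total,
        n_voxels_suprathreshold=n_supra,
        mean_supra_z=float(supra.mean()) if n_supra else math.nan,
        active_volume_mm3=n_supra * vv,
        roi_volume_mm3=n_total * vv,
        z_threshold=z_t,
    )


def roi_metrics_table(
    zmap: ZScoreMap,
    labels: LabelVolume,
    rois: list[str],
    subject_id: str = "",
    group: str = "",
) -> list[ROIRecord]:
    """Vectorized :func:`roi_metrics` over many ROIs (single bincount pass)."""
    z_t = _require_thresholded(zmap)
    lab = labels.labels
    in_mask = zmap.mask.mask
    supra = in_mask & (zmap.values >= z_t)
    n_ids = int(lab.max()) + 1
    tot_counts = np.bincount(lab[in_mask].ravel(), minlength=n_ids)
    supra_counts = np.bincount(lab[supra].ravel(), minlength=n_ids)
    supra_sums = np.bincount(
        lab[supra].ravel(), weights=zmap.values[supra].ravel(), minlength=n_ids
    )
    vv = zmap.voxel_volume
    records = []
    for roi in rois:
        ids = [i for i in labels.ids_for(roi) if i < n_ids]
        n_total = int(sum(tot_counts[i] for i in ids))
        n_supra = int(sum(supra_counts[i] for i in ids))
        s = float(sum(supra_sums[i] for i in ids))
        records.append(
            ROIRecord(
                subject_id=subject_id,
                group=group,
                roi=roi,
                n_voxels_total=n_total,
                n_voxels_suprathreshold=n_supra,
                mean_supra_z=s / n_supra if n_supra else math.nan,
                active_volume_mm3=n_supra * vv,
                roi_volume_mm3=n_total * vv,
                z_threshold=z_t,
            )
        )
    return records


def relative_intensity(
    image: VolumeImage, labels: LabelVolume, roi: str, mask: BrainMask
) -> float:
    """Mean ROI intensity divided by mean whole-brain (in-mask) intensity."""
    image.require_same_grid(mask, "mask")
    image.require_same_grid(labels, "labels")
    roi_mask = labels.mask(roi) & mask.mask
    if not roi_mask.any():
        raise ValueError(f"ROI {roi!r} is empty within the brain mask")
    brain_mean = float(image.values[mask.mask].mean(dtype=np.float64))
    if brain_mean == 0:
        raise ValueError("whole-brain mean intensity is zero")
    return float(image.values[roi_mask].mean(dtype=np.float64)) / brain_mean


def ca1_dg_ratio(image: VolumeImage, labels: LabelVolume, mask: BrainMask) -> float:
    """CA1:DG relative-intensity ratio (the whole-brain mean cancels)."""
    return relative_intensity(image, labels, "ca1", mask) / relative_intensity(
        image, labels, "dg", mask
    )


@dataclass
class ThicknessMeasure:
    thickness_mm: float  # mean over measurable hemispheres; NaN if none
    left_mm: float
    right_mm: float
    ap_coordinate_mm: float
    lateral_offset_mm: float


def _column_run_mm(column: np.ndarray, dz: float) -> float:
    """Length (mm) of the contiguous hippocampal run containing the
    dorsal-most hippocampal voxel of a dorsoventral column."""
    idx = np.flatnonzero(column)
    if idx.size == 0:
        return math.nan
    top = idx[-1]  # dorsal-most (z increases dorsally in RAS)
    k = top
    while k - 1 >= 0 and column[k - 1]:
        k -= 1
    return (top - k + 1) * dz


def hippocampal_thickness(
    labels: LabelVolume,
    ap_coordinate: float = -2.0,
    lateral_offset: float = 1.5,
) -> ThicknessMeasure:
    """Dorsoventral hippocampal thickness on a coronal slice.

    At the coronal (y) slice nearest ``ap_coordinate`` (mm from bregma),
    the column ``lateral_offset`` mm each side of the midsagittal plane is
    scanned along z; thickness is the contiguous run of hippocampal
    voxels containing the dorsal-most hit, times the z pitch.  Hemispheres
    are measured separately and averaged; a column that misses the
    hippocampus is a missing value, never zero.  Assumes an axis-aligned
    (atlas-space) grid.
    """
    aff = labels.affine
    inv = np.linalg.inv(aff)
    hip = np.isin(labels.labels, labels.ids_for("hippocampus"))

    def vox(world):
        return inv[:3, :3] @ np.asarray(world, float) + inv[:3, 3]

    j = int(round(vox([0.0, ap_coordinate, 0.0])[1]))
    if not 0 <= j < labels.shape[1]:
        raise ValueError(
            f"coronal plane y={ap_coordinate} mm falls outside the volume"
        )
    dz = float(labels.spacing[2])
    sides = {}
    for name, x in (("left", -lateral_offset), ("right", +lateral_offset)):
        i = int(round(vox([x, ap_coordinate, 0.0])[0]))
        if not 0 <= i < labels.shape[0]:
            sides[name] = math.nan
            continue
        sides[name] = _column_run_mm(hip[i, j, :], dz)
    measurable = [v for v in sides.values() if not math.isnan(v)]
    return ThicknessMeasure(
        thickness_mm=float(np.mean(measurable)) if measurable else math.nan,
        left_mm=sides["left"],
        right_mm=sides["right"],
        ap_coordinate_mm=ap_coordinate,
        lateral_offset_mm=lateral_offset,
    )


def segmented_volume(labels: LabelVolume, roi: str) -> float:
    """ROI volume in mm^3 (voxel count x voxel volume)."""
    n = labels.count(roi)
    if n == 0:
        raise ValueError(f"ROI {roi!r} is empty")
    return n * labels.voxel_volume


def group_volume_ratio(test_volumes, reference_volumes) -> float:
    """100 x mean(test) / mean(reference), in percent.

    With mutant volumes as test and control volumes as reference, a value
    of 70% corresponds to a 30% volume loss.
    """
    test = np.asarray(list(test_volumes), dtype=float)
    ref = np.asarray(list(reference_volumes), dtype=float)
    if test.size == 0 or ref.size == 0:
        raise ValueError("both groups need at least one volume")
    return float(100.0 * test.mean() / ref.mean())


def subregion_metrics(
    image: VolumeImage,
    labels: LabelVolume,
    mask: BrainMask,
    subject_id: str = "",
    group: str = "",
    ap_coordinate: float = -2.0,
    lateral_offset: float = 1.5,
) -> SubregionRecord:
    """Bundle the hippocampal sub-region readouts for one subject."""
    ca1 = relative_intensity(image, labels, "ca1", mask)
    dg = relative_intensity(image, labels, "dg", mask)
    thick = hippocampal_thickness(labels, ap_coordinate, lateral_offset)
    return SubregionRecord(
        subject_id=subject_id,
        group=group,
        rel_intensity_ca1=ca1,
        rel_intensity_dg=dg,
        ca1_dg_ratio=ca1 / dg,
        hippocampal_thickness_mm=thick.thickness_mm,
        hippocampus_volume_mm3=segmented_volume(labels, "hippocampus"),
        ca1_volume_mm3=segmented_volume(labels, "ca1"),
        dg_volume_mm3=segmented_volume(labels, "dg"),
    )
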