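"""Voxel-wise Z-score normalization, thresholding and histogram census.

Each masked, denoised scan is converted to a Z-score map: the mean signal
intensity over the extracted brain volume (x̄) is subtracted from every
in-mask voxel xᵢ and the result divided by the whole-brain standard
deviation σ,

    Zᵢ = (xᵢ − x̄) / σ,

with x̄ and σ computed over in-mask voxels only (population 1/N SD; at
the ~10⁵ brain voxels of a typical scan the sample/population distinction
is negligible, but one convention must be fixed for exact tests).  A
voxel at Z ≥ 1 sits at least one whole-brain standard deviation above the
mean — the preset activity threshold.  Thresholding zeroes sub-threshold
voxels and returns a *new* map; the un-thresholded map is retained for
the histogram census and suprathreshold-fraction statistics, which use
the full distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import BrainMask, VolumeImage

__all__ = [
    "ZScoreMap",
    "HistogramCensus",
    "zscore_normalize",
    "threshold_map",
    "suprathreshold_fraction",
    "histogram_census",
    "default_bin_edges",
    "NormalizationError",
]


class NormalizationError(ValueError):
    """Degenerate input to z-normalization (e.g. constant image)."""


@dataclass
class ZScoreMap:
    """Normalized map restricted to a brain mask.

    ``threshold`` is ``None`` while un-thresholded; after
    :func:`threshold_map` it records the applied Z_t.  ``brain_mean`` and
    ``brain_sd`` are kept as provenance of the normalization.
    """

    values: np.ndarray  # z scores; 0 outside the mask
    mask: BrainMask
    affine: np.ndarray
    brain_mean: float
    brain_sd: float
    threshold: float | None = None

    @property
    def in_mask(self) -> np.ndarray:
        """1-D array of in-mask z values."""
        return self.values[self.mask.mask]

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


def zscore_normalize(image: VolumeImage, mask: BrainMask) -> ZScoreMap:
    """Z-score the image over the brain mask.

    Raises :class:`NormalizationError` on a constant (zero-variance)
    image or a mask of fewer than two voxels.
    """
    image.require_same_grid(mask, "mask")
    if mask.n_voxels < 2:
        raise NormalizationError("mask must contain at least 2 voxels")
    inside = image.values[mask.mask].astype(np.float64)
    mean = float(inside.mean())
    sd = float(inside.std())  # population (1/N)
    if sd <= 0:
        raise NormalizationError("constant image: zero variance over the mask")
    z = np.zeros(image.shape, dtype=np.float64)
    z[mask.mask] = (inside - mean) / sd
    return ZScoreMap(
        values=z, mask=mask, affine=image.affine.copy(),
        brain_mean=mean, brain_sd=sd,
    )


def threshold_map(zmap: ZScoreMap, z_t: float = 1.0) -> ZScoreMap:
    """Zero in-mask voxels below ``z_t``; voxels at or above it are kept.

    Thresholding an already-thresholded map raises — idempotence must be
    requested explicitly by re-thresholding the original map.
    """
    if zmap.threshold is not None:
        raise ValueError(
            f"map already thresholded at Z >= {zmap.threshold}; "
            "threshold the un-thresholded map instead"
        )
    out = np.where(zmap.mask.mask & (zmap.values >= z_t), zmap.values, 0.0)
    return ZScoreMap(
        values=out, mask=zmap.mask, affine=zmap.affine.copy(),
        brain_mean=zmap.brain_mean, brain_sd=zmap.brain_sd, threshold=float(z_t),
    )


def suprathreshold_fraction(zmap: ZScoreMap, z_t: float = 1.0) -> float:
    """Fraction of in-mask voxels with Z >= ``z_t`` (un-thresholded map)."""
    if zmap.threshold is not None:
        raise ValueError("suprathreshold census requires the un-thresholded map")
    inside = zmap.in_mask
    if inside.size == 0:
        raise ValueError("empty mask")
    return float(np.count_nonzero(inside >= z_t) / inside.size)


def default_bin_edges(lo: float = -5.0, hi: float = 8.0, width: float = 0.25) -> np.ndarray:
    return np.arange(lo, hi + width / 2, width)


@dataclass
class HistogramCensus:
    """Per-subject voxel counts on shared Z bins plus group mean ± SE."""

    bin_edges: np.ndarray
    counts: pd.DataFrame  # columns: group, subject, bin_lo, bin_hi, count
    summary: pd.DataFrame  # columns: group, bin_lo, bin_hi, mean_count, se_count


def histogram_census(
    zmaps_by_group: dict[str, dict[str, ZScoreMap]],
    bin_edges: np.ndarray | None = None,
) -> HistogramCensus:
    """Census of z-value histograms per subject with group mean ± SE.

    Values beyond the outermost edges are clipped into the end bins so
    each subject's counts sum to its mask size.  SE is the standard error
    of the mean over subjects (0 for a single subject).
    """
    edges = np.asarray(bin_edges if bin_edges is not None else default_bin_edges())
    rows = []
    for group, subjects in zmaps_by_group.items():
        if not subjects:
            raise ValueError(f"group {group!r} has no subjects")
        for sid, zmap in subjects.items():
            vals = zmap.in_mask
            eps = (edges[-1] - edges[0]) * 1e-9
            clipped = np.clip(vals, edges[0], edges[-1] - eps)
            counts, _ = np.histogram(clipped, bins=edges)
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                rows.append(
                    {"group": group, "subject": sid, "bin_lo": float(lo),
                     "bin_hi": float(hi), "count": int(c)}
                )
    counts_df = pd.DataFrame(rows)
    grouped = counts_df.groupby(["group", "bin_lo", "bin_hi"], sort=True)["count"]
    summary = grouped.agg(
        mean_count="mean",
        se_count=lambda x: (x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0,
    ).reset_index()
    summary["se_count"] = summary["se_count"].fillna(0.0)
    return HistogramCensus(bin_edges=edges, counts=counts_df, summary=summary)
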