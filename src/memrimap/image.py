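"""Core in-memory containers shared by every pipeline stage.

All volumes live on a regular 3-D grid indexed ``(i, j, k)`` with a 4x4
voxel-to-world affine in RAS millimetre coordinates (x: left->right,
y: posterior->anterior, z: ventral->dorsal).  World coordinates refer to
voxel centres and indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeImage",
    "LabelVolume",
    "BrainMask",
    "GridMismatchError",
    "HIPPOCAMPAL_FORMATION",
]

#: ROI names whose union constitutes the whole hippocampal formation.  The
#: CA1 and dentate-gyrus subfields carry their own integer labels but are
#: anatomical subsets of the hippocampus, so any query for "hippocampus"
#: resolves to the union of these labels.
HIPPOCAMPAL_FORMATION = ("hippocampus", "ca1", "dg")


class GridMismatchError(ValueError):
    """Two grids that must agree (shape and spacing) do not."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine linear part is singular")
    return affine


@dataclass
class VolumeImage:
    """A 3-D scalar image with grid geometry.

    Parameters
    ----------
    values
        3-D array of intensities (stored float32).
    affine
        4x4 voxel-to-world matrix (mm, RAS).
    """

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got {values.ndim}-D data")
        if not np.isfinite(values).all():
            n_bad = int(np.size(values) - np.isfinite(values).sum())
            raise ValueError(f"volume contains {n_bad} non-finite voxels")
        self.values = np.ascontiguousarray(values, dtype=np.float32)
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel pitch in mm per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "VolumeImage | LabelVolume | BrainMask") -> bool:
        other_shape = other.shape
        other_affine = other.affine
        return self.shape == tuple(other_shape) and np.allclose(
            self.affine, other_affine, atol=1e-6
        )

    def require_same_grid(self, other, what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} grid {other.shape} does not match image grid {self.shape} "
                "(or affines differ)"
            )

    def copy_with(self, values: np.ndarray) -> "VolumeImage":
        return VolumeImage(values=values, affine=self.affine.copy())


@dataclass
class LabelVolume:
    """Integer label map with a name<->id table.

    ``roi_table`` maps ROI name to integer id; id 0 is background and is
    never listed.  The grid geometry mirrors :class:`VolumeImage`.
    """

    labels: np.ndarray
    affine: np.ndarray
    roi_table: dict[str, int]
    edit_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"expected a 3-D label map, got {labels.ndim}-D data")
        if labels.min() < 0:
            raise ValueError("label ids must be >= 0")
        self.labels = np.ascontiguousarray(labels, dtype=np.int16)
        self.affine = _check_affine(self.affine)
        if any(v <= 0 for v in self.roi_table.values()):
            raise ValueError("roi_table ids must be positive (0 is background)")
        present = set(np.unique(self.labels).tolist()) - {0}
        known = set(self.roi_table.values())
        orphans = sorted(present - known)
        if orphans:
            raise ValueError(f"label ids present but absent from roi_table: {orphans}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def id_to_name(self) -> dict[int, str]:
        return {v: k for k, v in self.roi_table.items()}

    def ids_for(self, roi: str) -> tuple[int, ...]:
        """Integer label ids composing ``roi``.

        The whole hippocampal formation is a composite of the generic
        hippocampus label and the CA1/DG subfield labels.
        """
        if roi == "hippocampus":
            ids = tuple(
                self.roi_table[name]
                for name in HIPPOCAMPAL_FORMATION
                if name in self.roi_table
            )
            if ids:
                return ids
        if roi not in self.roi_table:
            raise KeyError(f"ROI {roi!r} not in roi_table")
        return (self.roi_table[roi],)

    def mask(self, roi: str) -> np.ndarray:
        """Boolean mask of a (possibly composite) ROI."""
        return np.isin(self.labels, self.ids_for(roi))

    def count(self, roi: str) -> int:
        return int(self.mask(roi).sum())

    def copy_with(self, labels: np.ndarray) -> "LabelVolume":
        return LabelVolume(
            labels=labels,
            affine=self.affine.copy(),
            roi_table=dict(self.roi_table),
            edit_log=list(self.edit_log),
        )


@dataclass
class BrainMask:
    """Binary brain mask on a subject grid."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got {mask.ndim}-D data")
        self.mask = np.ascontiguousarray(mask.astype(bool))
        self.affine = _check_affine(self.affine)
        if not self.mask.any():
            raise ValueError("brain mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())
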