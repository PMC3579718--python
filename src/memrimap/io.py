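"""Reading and writing of volumes, label maps, masks and result tables.

Volumes travel as NIfTI-1 (``.nii``/``.nii.gz``) through :mod:`nibabel` and
are reoriented to canonical RAS on load; nothing is ever resampled here.
Tables are plain CSV.  Every NIfTI written by the pipeline gets a JSON
sidecar recording the producing stage, so later stages can refuse
out-of-order inputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .image import BrainMask, LabelVolume, VolumeImage

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
    "read_roi_table",
    "write_roi_table",
    "write_table",
    "read_sidecar",
    "write_sidecar",
]


def _load_canonical(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)  # RAS
    if len(img.shape) == 4 and img.shape[3] == 1:
        img = img.slicer[..., 0]
    if len(img.shape) != 3:
        raise ValueError(
            f"{path}: expected a 3-D volume, got {len(img.shape)}-D data "
            f"of shape {tuple(img.shape)}"
        )
    return img


def read_volume(path: str | Path) -> VolumeImage:
    """Load a 3-D scalar NIfTI volume (canonical RAS, no resampling)."""
    img = _load_canonical(path)
    data = np.asarray(img.get_fdata(dtype=np.float32))
    if not np.isfinite(data).all():
        n_bad = int(data.size - np.isfinite(data).sum())
        raise ValueError(f"{path}: {n_bad} non-finite voxels")
    return VolumeImage(values=data, affine=np.asarray(img.affine))


def write_volume(image: VolumeImage, path: str | Path, stage: str | None = None,
                 meta: dict | None = None) -> Path:
    """Write float32 NIfTI; optionally record a provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(image.values.astype(np.float32), image.affine)
    nib.save(img, str(path))
    if stage is not None:
        write_sidecar(path, stage=stage, meta=meta)
    return path


def read_mask(path: str | Path) -> BrainMask:
    img = _load_canonical(path)
    data = np.asarray(img.get_fdata()) > 0.5
    return BrainMask(mask=data, affine=np.asarray(img.affine))


def write_mask(mask: BrainMask, path: str | Path, stage: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), mask.affine)
    nib.save(img, str(path))
    if stage is not None:
        write_sidecar(path, stage=stage)
    return path


def read_labels(path: str | Path, roi_table_path: str | Path) -> LabelVolume:
    """Load an integer label map plus its two-column (id,name) ROI table.

    Raises if the grid contains label ids the table does not name.
    """
    img = _load_canonical(path)
    data = np.rint(np.asarray(img.get_fdata())).astype(np.int16)
    roi_table = read_roi_table(roi_table_path)
    return LabelVolume(labels=data, affine=np.asarray(img.affine), roi_table=roi_table)


def write_labels(labels: LabelVolume, path: str | Path,
                 roi_table_path: str | Path | None = None,
                 stage: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(labels.labels.astype(np.int16), labels.affine)
    nib.save(img, str(path))
    if roi_table_path is not None:
        write_roi_table(labels.roi_table, roi_table_path)
    if stage is not None:
        write_sidecar(path, stage=stage)
    return path


def read_roi_table(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path)
    if not {"id", "name"} <= set(df.columns):
        raise ValueError(f"{path}: ROI table needs columns 'id' and 'name'")
    return {str(row["name"]): int(row["id"]) for _, row in df.iterrows()}


def write_roi_table(roi_table: dict[str, int], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        sorted(((v, k) for k, v in roi_table.items())), columns=["id", "name"]
    )
    df.to_csv(path, index=False)
    return path


def write_table(records, path: str | Path, columns: list[str] | None = None) -> Path:
    """Write a list of dataclass records (or dicts) to CSV.

    An empty record list still produces a header-only CSV when ``columns``
    is given (or can be inferred).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [asdict(r) if is_dataclass(r) else dict(r) for r in records]
    if rows:
        df = pd.DataFrame(rows, columns=columns or list(rows[0].keys()))
    else:
        df = pd.DataFrame(columns=columns or [])
    df.to_csv(path, index=False)
    return path


def _sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    name = path.name
    for ext in (".nii.gz", ".nii", ".csv"):
        if name.endswith(ext):
            name = name[: -len(ext)]
            break
    return path.with_name(name + ".json")


def write_sidecar(path: str | Path, stage: str, meta: dict | None = None) -> Path:
    side = _sidecar_path(path)
    payload = {"stage": stage}
    if meta:
        payload.update(meta)
    side.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return side


def read_sidecar(path: str | Path) -> dict | None:
    side = _sidecar_path(path)
    if not side.exists():
        return None
    return json.loads(side.read_text())
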