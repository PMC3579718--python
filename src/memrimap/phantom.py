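"""Digital mouse-brain phantoms and simulated Mn2+-enhanced cohorts.

The phantom is a nested-ellipsoid stand-in for a segmented adult mouse
brain atlas: a brain ellipsoid carrying the twelve standard analysis ROIs
(neocortex, striatum, globus pallidus, olfactory bulb, hypothalamus,
septum/basal forebrain, midbrain, brainstem, thalamus, hippocampus,
amygdala, cerebellum), the hippocampal CA1/DG subfields as a dorsal
sheet-and-core pair inside a hippocampal slab, lateral ventricles, a
habenular pair, and a generic "other" tissue filler.  World coordinates
are anchored so that the bregma-equivalent origin puts the hippocampal
slab centre at y = -2 mm, mirroring rodent stereotaxic convention.

Simulated subjects modulate the template with region-wise multiplicative
uptake factors (Mn2+ accumulation shortens T1 and raises T1-weighted
signal, so basal activity maps onto a per-region intensity gain),
morphological atrophy with voxel reassignment (hippocampal loss donates
to the ventricles, mimicking ventricular widening), a smooth low-order
bias field, a random affine misalignment, and Rician or Gaussian voxel
noise.  Identical (spec, seed) pairs reproduce bit-identical volumes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import HIPPOCAMPAL_FORMATION, LabelVolume, VolumeImage
from .io import write_labels, write_mask, write_roi_table, write_volume
from .transform import AffineTransform, MisalignmentBounds, random_misalignment

__all__ = [
    "AtlasPhantom",
    "SubjectSpec",
    "CohortManifest",
    "PhantomConstructionError",
    "ATLAS_ROIS",
    "DEFAULT_GRID",
    "DEFAULT_SPACING",
    "build_atlas_phantom",
    "simulate_subject",
    "simulate_cohort",
    "default_control_spec",
    "default_mutant_spec",
]

#: The twelve atlas ROIs used in every group analysis.
ATLAS_ROIS = (
    "neocortex",
    "striatum",
    "globus_pallidus",
    "olfactory_bulb",
    "hypothalamus",
    "septum_basal_forebrain",
    "midbrain",
    "brainstem",
    "thalamus",
    "hippocampus",
    "amygdala",
    "cerebellum",
)

ROI_IDS: dict[str, int] = {
    "neocortex": 1,
    "striatum": 2,
    "globus_pallidus": 3,
    "olfactory_bulb": 4,
    "hypothalamus": 5,
    "septum_basal_forebrain": 6,
    "midbrain": 7,
    "brainstem": 8,
    "thalamus": 9,
    "hippocampus": 10,
    "amygdala": 11,
    "cerebellum": 12,
    "ca1": 13,
    "dg": 14,
    "ventricles": 15,
    "habenula": 16,
    "other": 17,
}

#: Base T1-weighted tissue intensity per label (arbitrary units).  CSF in
#: the ventricles is dark on T1; grey/white contrasts are mild.
TEMPLATE_INTENSITY: dict[str, float] = {
    "neocortex": 100.0,
    "striatum": 100.0,
    "globus_pallidus": 92.0,
    "olfactory_bulb": 105.0,
    "hypothalamus": 100.0,
    "septum_basal_forebrain": 98.0,
    "midbrain": 95.0,
    "brainstem": 94.0,
    "thalamus": 102.0,
    "hippocampus": 104.0,
    "amygdala": 100.0,
    "cerebellum": 98.0,
    "ca1": 106.0,
    "dg": 106.0,
    "ventricles": 35.0,
    "habenula": 104.0,
    "other": 88.0,
}

#: Geometry of the phantom in brain-normalized coordinates: centres and
#: semi-axes are fractions of the brain ellipsoid semi-axes.  Bilateral
#: structures are mirrored about the midline.
_STRUCTURES: list[tuple[str, tuple[float, float, float], tuple[float, float, float], bool]] = [
    # name, centre (ux, uy, uz), semi-axes, bilateral
    ("cerebellum", (0.0, -0.72, 0.30), (0.55, 0.28, 0.42), False),
    ("brainstem", (0.0, -0.78, -0.35), (0.45, 0.34, 0.40), False),
    ("midbrain", (0.0, -0.45, -0.02), (0.40, 0.24, 0.34), False),
    ("olfactory_bulb", (0.24, 0.85, 0.05), (0.22, 0.22, 0.30), True),
    ("striatum", (0.45, 0.35, -0.05), (0.24, 0.30, 0.30), True),
    ("globus_pallidus", (0.38, 0.12, -0.18), (0.13, 0.13, 0.13), True),
    ("septum_basal_forebrain", (0.0, 0.42, -0.32), (0.18, 0.26, 0.26), False),
    ("thalamus", (0.0, -0.05, 0.08), (0.34, 0.24, 0.27), False),
    ("hypothalamus", (0.0, 0.02, -0.55), (0.30, 0.28, 0.24), False),
    ("amygdala", (0.55, -0.02, -0.45), (0.19, 0.19, 0.19), True),
    ("habenula", (0.09, -0.05, 0.44), (0.07, 0.11, 0.09), True),
]

_HIPPO_CENTER = (0.0, -0.30, 0.50)
_HIPPO_SEMI = (0.60, 0.22, 0.18)
_VENTRICLE_CENTER = (0.18, 0.22, 0.18)
_VENTRICLE_SEMI = (0.08, 0.30, 0.13)

DEFAULT_GRID = (128, 128, 64)
DEFAULT_SPACING = (0.2, 0.156, 0.3)

#: relative intensity rise from an ROI's rim to its deepest interior, and
#: the concavity of the rise ((depth/max)^exponent): a sub-linear profile
#: keeps a broad plateau near each core so every ROI retains a
#: suprathreshold tail under subject-level uptake variability
_CORE_AMPLITUDE = 0.7
_CORE_EXPONENT = 0.4

#: Where voxels removed by atrophy are reassigned: hippocampal tissue loss
#: widens the adjacent ventricles; cortical loss becomes extra-axial CSF
#: (background).
ATROPHY_DONOR: dict[str, str] = {
    "hippocampus": "ventricles",
    "ca1": "ventricles",
    "dg": "ventricles",
}


class PhantomConstructionError(ValueError):
    """The requested grid cannot host every ROI."""


@dataclass
class AtlasPhantom:
    """A labeled template brain with its ROI dictionary."""

    template: VolumeImage
    labels: LabelVolume
    roi_table: dict[str, int]
    voxel_spacing: tuple[float, float, float]
    center_mm: np.ndarray  # world coordinates of the brain centre

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels.labels > 0


@dataclass
class SubjectSpec:
    """Generative recipe for one simulated subject.

    ``enhancement`` maps ROI name -> multiplicative uptake factor (the Mn2+
    activity stand-in); ``atrophy`` maps ROI name -> retained volume
    fraction in (0, 1].  Entries are applied in insertion order, so a
    subfield listed after its parent overrides the parent's factor.

    ``uptake_jitter_sd`` is the animal-to-animal regional variability:
    each tissue region's effective uptake is multiplied by an independent
    lognormal factor exp(N(0, sd)) per subject.  Individual animals
    differ in delivered dose, metabolism and behavioural state, so
    regional uptake varies between subjects well beyond voxel noise;
    without it a simulated cohort is unrealistically tight.  Set to 0 for
    analytically exact single-subject constructions.
    """

    group: str = "control"
    enhancement: dict[str, float] = field(default_factory=dict)
    atrophy: dict[str, float] = field(default_factory=dict)
    misalignment: AffineTransform | None = None
    bias_field_amplitude: float = 0.05
    noise_sigma: float = 5.0
    noise_model: str = "rician"
    uptake_jitter_sd: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        for roi, f in self.enhancement.items():
            if f <= 0:
                raise ValueError(f"enhancement factor for {roi!r} must be > 0")
        for roi, f in self.atrophy.items():
            if not 0 < f <= 1:
                raise ValueError(f"atrophy factor for {roi!r} must be in (0, 1]")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class CohortManifest:
    """On-disk inventory of a simulated cohort."""

    subjects: list[dict]  # subject_id, group, volume_path, mask_path, labels_path
    master_seed: int
    path: Path | None = None

    def __post_init__(self) -> None:
        ids = [s["subject_id"] for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")

    def by_group(self, group: str) -> list[dict]:
        return [s for s in self.subjects if s["group"] == group]


# ----------------------------------------------------------------------
# atlas construction
# ----------------------------------------------------------------------

def _ellipsoid(u, center, semi, bilateral=False):
    ux, uy, uz = u
    cx, cy, cz = center
    ax, ay, az = semi
    m = ((ux - cx) / ax) ** 2 + ((uy - cy) / ay) ** 2 + ((uz - cz) / az) ** 2 <= 1.0
    if bilateral and cx != 0.0:
        m |= ((ux + cx) / ax) ** 2 + ((uy - cy) / ay) ** 2 + ((uz - cz) / az) ** 2 <= 1.0
    return m


def build_atlas_phantom(
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING,
    geometry_seed: int = 0,
) -> AtlasPhantom:
    """Construct the deterministic nested-ellipsoid atlas phantom.

    ``geometry_seed`` applies a small reproducible jitter to structure
    centres along the y and z axes (the midline stays exact so bilateral
    symmetry and the midsagittal plane are preserved).
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    voxel_spacing = tuple(float(s) for s in voxel_spacing)
    if len(grid_shape) != 3 or any(n < 32 for n in grid_shape):
        raise ValueError(f"grid must be >= 32 voxels per axis, got {grid_shape}")
    if any(s <= 0 for s in voxel_spacing):
        raise ValueError(f"voxel spacing must be positive, got {voxel_spacing}")

    rng = np.random.default_rng(geometry_seed)
    jitter = {
        name: rng.uniform(-0.02, 0.02, size=2)
        for name, *_ in _STRUCTURES
    }
    jitter["hippocampus"] = rng.uniform(-0.02, 0.02, size=2)
    jitter["ventricles"] = rng.uniform(-0.02, 0.02, size=2)

    shape = np.asarray(grid_shape)
    spacing = np.asarray(voxel_spacing)
    extent = shape * spacing
    brain_semi = 0.45 * extent  # mm

    idx = np.indices(grid_shape).astype(float)
    # grid centre at the origin for construction; bregma anchoring shifts it
    world = [idx[a] * spacing[a] - spacing[a] * (shape[a] - 1) / 2 for a in range(3)]
    u = [world[a] / brain_semi[a] for a in range(3)]

    labels = np.zeros(grid_shape, dtype=np.int16)
    brain = _ellipsoid(u, (0, 0, 0), (1, 1, 1))
    labels[brain] = ROI_IDS["other"]

    # dorsal/lateral cortical shell over the anterior two thirds
    r = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    shell = brain & (r > 0.78) & (u[2] > -0.10) & (u[1] > -0.35)
    labels[shell] = ROI_IDS["neocortex"]

    def place(name, center, semi, bilateral):
        jy, jz = jitter.get(name, (0.0, 0.0))
        c = (center[0], center[1] + jy, center[2] + jz)
        m = _ellipsoid(u, c, semi, bilateral) & brain
        labels[m] = ROI_IDS[name]
        if not m.any():
            raise PhantomConstructionError(
                f"grid {grid_shape} too small to place ROI {name!r}"
            )
        return c

    for name, center, semi, bilateral in _STRUCTURES:
        place(name, center, semi, bilateral)

    hc = place("hippocampus", _HIPPO_CENTER, _HIPPO_SEMI, False)
    # CA1 is a dorsal sheet inside the slab; DG a ventral core beneath it
    hip = labels == ROI_IDS["hippocampus"]
    local = (u[2] - hc[2]) / _HIPPO_SEMI[2]
    labels[hip & (local >= 0.10) & (local <= 0.70)] = ROI_IDS["ca1"]
    labels[hip & (local >= -0.50) & (local < 0.00)] = ROI_IDS["dg"]
    for sub in ("ca1", "dg"):
        if not (labels == ROI_IDS[sub]).any():
            raise PhantomConstructionError(
                f"grid {grid_shape} too small to place ROI {sub!r}"
            )

    place("ventricles", _VENTRICLE_CENTER, _VENTRICLE_SEMI, True)

    template = np.zeros(grid_shape, dtype=np.float64)
    for name, lab in ROI_IDS.items():
        template[labels == lab] = TEMPLATE_INTENSITY[name]

    # Within-region uptake texture: each grey-matter ROI carries a "hot
    # core" rising toward its interior (amplitude _CORE_AMPLITUDE above
    # the rim).  Mn2+ uptake is subregionally heterogeneous in vivo —
    # central amygdala, olfactory-bulb layers, hippocampal laminae — and
    # this texture is what puts a suprathreshold tail in every ROI rather
    # than only in the globally enhanced ones.  It is part of the atlas:
    # identical across subjects, like anatomy.
    for name, lab in ROI_IDS.items():
        if name in ("ventricles", "other"):
            continue
        m = labels == lab
        depth = ndimage.distance_transform_edt(m, sampling=spacing)
        peak = depth.max()
        if peak > 0:
            template[m] *= 1.0 + _CORE_AMPLITUDE * (depth[m] / peak) ** _CORE_EXPONENT

    # anchor bregma: world origin such that the hippocampal slab centre
    # sits at y = -2 mm on the midline
    hippo_y_mm = hc[1] * brain_semi[1]
    shift = np.array([0.0, -2.0 - hippo_y_mm, 0.0])
    origin = -spacing * (shape - 1) / 2 + shift
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin

    template_img = VolumeImage(values=template, affine=affine)
    label_vol = LabelVolume(labels=labels, affine=affine, roi_table=dict(ROI_IDS))
    return AtlasPhantom(
        template=template_img,
        labels=label_vol,
        roi_table=dict(ROI_IDS),
        voxel_spacing=voxel_spacing,
        center_mm=shift,
    )


# ----------------------------------------------------------------------
# subject simulation
# ----------------------------------------------------------------------

def _erode_to_fraction(mask: np.ndarray, fraction: float, spacing: np.ndarray) -> np.ndarray:
    """Boolean mask of the voxels *removed* when eroding ``mask`` toward its
    interior until ``fraction`` of its volume remains.

    Outermost voxels (smallest Euclidean distance to the boundary, in mm)
    go first; ties break on flat index for determinism.
    """
    n0 = int(mask.sum())
    n_target = int(round(fraction * n0))
    if n_target < 1:
        raise ValueError(f"atrophy would empty the ROI ({n0} -> {n_target} voxels)")
    n_remove = n0 - n_target
    if n_remove <= 0:
        return np.zeros_like(mask)
    dist = ndimage.distance_transform_edt(mask, sampling=spacing)
    flat = np.flatnonzero(mask)
    order = np.lexsort((flat, dist.ravel()[flat]))
    removed = np.zeros(mask.size, dtype=bool)
    removed[flat[order[:n_remove]]] = True
    return removed.reshape(mask.shape)


def _bias_field(shape, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Smooth multiplicative shading: 1 + amplitude * quadratic polynomial
    with random coefficients, normalized to unit max magnitude."""
    ax = [np.linspace(-1.0, 1.0, n) for n in shape]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    terms = [x, y, z, x * y, x * z, y * z, x**2, y**2, z**2]
    coef = rng.normal(size=len(terms))
    f = sum(c * t for c, t in zip(coef, terms))
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    return 1.0 + amplitude * f


def _resample_by_misalignment(
    values: np.ndarray,
    labels: np.ndarray,
    affine: np.ndarray,
    mis: AffineTransform,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample intensity (linear) and labels (nearest) onto the same grid
    under an atlas->subject world misalignment."""
    A = affine
    M = mis.matrix
    vox = np.linalg.inv(A) @ np.linalg.inv(M) @ A
    matrix, offset = vox[:3, :3], vox[:3, 3]
    out_vals = ndimage.affine_transform(
        values, matrix, offset=offset, order=1, mode="constant", cval=0.0
    )
    out_labs = ndimage.affine_transform(
        labels, matrix, offset=offset, order=0, mode="constant", cval=0
    )
    return out_vals, out_labs


def simulate_subject(
    atlas: AtlasPhantom, spec: SubjectSpec
) -> tuple[VolumeImage, LabelVolume]:
    """Render one subject volume plus its ground-truth label map.

    Processing order: atrophy (labels + template), region-wise uptake
    factors, bias field, affine misalignment resampling, voxel noise.
    """
    for roi in list(spec.enhancement) + list(spec.atrophy):
        atlas.labels.ids_for(roi)  # raises KeyError on unknown ROI

    labels = atlas.labels.labels.copy()
    template = atlas.template.values.astype(np.float64)
    spacing = atlas.template.spacing

    for roi, frac in spec.atrophy.items():
        if frac >= 1.0:
            continue
        mask = np.isin(labels, atlas.labels.ids_for(roi))
        removed = _erode_to_fraction(mask, frac, spacing)
        donor = ATROPHY_DONOR.get(roi, "background")
        if donor == "background":
            labels[removed] = 0
            template[removed] = 0.0
        else:
            donor_id = atlas.roi_table[donor]
            labels[removed] = donor_id
            template[removed] = TEMPLATE_INTENSITY[donor]

    max_id = int(max(atlas.roi_table.values()))
    gain = np.ones(max_id + 1)
    for roi, f in spec.enhancement.items():
        for lab in atlas.labels.ids_for(roi):
            gain[lab] = f

    rng = np.random.default_rng(spec.seed)
    # subject-specific regional uptake variability (CSF excluded); drawn
    # unconditionally to keep the stream aligned across jitter settings
    jitter = np.exp(rng.normal(0.0, 1.0, size=max_id + 1) * spec.uptake_jitter_sd)
    jitter[0] = 1.0
    if "ventricles" in atlas.roi_table:
        jitter[atlas.roi_table["ventricles"]] = 1.0
    gain = gain * jitter
    intensity = template * gain[labels]
    if spec.bias_field_amplitude > 0:
        intensity = intensity * _bias_field(labels.shape, rng, spec.bias_field_amplitude)
    else:
        # keep the draw sequence aligned whether or not a bias is applied
        rng.normal(size=9)

    if spec.misalignment is not None and not spec.misalignment.is_identity():
        intensity, labels = _resample_by_misalignment(
            intensity, labels, atlas.template.affine, spec.misalignment
        )

    if spec.noise_sigma > 0:
        s = spec.noise_sigma
        if spec.noise_model == "gaussian":
            intensity = intensity + rng.normal(0.0, s, size=intensity.shape)
        else:  # rician: Gaussian noise on two quadrature channels
            re = intensity + rng.normal(0.0, s, size=intensity.shape)
            im = rng.normal(0.0, s, size=intensity.shape)
            intensity = np.sqrt(re**2 + im**2)

    volume = VolumeImage(values=intensity, affine=atlas.template.affine.copy())
    truth = atlas.labels.copy_with(labels)
    return volume, truth


#: Uptake factors shared by both groups: strong enhancement in the
#: canonical Mn2+-avid structures (hippocampal subfields, hypothalamus,
#: amygdala, habenula, basal forebrain, olfactory bulb, cerebellum) and
#: moderate enhancement in basal ganglia and midbrain/brainstem (the
#: colliculi and pituitary region accumulate Mn2+ systemically).
_BASE_ENHANCEMENT: dict[str, float] = {
    "hippocampus": 1.35,
    "ca1": 1.50,
    "dg": 1.60,
    "hypothalamus": 1.40,
    "amygdala": 1.45,
    "habenula": 1.50,
    "septum_basal_forebrain": 1.30,
    "olfactory_bulb": 1.45,
    "cerebellum": 1.30,
    "globus_pallidus": 1.35,
    "striatum": 1.10,
    "midbrain": 1.20,
    "brainstem": 1.15,
    "thalamus": 1.15,
}


def default_control_spec(**overrides) -> SubjectSpec:
    """Uptake pattern of a healthy (nonTg-like) subject."""
    spec = SubjectSpec(group="control", enhancement=dict(_BASE_ENHANCEMENT), atrophy={})
    return replace(spec, **overrides)


def default_mutant_spec(**overrides) -> SubjectSpec:
    """Tauopathy-like (rTg4510) subject: strongly reduced hippocampal and
    amygdalar uptake with the CA1/DG contrast inverted (CA1 slightly up,
    DG strongly down), increased striatal activity, ~30% hippocampal
    volume loss donated to the ventricles, and mild cortical atrophy."""
    enhancement = dict(_BASE_ENHANCEMENT)
    enhancement.update(
        {
            "hippocampus": 1.00,
            "ca1": 1.70,
            "dg": 1.05,
            "amygdala": 1.10,
            "striatum": 1.40,
        }
    )
    spec = SubjectSpec(
        group="mutant",
        enhancement=enhancement,
        atrophy={"hippocampus": 0.70, "neocortex": 0.92},
    )
    return replace(spec, **overrides)


# ----------------------------------------------------------------------
# cohort simulation
# ----------------------------------------------------------------------

def simulate_cohort(
    atlas: AtlasPhantom,
    n_per_group: int,
    control_spec: SubjectSpec | None = None,
    mutant_spec: SubjectSpec | None = None,
    master_seed: int = 0,
    out_dir: str | Path = ".",
    misalignment_bounds: MisalignmentBounds | None = None,
    write_files: bool = True,
) -> CohortManifest:
    """Simulate two cohorts of ``n_per_group`` subjects each.

    Per-subject seeds and misalignments derive deterministically from
    ``master_seed``.  Volumes, brain masks and ground-truth label maps are
    written as NIfTI under ``out_dir`` with a ``manifest.csv`` index; with
    ``write_files=False`` the rendered arrays are kept in memory on the
    manifest entries instead (key ``data``).
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    control_spec = control_spec or default_control_spec()
    mutant_spec = mutant_spec or default_mutant_spec()
    out_dir = Path(out_dir)
    if write_files:
        out_dir.mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng(master_seed)
    subjects: list[dict] = []
    for group, proto in (("control", control_spec), ("mutant", mutant_spec)):
        for i in range(n_per_group):
            mis_seed, noise_seed = master.integers(0, 2**31 - 1, size=2)
            mis = random_misalignment(
                np.random.default_rng(mis_seed),
                bounds=misalignment_bounds,
                center_mm=atlas.center_mm,
            )
            spec = replace(
                proto, group=group, misalignment=mis, seed=int(noise_seed)
            )
            volume, truth = simulate_subject(atlas, spec)
            sid = f"{group}{i + 1:02d}"
            entry = {"subject_id": sid, "group": group}
            if write_files:
                vol_path = out_dir / f"{sid}_vol.nii.gz"
                mask_path = out_dir / f"{sid}_mask.nii.gz"
                lab_path = out_dir / f"{sid}_truth.nii.gz"
                write_volume(volume, vol_path, stage="simulated")
                from .image import BrainMask

                write_mask(
                    BrainMask(mask=truth.labels > 0, affine=truth.affine), mask_path
                )
                write_labels(truth, lab_path)
                entry.update(
                    volume_path=str(vol_path),
                    mask_path=str(mask_path),
                    labels_path=str(lab_path),
                )
            else:
                entry["data"] = (volume, truth)
            entry["spec"] = spec
            subjects.append(entry)

    manifest = CohortManifest(subjects=subjects, master_seed=master_seed)
    if write_files:
        manifest_path = out_dir / "manifest.csv"
        with open(manifest_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subject_id", "group", "volume_path", "mask_path", "labels_path"])
            for s in subjects:
                w.writerow(
                    [s["subject_id"], s["group"], s["volume_path"], s["mask_path"], s["labels_path"]]
                )
        write_roi_table(atlas.roi_table, out_dir / "roi_table.csv")
        manifest.path = manifest_path
    return manifest
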