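"""End-to-end orchestration: simulate -> preprocess -> z-map -> ROI stats
-> group comparison, as a deterministic, re-entrant chain.

Every stage writes its artifacts to disk with a JSON provenance sidecar
(stage name, config hash, seed), so any stage can be re-run from the
previous stage's outputs and out-of-order invocations are refused rather
than silently accepted.  A single master seed drives every stochastic
choice (phantom noise, registration restarts); re-runs are bit-stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .groupstats import compare_cohort, comparisons_to_frame
from .image import BrainMask
from .phantom import ATLAS_ROIS
from .preprocess import (
    RegistrationOptions,
    apply_brain_mask,
    denoise,
    register_affine,
    warp_labels,
)
from .roistats import (
    group_volume_ratio,
    roi_metrics_table,
    segmented_volume,
    subregion_metrics,
)
from .zmap import (
    default_bin_edges,
    histogram_census,
    suprathreshold_fraction,
    threshold_map,
    zscore_normalize,
)

__all__ = ["PipelineConfig", "PipelineError", "ProvenanceError", "run_pipeline"]

log = logging.getLogger("memrimap")

#: metrics tested across groups, per ROI
ROI_METRICS = ("mean_supra_z", "active_volume_mm3")
SUBREGION_METRICS = (
    "rel_intensity_ca1",
    "rel_intensity_dg",
    "ca1_dg_ratio",
    "hippocampal_thickness_mm",
    "hippocampus_volume_mm3",
    "ca1_volume_mm3",
    "dg_volume_mm3",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and subject."""


class ProvenanceError(RuntimeError):
    """A stage was fed an artifact produced out of order."""


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults echo the study design
    (Z threshold 1, homoscedastic two-tailed test, alpha 0.05)."""

    atlas_template: str = ""
    atlas_labels: str = ""
    roi_table: str = ""
    manifest: str = ""
    out_dir: str = "memrimap_run"
    z_threshold: float = 1.0
    denoise_method: str = "median3d"
    denoise_radius: int = 1
    registration_metric: str = "mutual_information"
    registration_restarts: int = 3
    labels_source: str = "register"  # or "truth" (use manifest label maps)
    alpha: float = 0.05
    master_seed: int = 0
    roi_set: tuple[str, ...] = field(default_factory=lambda: tuple(ATLAS_ROIS))
    ap_coordinate_mm: float = -2.0
    lateral_offset_mm: float = 1.5

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["roi_set"] = list(d["roi_set"])
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "roi_set" in d:
            d["roi_set"] = tuple(d["roi_set"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        d = asdict(self)
        d["roi_set"] = list(d["roi_set"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:12]


def _validate_inputs(config: PipelineConfig) -> pd.DataFrame:
    for name in ("atlas_template", "atlas_labels", "roi_table", "manifest"):
        p = getattr(config, name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"{name} not found: {p!r}")
    manifest = pd.read_csv(config.manifest)
    need = {"subject_id", "group", "volume_path", "mask_path"}
    if not need <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(need)}")
    if config.labels_source == "truth" and "labels_path" not in manifest.columns:
        raise ValueError("labels_source='truth' needs a labels_path manifest column")
    for _, row in manifest.iterrows():
        for col in ("volume_path", "mask_path"):
            if not Path(row[col]).exists():
                raise FileNotFoundError(
                    f"subject {row['subject_id']}: missing {col} {row[col]}"
                )
    return manifest


def preprocess_subject(config: PipelineConfig, volume, mask, atlas_template,
                       atlas_labels, seed: int):
    """Mask, denoise and label one subject; returns (clean volume, labels)."""
    masked = apply_brain_mask(volume, mask)
    clean = denoise(masked, method=config.denoise_method, mask=mask,
                    radius=config.denoise_radius)
    if config.labels_source == "register":
        opts = RegistrationOptions(
            metric=config.registration_metric,
            restarts=config.registration_restarts,
            seed=seed,
        )
        result = register_affine(moving=atlas_template, fixed=clean, options=opts)
        labels = warp_labels(atlas_labels, result.transform, clean)
    else:
        labels = atlas_labels
    return clean, labels


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full chain and return the run directory.

    Outputs: per-subject z maps (NIfTI + sidecars), ROI and sub-region
    CSVs, group-comparison CSV, histogram census CSVs, suprathreshold
    fractions, run log, the effective config, and a plain-text report.
    """
    manifest = _validate_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    incomplete = out / "INCOMPLETE"
    incomplete.write_text("run in progress\n")

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        config.to_yaml(out / "config.yaml")
        atlas_template = mio.read_volume(config.atlas_template)
        atlas_labels = mio.read_labels(config.atlas_labels, config.roi_table)
        master = np.random.default_rng(config.master_seed)
        subject_seeds = {
            row.subject_id: int(s)
            for row, s in zip(
                manifest.itertuples(),
                master.integers(0, 2**31 - 1, size=len(manifest)),
            )
        }

        roi_records, sub_records, frac_rows = [], [], []
        zmaps_by_group: dict[str, dict] = {}
        stage = "setup"
        for row in manifest.itertuples():
            sid, group = row.subject_id, row.group
            try:
                stage = "read"
                volume = mio.read_volume(row.volume_path)
                mask = mio.read_mask(row.mask_path)
                stage = "preprocess"
                if config.labels_source == "truth":
                    atlas_for_subject = mio.read_labels(
                        row.labels_path, config.roi_table
                    )
                else:
                    atlas_for_subject = atlas_labels
                clean, labels = preprocess_subject(
                    config, volume, mask, atlas_template, atlas_for_subject,
                    seed=subject_seeds[sid],
                )
                mio.write_volume(
                    clean, out / f"{sid}_preproc.nii.gz", stage="preprocessed",
                    meta={"config_hash": config.config_hash, "seed": subject_seeds[sid]},
                )
                stage = "zmap"
                zm = zscore_normalize(clean, mask)
                frac_rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "suprathreshold_fraction": suprathreshold_fraction(
                            zm, config.z_threshold
                        ),
                        "z_threshold": config.z_threshold,
                    }
                )
                zmaps_by_group.setdefault(group, {})[sid] = zm
                zt = threshold_map(zm, config.z_threshold)
                from .image import VolumeImage

                mio.write_volume(
                    VolumeImage(values=zt.values, affine=zt.affine),
                    out / f"{sid}_zmap.nii.gz",
                    stage="zmap",
                    meta={
                        "config_hash": config.config_hash,
                        "z_threshold": config.z_threshold,
                        "brain_mean": zm.brain_mean,
                        "brain_sd": zm.brain_sd,
                    },
                )
                stage = "analyze"
                roi_records.extend(
                    roi_metrics_table(zt, labels, list(config.roi_set), sid, group)
                )
                sub_records.append(
                    subregion_metrics(
                        clean, labels, mask, sid, group,
                        ap_coordinate=config.ap_coordinate_mm,
                        lateral_offset=config.lateral_offset_mm,
                    )
                )
                log.info("subject %s done", sid)
            except Exception as exc:
                raise PipelineError(
                    f"stage {stage!r} failed for subject {sid}: {exc}"
                ) from exc

        stage = "compare"
        roi_df = pd.DataFrame([asdict(r) for r in roi_records])
        roi_df["z_threshold"] = config.z_threshold
        roi_df.to_csv(out / "roi_metrics.csv", index=False)
        sub_df = pd.DataFrame([asdict(r) for r in sub_records])
        sub_df.to_csv(out / "subregions.csv", index=False)
        pd.DataFrame(frac_rows).to_csv(out / "suprathreshold_fractions.csv", index=False)

        comparisons = []
        for metric in ROI_METRICS:
            comparisons.extend(
                compare_cohort(roi_df, metric, alpha=config.alpha)
            )
        sub_long = sub_df.melt(
            id_vars=["subject_id", "group"], var_name="metric", value_name="value"
        )
        for metric in SUBREGION_METRICS:
            tab = sub_long[sub_long["metric"] == metric].rename(
                columns={"value": metric}
            )
            tab = tab.assign(roi="hippocampal_subregions")
            comparisons.extend(compare_cohort(tab, metric, alpha=config.alpha))
        comp_df = comparisons_to_frame(comparisons)
        comp_df["z_threshold"] = config.z_threshold
        comp_df.to_csv(out / "group_comparison.csv", index=False)

        census = histogram_census(zmaps_by_group, default_bin_edges())
        census.counts.assign(z_threshold=config.z_threshold).to_csv(
            out / "histogram_census.csv", index=False
        )
        census.summary.to_csv(out / "histogram_summary.csv", index=False)

        _write_report(out, config, roi_df, sub_df, comp_df, frac_rows)
        incomplete.unlink()
        log.info("run complete: %s", out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _write_report(out, config, roi_df, sub_df, comp_df, frac_rows) -> None:
    lines = []
    lines.append("MEMRI basal-activity mapping report")
    lines.append("=" * 40)
    lines.append(f"config hash: {config.config_hash}   master seed: {config.master_seed}")
    lines.append(f"Z threshold: {config.z_threshold}   alpha: {config.alpha}")
    lines.append("")
    lines.append("Suprathreshold fraction of brain voxels (Z >= threshold):")
    frac = pd.DataFrame(frac_rows)
    for group, g in frac.groupby("group"):
        lines.append(
            f"  {group}: {100 * g['suprathreshold_fraction'].mean():.1f}% "
            f"(mean over {len(g)} subjects)"
        )
    lines.append("")
    lines.append("Per-ROI group comparisons (unpaired two-tailed t, pooled variance):")
    for _, r in comp_df.iterrows():
        star = " *" if r["significant"] else ""
        lines.append(
            f"  {r['roi']:<24s} {r['metric']:<24s} t({int(r['df'])})="
            f"{r['t_statistic']:.3f}  p={r['p_two_tailed']:.3f}{star}"
        )
    lines.append("")
    if {"hippocampus_volume_mm3"} <= set(sub_df.columns):
        ctrl = sub_df[sub_df["group"] == "control"]
        mut = sub_df[sub_df["group"] == "mutant"]
        if len(ctrl) and len(mut):
            lines.append("Segmented hippocampal volumes, mutant as % of control:")
            for col, name in (
                ("hippocampus_volume_mm3", "whole hippocampus"),
                ("ca1_volume_mm3", "dorsal CA1"),
                ("dg_volume_mm3", "dorsal DG"),
            ):
                ratio = group_volume_ratio(mut[col], ctrl[col])
                lines.append(f"  {name:<20s} {ratio:.1f}%")
    (out / "report.txt").write_text("\n".join(lines) + "\n")


def check_stage(path: str | Path, expected: str) -> None:
    """Refuse an input whose provenance sidecar names a different stage."""
    side = mio.read_sidecar(path)
    if side is None or side.get("stage") != expected:
        got = side.get("stage") if side else "none"
        raise ProvenanceError(
            f"{path}: expected an artifact of stage {expected!r}, got {got!r} — "
            "run the earlier pipeline stages first"
        )
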