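"""Simulate a two-cohort MEMRI study on the digital brain phantom.

Builds the labeled atlas phantom, renders 5 control and 5 tau-mutant
subjects (region-wise Mn2+ uptake, hippocampal atrophy, bias field,
misalignment, Rician noise) and writes NIfTI volumes plus a manifest.
"""
from pathlib import Path

import memrimap as mm
from memrimap import io as mio

out = Path("example_study")
atlas = mm.build_atlas_phantom((64, 64, 48), (0.2, 0.2, 0.25), geometry_seed=1)
mio.write_volume(atlas.template, out / "atlas_template.nii.gz", stage="atlas")
mio.write_labels(atlas.labels, out / "atlas_labels.nii.gz",
                 roi_table_path=out / "roi_table.csv", stage="atlas")

manifest = mm.simulate_cohort(atlas, n_per_group=5, master_seed=7,
                              out_dir=out / "cohort")

print(f"atlas: {atlas.template.shape} voxels at {atlas.voxel_spacing} mm")
print(f"ROIs: {len(atlas.roi_table)} labels, "
      f"hippocampus = {atlas.labels.count('hippocampus')} voxels")
for s in manifest.subjects:
    print(f"  {s['subject_id']:<10s} ({s['group']}) -> {s['volume_path']}")
print("Each subject differs in uptake, pose and noise; the mutants carry "
      "a hippocampal/amygdalar uptake deficit and ~30% hippocampal atrophy.")
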