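"""Recover a subject's pose by affine atlas registration.

A subject is rendered with a known random misalignment; mutual-information
registration estimates the atlas->subject affine, atlas labels are warped
into subject space, and the overlap with the ground truth is scored.
"""
import numpy as np

import memrimap as mm
from memrimap.preprocess import RegistrationOptions


def dice(a, b):
    return 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


atlas = mm.build_atlas_phantom((64, 64, 48), (0.2, 0.2, 0.25), geometry_seed=1)
true_mis = mm.random_misalignment(np.random.default_rng(21),
                                  center_mm=atlas.center_mm)
spec = mm.default_control_spec(seed=21, misalignment=true_mis)
volume, truth = mm.simulate_subject(atlas, spec)
mask = mm.BrainMask(mask=truth.labels > 0, affine=truth.affine)
clean = mm.denoise(mm.apply_brain_mask(volume, mask), mask=mask)

result = mm.register_affine(atlas.template, clean, RegistrationOptions(seed=22))
warped = mm.warp_labels(atlas.labels, result.transform, clean)

print(f"true translation   : {np.round(true_mis.translation, 3)} mm")
print(f"recovered translation: {np.round(result.transform.translation, 3)} mm")
print(f"metric value {result.metric_value:.4f}, converged: {result.converged}")
for roi in ("hippocampus", "amygdala", "cerebellum"):
    d = dice(warped.mask(roi), truth.mask(roi))
    print(f"  {roi:<12s} Dice vs ground truth: {d:.3f}")
print("Dice near 1 means the warped atlas labels land on the true anatomy.")
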