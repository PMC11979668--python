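"""Generate a longitudinal phantom case pair and inspect its structure.

Each case pair mimics paired pre-/mid-treatment head-and-neck MRI: bright
ellipsoidal lesions (GTVp label 1, GTVn label 2) on a textured background,
lesions shrunk at the mid timepoint, and a slightly misaligned "registered"
prior mask attached to the mid case.
"""

import numpy as np

from stagedseg import PhantomParams, make_case, save_case

params = PhantomParams(shrink_factor=0.7, prior_jitter_mm=2.0, seed=42)
pre, mid = make_case(params, "demo")

for name, case in [("pre-RT", pre), ("mid-RT", mid)]:
    ref = case.reference.labels
    print(
        f"{name}: shape {case.image.shape}, spacing {case.image.spacing} mm, "
        f"GTVp voxels {int((ref == 1).sum())}, GTVn voxels {int((ref == 2).sum())}"
    )

ratio = (mid.reference.labels == 1).sum() / (pre.reference.labels == 1).sum()
print(f"GTVp volume ratio mid/pre: {ratio:.3f} (radii x0.7 => volumes near 0.7^3 = {0.7**3:.3f})")

shift = np.array(mid.prior_mask.labels.nonzero()).mean(axis=1) - np.array(
    pre.reference.labels.nonzero()
).mean(axis=1)
print(f"prior mask centroid offset vs pre reference (voxels): {np.round(shift, 2)}")

out = save_case(mid, "scratch/example_cohort")
print(f"mid case written to {out} (image/ref/prior_image/prior_mask NIfTI files)")
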