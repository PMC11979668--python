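"""Mask-restricted sliding-window inference and the island artifact.

A model trained with mask-guided sampling only ever sees patches containing
lesions, so it learns "bright blob = tumor".  Run unrestricted over the
whole volume, it may label bright non-tumor structures far from the prior —
spurious islands.  Restricting the sliding window to the prior region
removes them by construction (windows that never run cannot predict).
"""

import numpy as np

from stagedseg import (
    PhantomParams,
    RECIPE_IMAGE_ONLY,
    StageConfig,
    count_islands,
    enumerate_patches,
    make_cohort,
    sliding_window_predict,
    train_stage,
)

pairs = make_cohort(PhantomParams(n_decoys=2), 8, seed=101)
mids = [mid for _, mid in pairs]
train, val = mids[:6], mids[6:]

# c1-style refinement stage: prior guides sampling but is NOT an input channel
cfg = StageConfig(
    recipe=RECIPE_IMAGE_ONLY, sampler="masked", prior_source="provided_prior",
    epochs=6, steps_per_epoch=50, seed=0,
)
net, _ = train_stage(cfg, train, val)

# a 16^3 window at inference makes the ROI restriction bite on this grid
# (32^3 windows each cover most of the volume and all intersect the prior)
patch = (16, 16, 16)
for case in val:
    unrestricted = sliding_window_predict(net, case, RECIPE_IMAGE_ONLY, patch=patch)
    restricted = sliding_window_predict(
        net, case, RECIPE_IMAGE_ONLY, patch=patch, roi=case.prior_mask
    )
    specs_full = enumerate_patches(case.image.shape, patch, 0.5)
    specs_roi = enumerate_patches(case.image.shape, patch, 0.5, roi=case.prior_mask)
    covered = np.zeros(case.image.shape, dtype=bool)
    for s in specs_roi:
        covered[s.slices()] = True
    print(
        f"{case.case_id}: windows {len(specs_full)} -> {len(specs_roi)} with ROI; "
        f"unrestricted islands outside prior: {count_islands(unrestricted, case.prior_mask)}; "
        f"restricted foreground voxels outside window coverage: "
        f"{int((restricted.labels[~covered] > 0).sum())}"
    )
print(
    "Any nonzero unrestricted island count reproduces the qualitative failure "
    "mode of sampling-only prior guidance.  The restricted pass runs fewer "
    "windows and, by construction, cannot emit foreground where no window ran — "
    "far-field decoys are simply never looked at."
)
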