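"""Training-patch sampling and channel stacking.

Two samplers are provided, mirroring the two strategies a staged pipeline
contrasts:

* :func:`sample_default` — the conventional foreground-oversampling rule: a
  fraction ``fg_fraction`` of patches is forced to contain reference
  foreground by centering on a uniformly drawn foreground voxel; the rest
  are uniform over all valid origins.
* :func:`sample_masked` — prior-mask-guided sampling: the patch center is a
  uniformly drawn nonzero voxel of the (binarized) prior mask, so every
  patch intersects the prior.  This concentrates training on the candidate
  region supplied by an earlier stage or an earlier timepoint.

:func:`extract_patch` crops the configured channel stack.  Image channels
are z-score normalized over the whole volume; a prior-mask channel is passed
through as raw integer labels.  Patches may extend past the volume; the
out-of-bounds region is zero-padded (i.e. mean intensity after
normalization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .caseio import CaseRecord, LabelMap

logger = logging.getLogger(__name__)

_EPS_SD = 1e-6


@dataclass(frozen=True)
class PatchSpec:
    """Axis-aligned crop: half-open voxel range [origin, origin + size)."""

    origin: tuple[int, int, int]
    size: tuple[int, int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + s) for o, s in zip(self.origin, self.size))


@dataclass(frozen=True)
class ChannelRecipe:
    """Which channels the network sees, in fixed order [image, prior_image, prior_mask]."""

    use_image: bool = True
    use_prior_image: bool = False
    use_prior_mask_channel: bool = False

    def __post_init__(self) -> None:
        if not self.use_image:
            raise ValueError("the image channel is always required")

    @property
    def n_channels(self) -> int:
        return 1 + int(self.use_prior_image) + int(self.use_prior_mask_channel)


# the three configurations studied for staged training
RECIPE_IMAGE_ONLY = ChannelRecipe()  # c1: prior used (if at all) for sampling only
RECIPE_PRIOR_MASK = ChannelRecipe(use_prior_mask_channel=True)  # c2
RECIPE_FULL_PRIOR = ChannelRecipe(use_prior_image=True, use_prior_mask_channel=True)  # c3


def _clip_origin(center: np.ndarray, size, shape) -> tuple[int, int, int]:
    """Origin of the patch centered at ``center``, clipped into bounds.

    If the patch is larger than the volume along an axis the origin goes
    negative symmetrically (handled by padding at extraction time).
    """
    origin = []
    for c, s, n in zip(center, size, shape):
        o = int(c) - s // 2
        if s <= n:
            o = min(max(o, 0), n - s)
        else:
            o = -((s - n) // 2)
        origin.append(o)
    return tuple(origin)


def _uniform_origin(rng: np.random.Generator, size, shape) -> tuple[int, int, int]:
    return tuple(
        int(rng.integers(0, max(n - s, 0) + 1)) - (0 if s <= n else (s - n) // 2)
        for s, n in zip(size, shape)
    )


def sample_default(
    case: CaseRecord,
    size: tuple[int, int, int],
    fg_fraction: float,
    rng: np.random.Generator,
) -> PatchSpec:
    """Draw one patch with probability ``fg_fraction`` of forced foreground.

    Foreground patches are centered on a uniformly chosen reference
    foreground voxel and then clipped to bounds; other patches have uniform
    origins.  If the reference has no foreground, falls back to uniform
    sampling with a logged warning.
    """
    if not (0.0 <= fg_fraction <= 1.0):
        raise ValueError(f"fg_fraction must be in [0, 1], got {fg_fraction}")
    shape = case.image.shape
    if rng.random() < fg_fraction:
        fg = np.argwhere(case.reference.labels > 0)
        if fg.size == 0:
            logger.warning(
                "case %s: foreground oversampling requested but reference is empty; "
                "drawing a uniform patch",
                case.case_id,
            )
        else:
            center = fg[rng.integers(len(fg))]
            return PatchSpec(_clip_origin(center, size, shape), tuple(size))
    return PatchSpec(_uniform_origin(rng, size, shape), tuple(size))


def sample_masked(
    case: CaseRecord,
    prior: LabelMap,
    size: tuple[int, int, int],
    rng: np.random.Generator,
) -> PatchSpec:
    """Draw one patch centered on a uniformly chosen voxel of the prior mask.

    GTVp and GTVn are merged for eligibility.  Every returned patch
    intersects the binarized prior.  An empty prior raises; the training
    caller decides whether to fall back to :func:`sample_default`.
    """
    mask_voxels = np.argwhere(prior.labels > 0)
    if mask_voxels.size == 0:
        raise ValueError(
            f"case {case.case_id}: prior mask is empty; caller should fall back to "
            "default sampling"
        )
    center = mask_voxels[rng.integers(len(mask_voxels))]
    return PatchSpec(_clip_origin(center, size, case.image.shape), tuple(size))


def _crop_padded(arr: np.ndarray, spec: PatchSpec, cval: float = 0.0) -> np.ndarray:
    """Crop with zero padding where the patch leaves the array."""
    out = np.full(spec.size, cval, dtype=arr.dtype)
    src, dst = [], []
    for o, s, n in zip(spec.origin, spec.size, arr.shape):
        lo, hi = max(o, 0), min(o + s, n)
        if lo >= hi:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - o, hi - o))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def zscore(data: np.ndarray) -> np.ndarray:
    """Per-volume z-score; degenerate (near-constant) volumes map to zero."""
    mean = float(data.mean())
    sd = float(data.std())
    if sd < _EPS_SD * max(1.0, abs(mean)):
        return np.zeros_like(data, dtype=np.float32)
    return ((data - mean) / sd).astype(np.float32)


def extract_patch(
    case: CaseRecord, spec: PatchSpec, recipe: ChannelRecipe
) -> tuple[np.ndarray, np.ndarray]:
    """Crop the input channel stack and the target labels for one patch.

    Returns ``(stack, target)`` with ``stack`` of shape ``(C, *size)`` in the
    fixed channel order [image, prior_image?, prior_mask?] and ``target`` of
    shape ``size`` (int labels).  Image channels are z-score normalized over
    the whole volume before cropping; out-of-bounds regions are zero.
    """
    if recipe.use_prior_image and case.prior_image is None:
        raise ValueError(f"case {case.case_id}: recipe needs prior_image but it is absent")
    if recipe.use_prior_mask_channel and case.prior_mask is None:
        raise ValueError(f"case {case.case_id}: recipe needs prior_mask but it is absent")

    channels = [_crop_padded(zscore(case.image.data), spec)]
    if recipe.use_prior_image:
        channels.append(_crop_padded(zscore(case.prior_image.data), spec))
    if recipe.use_prior_mask_channel:
        channels.append(
            _crop_padded(case.prior_mask.labels.astype(np.float32), spec)
        )
    target = _crop_padded(case.reference.labels, spec)
    return np.stack(channels, axis=0), target
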