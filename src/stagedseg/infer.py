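"""Gaussian-weighted sliding-window prediction, optionally mask-restricted.

A volume is tiled with overlapping patches; per-patch softmax probabilities
are blended with a separable Gaussian weight kernel (maximal at the patch
center) and the per-voxel argmax gives the label.  In masked mode only
patches whose extent intersects a region-of-interest prior are inferred;
voxels covered by no patch are emitted as background — so an inaccurate or
stale prior restricts *where* the network is consulted, and everything
outside stays empty by contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import _tensor
from .caseio import CaseRecord, LabelMap
from .model import Network
from .sampling import ChannelRecipe, PatchSpec, zscore

logger = logging.getLogger(__name__)

DEFAULT_OVERLAP = 0.5
DEFAULT_SIGMA_SCALE = 0.125
_MIN_WEIGHT = 1e-3


@dataclass
class WindowPlan:
    patches: list[PatchSpec]
    overlap: float
    weight_kernel: np.ndarray


def _axis_starts(n: int, patch: int, overlap: float) -> list[int]:
    """Start positions along one axis: spaced by ceil(patch*(1-overlap)), last clipped."""
    if patch >= n:
        return [0]
    step = max(1, math.ceil(patch * (1.0 - overlap)))
    starts = list(range(0, n - patch + 1, step))
    if starts[-1] != n - patch:
        starts.append(n - patch)
    return starts


def enumerate_patches(
    grid_shape,
    patch,
    overlap: float = DEFAULT_OVERLAP,
    roi: LabelMap | np.ndarray | None = None,
) -> list[PatchSpec]:
    """Sliding-window patch plan over a grid.

    Without a ROI, the union of patches covers the full grid.  With a ROI,
    exactly those patches whose extent intersects a nonzero (binarized) ROI
    voxel are kept.  An empty ROI raises; callers may then fall back to
    unmasked inference.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    for ax, (p, n) in enumerate(zip(patch, grid_shape)):
        if p > n:
            raise ValueError(f"patch axis {ax} ({p}) exceeds grid ({n}); pad upstream")
    mask = None
    if roi is not None:
        mask = roi.labels > 0 if isinstance(roi, LabelMap) else np.asarray(roi) > 0
        if not mask.any():
            raise ValueError("ROI is empty; fall back to unmasked inference")

    axes = [_axis_starts(n, p, overlap) for n, p in zip(grid_shape, patch)]
    specs = []
    for sx in axes[0]:
        for sy in axes[1]:
            for sz in axes[2]:
                spec = PatchSpec((sx, sy, sz), tuple(patch))
                if mask is not None and not mask[spec.slices()].any():
                    continue
                specs.append(spec)
    return specs


def gaussian_kernel(patch, sigma_scale: float = DEFAULT_SIGMA_SCALE) -> np.ndarray:
    """Separable Gaussian blending weights, max-normalized to 1, floor-clamped."""
    if sigma_scale <= 0:
        raise ValueError("sigma_scale must be > 0")
    axes = []
    for p in patch:
        center = (p - 1) / 2.0
        sigma = sigma_scale * p
        x = np.arange(p)
        axes.append(np.exp(-0.5 * ((x - center) / sigma) ** 2))
    k = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    k /= k.max()
    return np.maximum(k, _MIN_WEIGHT).astype(np.float32)


def plan_windows(
    grid_shape, patch, overlap=DEFAULT_OVERLAP, roi=None, sigma_scale=DEFAULT_SIGMA_SCALE
) -> WindowPlan:
    return WindowPlan(
        patches=enumerate_patches(grid_shape, patch, overlap, roi),
        overlap=overlap,
        weight_kernel=gaussian_kernel(patch, sigma_scale),
    )


def _channel_stack(case: CaseRecord, recipe: ChannelRecipe) -> np.ndarray:
    chans = [zscore(case.image.data)]
    if recipe.use_prior_image:
        if case.prior_image is None:
            raise ValueError(f"case {case.case_id}: recipe needs prior_image")
        chans.append(zscore(case.prior_image.data))
    if recipe.use_prior_mask_channel:
        if case.prior_mask is None:
            raise ValueError(f"case {case.case_id}: recipe needs prior_mask")
        chans.append(case.prior_mask.labels.astype(np.float32))
    return np.stack(chans, axis=0)


def sliding_window_predict(
    net: Network,
    case: CaseRecord,
    recipe: ChannelRecipe,
    patch=None,
    overlap: float = DEFAULT_OVERLAP,
    roi: LabelMap | None = None,
    sigma_scale: float = DEFAULT_SIGMA_SCALE,
    return_proba: bool = False,
):
    """Predict a label map for one case.

    Blends Gaussian-weighted softmax probabilities over the window plan and
    takes the per-voxel argmax.  With ``roi``, only intersecting patches are
    inferred and uncovered voxels are labeled background.  An empty ROI
    falls back to unmasked inference with a warning.
    """
    if recipe.n_channels != net.cfg.in_channels:
        raise ValueError(
            f"network expects {net.cfg.in_channels} channels but recipe supplies "
            f"{recipe.n_channels}"
        )
    if patch is None:
        patch = case.image.shape
    grid = case.image.shape
    if roi is not None and not (roi.labels > 0).any():
        logger.warning("case %s: ROI empty, falling back to unmasked inference", case.case_id)
        roi = None
    _tensor.clear_buffers()  # new shapes; drop stale per-layer workspaces
    plan = plan_windows(grid, patch, overlap, roi, sigma_scale)
    stack = _channel_stack(case, recipe)

    k = net.cfg.n_classes
    acc = np.zeros((k,) + tuple(grid), dtype=np.float32)
    wsum = np.zeros(grid, dtype=np.float32)
    kernel = plan.weight_kernel
    for spec in plan.patches:
        sl = spec.slices()
        x = stack[(slice(None),) + sl][None]
        proba = net.predict_proba(x)[0]
        acc[(slice(None),) + sl] += proba * kernel[None]
        wsum[sl] += kernel

    covered = wsum > 0
    labels = np.zeros(grid, dtype=np.int16)
    proba_out = np.zeros_like(acc)
    if covered.any():
        proba_out[:, covered] = acc[:, covered] / wsum[covered]
        labels[covered] = np.argmax(proba_out[:, covered], axis=0).astype(np.int16)
    out = LabelMap(labels, case.image.spacing, case.image.origin)
    if return_proba:
        return out, proba_out, covered
    return out
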