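"""Synthetic longitudinal phantom cases.

Each case pair emulates the structure of paired pre-treatment and
mid-treatment head-and-neck MRI: a smoothly varying textured background
(bias-field-like low-frequency component plus white Gaussian noise), one
bright ellipsoidal primary tumor (GTVp, label 1), a configurable number of
bright ellipsoidal nodal lesions (GTVn, label 2), and optionally bright
*decoy* blobs that look like lesions but carry no label — standing in for
non-tumor hyperintense structures.  Between the two timepoints every lesion
shrinks isotropically by ``shrink_factor`` while staying in place, and the
mid-treatment case carries the pre-treatment image and reference as a
"registered" prior, displaced by a small rigid jitter to emulate residual
misregistration.

Ellipsoids are used deliberately: their voxelized volume is analytically
predictable, which gives downstream tests an exact oracle.  Radii are
specified in mm and honored under anisotropic spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .caseio import CaseRecord, LabelMap, Volume3D

_MAX_PLACEMENT_ATTEMPTS = 200


class PhantomGenerationError(RuntimeError):
    """Lesions could not be placed without overlap; advise a larger shape."""


@dataclass(frozen=True)
class PhantomParams:
    """Study conditions for one phantom case pair.

    Radii are semi-axis ranges in mm; ``lesion_contrast`` is the additive
    intensity offset of lesions over the unit-scale background;
    ``shrink_factor`` multiplies every lesion radius at mid-treatment;
    ``prior_jitter_mm`` bounds the rigid displacement of the "registered"
    prior; ``n_decoys`` bright unlabeled blobs are kept away from lesions.
    """

    shape: tuple[int, int, int] = (48, 48, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    n_gtvn: int = 2
    gtvp_radius_range: tuple[float, float] = (6.0, 10.0)
    gtvn_radius_range: tuple[float, float] = (3.0, 5.0)
    lesion_contrast: float = 3.0
    noise_sd: float = 0.3
    shrink_factor: float = 0.7
    prior_jitter_mm: float = 2.0
    n_decoys: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.shrink_factor <= 1.0):
            raise ValueError(f"shrink_factor must lie in (0, 1], got {self.shrink_factor}")
        for name in ("gtvp_radius_range", "gtvn_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered, got {(lo, hi)}")
        if self.n_gtvn < 0 or self.n_decoys < 0:
            raise ValueError("n_gtvn and n_decoys must be >= 0")
        if self.prior_jitter_mm < 0:
            raise ValueError("prior_jitter_mm must be >= 0")


@dataclass(frozen=True)
class _Lesion:
    center_mm: np.ndarray  # (3,)
    radii_mm: np.ndarray  # (3,) semi-axes


def _voxel_coords_mm(shape, spacing) -> list[np.ndarray]:
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside the ellipsoid."""
    ax = _voxel_coords_mm(shape, spacing)
    dx = (ax[0] - center_mm[0]) / radii_mm[0]
    dy = (ax[1] - center_mm[1]) / radii_mm[1]
    dz = (ax[2] - center_mm[2]) / radii_mm[2]
    return (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    ) <= 1.0


def _place_lesions(params: PhantomParams, rng: np.random.Generator):
    """Sample non-overlapping lesions (GTVp first, then GTVn, then decoys)."""
    shape, spacing = params.shape, params.spacing
    extent = np.array(shape) * np.array(spacing)
    specs = [("gtvp", params.gtvp_radius_range)]
    specs += [("gtvn", params.gtvn_radius_range)] * params.n_gtvn
    specs += [("decoy", params.gtvn_radius_range)] * params.n_decoys

    placed: list[tuple[str, _Lesion]] = []
    occupied = np.zeros(shape, dtype=bool)
    for kind, (rlo, rhi) in specs:
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            radii = rng.uniform(rlo, rhi, size=3)
            margin = radii + np.array(spacing)  # keep one voxel clear of the border
            if np.any(extent - 2 * margin <= 0):
                continue
            center = rng.uniform(margin, extent - margin)
            mask = ellipsoid_mask(shape, spacing, center, radii)
            # one voxel of clearance between structures
            if mask.sum() == 0 or np.any(occupied & ndimage.binary_dilation(mask)):
                continue
            occupied |= mask
            placed.append((kind, _Lesion(center, radii)))
            break
        else:
            raise PhantomGenerationError(
                f"could not place a {kind} lesion without overlap after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts; use a larger shape"
            )
    return placed


def _paint_reference(params: PhantomParams, lesions, scale: float) -> np.ndarray:
    labels = np.zeros(params.shape, dtype=np.int16)
    for kind, les in lesions:
        if kind == "decoy":
            continue
        mask = ellipsoid_mask(params.shape, params.spacing, les.center_mm, les.radii_mm * scale)
        labels[mask] = 1 if kind == "gtvp" else 2
    return labels


def _render_image(
    params: PhantomParams, lesions, scale: float, background: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    img = background.copy()
    for kind, les in lesions:
        s = 1.0 if kind == "decoy" else scale
        mask = ellipsoid_mask(params.shape, params.spacing, les.center_mm, les.radii_mm * s)
        img[mask] += params.lesion_contrast
    # soften lesion edges by about half a voxel before adding acquisition noise
    img = ndimage.gaussian_filter(img, sigma=0.5)
    img += rng.normal(0.0, params.noise_sd, size=params.shape)
    return img.astype(np.float32)


def _smooth_background(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    field = rng.normal(0.0, 1.0, size=params.shape)
    field = ndimage.gaussian_filter(field, sigma=[8.0 / s for s in params.spacing])
    sd = field.std()
    if sd > 0:
        field = field / sd * 0.5
    return 1.0 + field


def _rigid_jitter(rng: np.random.Generator, jitter_mm: float) -> np.ndarray:
    if jitter_mm == 0:
        return np.zeros(3)
    direction = rng.normal(size=3)
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    return direction * rng.uniform(0.0, jitter_mm)


def make_case(params: PhantomParams, case_id: str) -> tuple[CaseRecord, CaseRecord]:
    """Generate one (pre-treatment, mid-treatment) case pair.

    The pre record has no prior fields; the mid record carries the pre image
    and reference shifted by a rigid jitter of magnitude at most
    ``prior_jitter_mm`` as its registered prior.  Same params and seed give
    bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    lesions = _place_lesions(params, rng)
    background = _smooth_background(params, rng)

    pre_img = _render_image(params, lesions, 1.0, background, rng)
    pre_ref = _paint_reference(params, lesions, 1.0)
    mid_img = _render_image(params, lesions, params.shrink_factor, background, rng)
    mid_ref = _paint_reference(params, lesions, params.shrink_factor)

    shift_mm = _rigid_jitter(rng, params.prior_jitter_mm)
    shift_vox = shift_mm / np.array(params.spacing)
    prior_img = ndimage.shift(pre_img, shift_vox, order=1, mode="nearest").astype(np.float32)
    prior_ref = ndimage.shift(pre_ref, shift_vox, order=0, mode="constant", cval=0)

    sp = params.spacing
    pre = CaseRecord(
        case_id=f"{case_id}_pre",
        image=Volume3D(pre_img, sp),
        reference=LabelMap(pre_ref, sp),
    )
    mid = CaseRecord(
        case_id=f"{case_id}_mid",
        image=Volume3D(mid_img, sp),
        reference=LabelMap(mid_ref, sp),
        prior_image=Volume3D(prior_img, sp),
        prior_mask=LabelMap(prior_ref.astype(np.int16), sp),
    )
    return pre, mid


def make_cohort(
    params: PhantomParams, n_cases: int, seed: int | None = None
) -> list[tuple[CaseRecord, CaseRecord]]:
    """Generate ``n_cases`` case pairs with per-case seeds derived from ``seed``.

    ``seed`` defaults to ``params.seed``.  Lesion sizes and positions vary
    across cases; the whole cohort is reproducible from the single seed.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    children = root.spawn(n_cases)
    cohort = []
    for i, child in enumerate(children):
        case_seed = int(child.generate_state(1)[0] % (2**31))
        case_params = replace(params, seed=case_seed)
        cohort.append(make_case(case_params, f"case{i:03d}"))
    return cohort
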