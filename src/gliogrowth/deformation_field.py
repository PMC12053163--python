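"""Dense displacement fields between serial tumor masks.

The growth of a tumor between timepoints is summarized two ways:

* a :class:`DifferentialMap` — the voxel-wise set difference of the two
  masks, +1 where tumor appeared, -1 where it vanished (segmentation
  variability), 0 elsewhere; and
* a :class:`DisplacementField` — a per-voxel 3-vector (mm, world axes)
  describing where timepoint-1 tissue moved to by timepoint 2.

The field is recovered by a demons-style iterative registration of the
Gaussian-smoothed signed distance transforms of the two masks: distance maps
turn a binary registration problem into a smooth intensity one with a
well-defined gradient everywhere near the boundary, so the classic demons
force

    u = (F - M o phi) grad(M o phi) / (|grad|^2 + (F - M o phi)^2)

is usable directly.  Updates are capped, fluid-smoothed, composed additively
and diffusion-smoothed, coarse-to-fine over a small multiresolution pyramid.
Registration runs on a crop around the union of the two masks (the field is
identically zero far from the tumor by construction), which keeps
template-size grids cheap.

Convention: the internal demons field maps fixed-image (timepoint 2) voxels
back into the moving image (timepoint 1); the returned growth field is its
negation, i.e. points in the direction of growth (T1 -> T2).  The downstream
acute-angle statistic is invariant to this sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .angular_alignment import MaskedVectorField
from .volume_io import TemplateGrid, Volume


@dataclass(frozen=True)
class RegistrationParams:
    """Demons parameters; scales are in voxels of the current level."""

    levels: int = 3
    iterations: int = 50
    sigma_image: float = 1.0      # pre-smoothing of the distance maps
    sigma_fluid: float = 1.5      # smoothing of each update (fluid-like)
    sigma_diffusion: float = 1.0  # smoothing of the composed field
    step_cap: float = 0.5         # max |update| per voxel per iteration
    convergence_tol: float = 1e-4
    support_radius: float = 5.0   # field zeroed beyond this (voxels) from union
    crop_margin: int = 8

    def __post_init__(self) -> None:
        if self.levels < 1 or self.iterations < 1:
            raise ValueError("levels and iterations must be >= 1")
        for name in ("sigma_image", "sigma_fluid", "sigma_diffusion",
                     "step_cap", "support_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DisplacementField:
    """Per-voxel growth displacement in mm, world axes, T1 -> T2."""

    grid: TemplateGrid
    vectors: np.ndarray  # (i,j,k,3) float32
    direction_convention: str = "T1->T2"

    def __post_init__(self) -> None:
        if self.vectors.shape != self.grid.shape + (3,):
            raise ValueError("vectors must have shape grid.shape + (3,)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field must be finite everywhere")

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def to_volume(self) -> Volume:
        return Volume(self.grid, self.vectors, "vector3")


@dataclass
class DifferentialMap:
    """Voxel-wise growth map: +1 new tumor, -1 lost, 0 unchanged."""

    grid: TemplateGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.all(np.isin(np.unique(v), (-1, 0, 1))):
            raise ValueError("differential map may contain only -1, 0, +1")
        self.values = v.astype(np.int8)

    @property
    def n_positive(self) -> int:
        return int((self.values == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.values == -1).sum())


def differential_map(mask_t1: Volume, mask_t2: Volume) -> DifferentialMap:
    """T21 map: +1 on mask_t2 minus mask_t1, -1 on mask_t1 minus mask_t2."""
    _check_pair(mask_t1, mask_t2)
    a = mask_t1.values.astype(np.int8)
    b = mask_t2.values.astype(np.int8)
    return DifferentialMap(mask_t1.grid, b - a)


def _check_pair(a: Volume, b: Volume) -> None:
    if a.kind != "mask" or b.kind != "mask":
        raise ValueError("both inputs must be mask volumes")
    if not a.grid.same_as(b.grid):
        raise ValueError("masks are on different grids")


def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Positive outside the mask, negative inside (voxel-isotropic units)."""
    m = mask.astype(bool)
    out = ndimage.distance_transform_edt(~m, sampling=spacing)
    inn = ndimage.distance_transform_edt(m, sampling=spacing)
    return (out - inn).astype(np.float32)


def _warp(image: np.ndarray, disp: np.ndarray, order: int = 1) -> np.ndarray:
    """Sample image at x + disp(x); disp in voxel units on image's grid."""
    idx = np.indices(image.shape, dtype=np.float32)
    coords = idx + np.moveaxis(disp, -1, 0)
    return ndimage.map_coordinates(image, coords, order=order, mode="nearest")


def _demons_level(fixed: np.ndarray, moving: np.ndarray, disp: np.ndarray,
                  params: RegistrationParams) -> tuple[np.ndarray, int, bool]:
    eps = 1e-9
    prev_cost = None
    converged = False
    iters = 0
    for iters in range(1, params.iterations + 1):
        warped = _warp(moving, disp)
        diff = fixed - warped
        grads = np.gradient(warped)
        g2 = sum(g * g for g in grads)
        denom = g2 + diff * diff + eps
        upd = np.stack([(diff * g) / denom for g in grads], axis=-1)
        mag = np.linalg.norm(upd, axis=-1, keepdims=True)
        scale = np.minimum(1.0, params.step_cap / np.maximum(mag, eps))
        upd *= scale
        if params.sigma_fluid > 0:
            for c in range(3):
                upd[..., c] = ndimage.gaussian_filter(upd[..., c],
                                                      params.sigma_fluid)
        disp = disp + upd
        if params.sigma_diffusion > 0:
            for c in range(3):
                disp[..., c] = ndimage.gaussian_filter(disp[..., c],
                                                       params.sigma_diffusion)
        cost = float(np.mean(diff * diff))
        if prev_cost is not None and prev_cost > 0:
            if abs(prev_cost - cost) / prev_cost < params.convergence_tol:
                converged = True
                break
        prev_cost = cost
    return disp, iters, converged


def _zoom_to(arr: np.ndarray, shape: tuple[int, ...], order: int = 1) -> np.ndarray:
    factors = [t / s for t, s in zip(shape, arr.shape[:3])]
    if arr.ndim == 3:
        return ndimage.zoom(arr, factors, order=order, mode="nearest",
                            grid_mode=False)
    out = np.empty(tuple(shape) + (arr.shape[3],), dtype=arr.dtype)
    for c in range(arr.shape[3]):
        out[..., c] = ndimage.zoom(arr[..., c], factors, order=order,
                                   mode="nearest", grid_mode=False)
    return out


def jacobian_determinant(disp_vox: np.ndarray) -> np.ndarray:
    """Determinant of d(x + u)/dx for a displacement in voxel units."""
    J = np.zeros(disp_vox.shape[:3] + (3, 3))
    for c in range(3):
        gx, gy, gz = np.gradient(disp_vox[..., c])
        J[..., c, 0], J[..., c, 1], J[..., c, 2] = gx, gy, gz
    J += np.eye(3)
    return np.linalg.det(J)


def register(mask_t1: Volume, mask_t2: Volume,
             params: RegistrationParams | None = None,
             ) -> tuple[DisplacementField, dict]:
    """Register mask_t1 to mask_t2 via demons on signed distance transforms.

    Returns the growth displacement field (mm, world axes, pointing T1->T2)
    and diagnostics: per-level iteration counts, warped-mask Dice against
    mask_t2 after each level, fraction of union-support voxels with positive
    Jacobian determinant, and a convergence flag.
    """
    params = params or RegistrationParams()
    _check_pair(mask_t1, mask_t2)
    if mask_t1.values.sum() == 0 or mask_t2.values.sum() == 0:
        raise ValueError("registration requires two nonempty masks")
    grid = mask_t1.grid
    union = (mask_t1.values > 0) | (mask_t2.values > 0)

    # crop to the union bounding box: the field is zero far from the tumor
    idx = np.argwhere(union)
    margin = params.crop_margin + int(np.ceil(params.support_radius))
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, grid.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    m1 = mask_t1.values[sl].astype(bool)
    m2 = mask_t2.values[sl].astype(bool)

    # distance maps in voxel units (assumes near-isotropic spacing)
    moving = _signed_distance(m1, (1.0, 1.0, 1.0))
    fixed = _signed_distance(m2, (1.0, 1.0, 1.0))
    if params.sigma_image > 0:
        moving = ndimage.gaussian_filter(moving, params.sigma_image)
        fixed = ndimage.gaussian_filter(fixed, params.sigma_image)

    shape = m1.shape
    min_dim = min(shape)
    levels = min(params.levels, max(1, int(np.log2(max(min_dim // 8, 1))) + 1))
    dice_per_level = []
    iters_per_level = []
    converged_all = True
    disp = None
    for li in range(levels):
        factor = 2 ** (levels - 1 - li)
        lshape = tuple(max(s // factor, 4) for s in shape)
        f_l = _zoom_to(fixed, lshape) if lshape != shape else fixed
        m_l = _zoom_to(moving, lshape) if lshape != shape else moving
        if disp is None:
            disp = np.zeros(lshape + (3,), dtype=np.float32)
        else:
            prev_shape = disp.shape[:3]
            disp = _zoom_to(disp, lshape)
            disp *= np.array([ls / ps for ls, ps in zip(lshape, prev_shape)],
                             dtype=np.float32)
        # demons operates in the level's voxel units; distances stay in
        # full-resolution voxels, which only rescales the force uniformly
        disp, iters, conv = _demons_level(f_l, m_l, disp, params)
        iters_per_level.append(iters)
        converged_all &= conv
        # diagnostic dice at this level
        full_disp = _zoom_to(disp, shape)
        full_disp *= np.array([s / ls for s, ls in zip(shape, lshape)],
                              dtype=np.float32)
        warped_m1 = _warp(m1.astype(np.float32), full_disp) > 0.5
        inter = np.logical_and(warped_m1, m2).sum()
        dice_per_level.append(
            float(2 * inter / max(warped_m1.sum() + m2.sum(), 1)))
    disp = full_disp  # full-resolution field, fixed(T2)-frame, points T2->T1

    growth_vox = -disp  # growth direction T1 -> T2

    # zero beyond the support radius around the union mask
    dist_out = ndimage.distance_transform_edt(~((m1 | m2)))
    growth_vox[dist_out > params.support_radius] = 0.0

    jac = jacobian_determinant(disp)
    support = m1 | m2
    jac_pos = float((jac[support] > 0).mean()) if support.any() else 1.0

    # embed into the full grid and convert voxel offsets to world-axis mm
    vec_full = np.zeros(grid.shape + (3,), dtype=np.float32)
    vec_full[sl] = growth_vox
    A = grid.affine[:3, :3]
    vec_full = (vec_full.reshape(-1, 3) @ A.T).reshape(grid.shape + (3,))
    vec_full = vec_full.astype(np.float32)

    diagnostics = {
        "dice_after": dice_per_level[-1],
        "dice_per_level": dice_per_level,
        "iterations_used": iters_per_level,
        "jacobian_positive_fraction": jac_pos,
        "converged": bool(converged_all),
        "levels": levels,
    }
    return DisplacementField(grid, vec_full), diagnostics


def growth_vectors(field: DisplacementField, support: Volume,
                   min_magnitude: float = 0.2) -> MaskedVectorField:
    """Restrict a displacement field to supported, non-negligible vectors.

    Vectors are kept where the support mask is 1 and |v| >= min_magnitude
    (mm); sub-threshold displacements carry no meaningful direction and are
    flagged invalid before any angle computation.
    """
    if support.kind != "mask":
        raise ValueError("support must be a mask volume")
    if not field.grid.same_as(support.grid):
        raise ValueError("field and support are on different grids")
    mag = field.magnitude()
    valid = (support.values > 0) & (mag >= min_magnitude)
    return MaskedVectorField(field.grid, field.vectors, valid)


def angle_support(mask_t1: Volume, diff: DifferentialMap,
                  mode: str = "union") -> Volume:
    """Support mask for angle analysis.

    ``union``: T1 mask plus the +1 growth region (default);
    ``t21``: the +1 growth region only.
    """
    if mode == "t21":
        vals = (diff.values == 1).astype(np.uint8)
    elif mode == "union":
        vals = ((mask_t1.values > 0) | (diff.values == 1)).astype(np.uint8)
    else:
        raise ValueError("support mode must be 'union' or 't21'")
    return Volume(mask_t1.grid, vals, "mask")
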