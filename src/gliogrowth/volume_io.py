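"""Volumetric I/O, grid conventions, harmonization and mirroring.

Every array in this package lives on a :class:`TemplateGrid` in a canonical
right-anterior-superior (RAS) orientation: indices are 0-based, world
coordinates in mm come from the grid's voxel->world affine.  Files are
reoriented to this convention at read time, so downstream modules never see
storage-order differences.  Vector-valued volumes (4-D, three components in
the last axis) carry their components in *world* (RAS) axes, which makes
axis reordering a pure index permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: world-coordinate agreement tolerance (mm) for grid alignment checks;
#: far below the 1 mm voxel size, so it catches real misregistration.
ALIGNMENT_TOL_MM = 0.1

#: threshold for binarizing probabilistic segmentations (majority rule)
PRESENCE_THRESHOLD = 0.5


class VolumeFormatError(ValueError):
    """Payload is not a 3-D scalar or 3-component 4-D volume."""


class HarmonizationError(ValueError):
    """Grids cannot be harmonized by truncation alone."""


class MirrorError(ValueError):
    """Grid is not symmetric about the requested midsagittal plane."""


@dataclass(frozen=True)
class TemplateGrid:
    """Common analysis space: voxel counts plus a voxel->world affine.

    The default analysis grid is 181 x 217 x 181 voxels at 1 mm^3, the MR
    template space all masks are assumed to share; the companion atlas grid
    (182 x 218 x 182) holds one extra trailing voxel per axis whose world
    coordinate falls outside the MR bounds.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if np.any(self.spacing_from(aff) <= 0):
            raise ValueError("voxel spacing must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", aff)

    @staticmethod
    def spacing_from(affine: np.ndarray) -> np.ndarray:
        return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm, one per grid axis."""
        return self.spacing_from(self.affine)

    @property
    def origin(self) -> np.ndarray:
        return self.affine[:3, 3].copy()

    @classmethod
    def mr_default(cls) -> "TemplateGrid":
        """181 x 217 x 181 analysis grid at 1 mm, MNI-style origin."""
        return cls.from_origin((181, 217, 181), (1.0, 1.0, 1.0),
                               (-90.0, -126.0, -72.0))

    @classmethod
    def atlas_default(cls) -> "TemplateGrid":
        """182 x 218 x 182 atlas grid: one extra trailing voxel per axis."""
        return cls.from_origin((182, 218, 182), (1.0, 1.0, 1.0),
                               (-90.0, -126.0, -72.0))

    @classmethod
    def from_origin(cls, shape, spacing, origin) -> "TemplateGrid":
        aff = np.eye(4)
        aff[:3, :3] = np.diag(spacing)
        aff[:3, 3] = origin
        return cls(tuple(shape), aff)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) world coordinates of the first and last voxel centers."""
        corners = np.array([[0, 0, 0], [s - 1 for s in self.shape]])
        w = self.voxel_to_world(corners)
        return w.min(axis=0), w.max(axis=0)

    def same_as(self, other: "TemplateGrid", tol: float = ALIGNMENT_TOL_MM) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.affine, other.affine, atol=tol))

    def __eq__(self, other) -> bool:  # affine is an array: custom equality
        return isinstance(other, TemplateGrid) and self.same_as(other)

    def __hash__(self) -> int:
        return hash(self.shape)


@dataclass
class Volume:
    """An array on a TemplateGrid: binary mask, scalar, or 3-vector field."""

    grid: TemplateGrid
    values: np.ndarray
    kind: str  # {"mask", "scalar", "vector3"}

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if self.kind == "vector3":
            if v.ndim != 4 or v.shape[3] != 3:
                raise VolumeFormatError("vector3 volume needs shape (i,j,k,3)")
            if v.shape[:3] != self.grid.shape:
                raise ValueError("values do not match grid shape")
        else:
            if v.ndim != 3:
                raise VolumeFormatError(f"{self.kind} volume must be 3-D")
            if v.shape != self.grid.shape:
                raise ValueError("values do not match grid shape")
        if self.kind == "mask":
            u = np.unique(v)
            if not np.all(np.isin(u, (0, 1))):
                raise ValueError("mask volumes may contain only 0 and 1")
            v = v.astype(np.uint8)
        self.values = v

    def copy(self) -> "Volume":
        return Volume(self.grid, self.values.copy(), self.kind)


def _classify(values: np.ndarray) -> str:
    if values.ndim == 4:
        return "vector3"
    u = np.unique(values)
    return "mask" if u.size and np.all(np.isin(u, (0, 1))) else "scalar"


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 volume and normalize it to canonical RAS orientation.

    Only axis reorderings/flips are applied — never resampling.  3-D payloads
    become ``mask`` (if strictly binary) or ``scalar`` volumes; 4-D payloads
    must carry exactly three components in the last axis (``vector3``).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    if img.ndim not in (3, 4) or (img.ndim == 4 and img.shape[3] != 3):
        raise VolumeFormatError(
            f"{path}: expected 3-D or (i,j,k,3) payload, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    values = np.asarray(img.dataobj)
    grid = TemplateGrid(values.shape[:3], np.asarray(img.affine))
    return Volume(grid, values, _classify(values))


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a Volume as NIfTI-1 (.nii or .nii.gz)."""
    path = Path(path)
    dtype = np.uint8 if vol.kind == "mask" else np.float32
    img = nib.Nifti1Image(vol.values.astype(dtype), vol.grid.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def harmonize_to_grid(vol: Volume, target: TemplateGrid) -> Volume:
    """Truncate a volume to a target grid that it contains.

    Voxels are dropped exactly when their world coordinates fall outside the
    target's bounds; every retained voxel keeps its world coordinate (checked
    to ``ALIGNMENT_TOL_MM``), so retained values are bit-identical.  This is
    how the one-voxel-larger atlas grid is reduced to the MR analysis grid.
    No resampling: a spacing mismatch is an error.
    """
    if vol.grid.same_as(target):
        return vol
    if not np.allclose(vol.grid.spacing, target.spacing, atol=1e-6):
        raise HarmonizationError(
            f"spacing mismatch {vol.grid.spacing} vs {target.spacing}; "
            "resampling is out of scope")
    if not np.allclose(vol.grid.affine[:3, :3], target.affine[:3, :3],
                       atol=1e-6):
        raise HarmonizationError("grid axes differ beyond a translation")
    # integral voxel offset of the target origin inside the source grid
    off_f = np.linalg.solve(vol.grid.affine[:3, :3],
                            target.origin - vol.grid.origin)
    off = np.round(off_f).astype(int)
    resid = np.abs((off_f - off) * vol.grid.spacing)
    if np.any(resid > ALIGNMENT_TOL_MM):
        raise HarmonizationError(
            f"grids misaligned by {resid} mm (> {ALIGNMENT_TOL_MM} mm)")
    hi = off + np.array(target.shape)
    if np.any(off < 0) or np.any(hi > np.array(vol.grid.shape)):
        raise HarmonizationError(
            "target grid extends beyond the source volume; only truncation "
            "is supported")
    sl = tuple(slice(o, h) for o, h in zip(off, hi))
    values = vol.values[sl] if vol.kind != "vector3" else vol.values[sl + (slice(None),)]
    return Volume(target, values.copy(), vol.kind)


def mirror_to_left(vol: Volume, midsagittal_x: float = 0.0) -> Volume:
    """Reflect a volume across the midsagittal plane (world x = const).

    Used to fold right-hemisphere tumors onto the left so the cohort shares
    one hemisphere.  Masks are reflected voxel-for-voxel (count preserved);
    for vector fields the left-right (world x) component is negated as well.
    The grid must be symmetric about the plane to within half a voxel.
    """
    if vol.kind not in ("mask", "vector3"):
        raise MirrorError("mirroring is defined for mask and vector3 volumes")
    # world x must map to grid axis 0 (canonical RAS)
    ax_dir = np.abs(vol.grid.affine[:3, 0])
    if ax_dir[0] < max(ax_dir[1], ax_dir[2]):
        raise MirrorError("grid axis 0 is not the left-right axis")
    n = vol.grid.shape[0]
    x0 = vol.grid.voxel_to_world([0, 0, 0])[0]
    x1 = vol.grid.voxel_to_world([n - 1, 0, 0])[0]
    center = 0.5 * (x0 + x1)
    if abs(center - midsagittal_x) > 0.5 * vol.grid.spacing[0]:
        raise MirrorError(
            f"grid center x={center:.2f} mm is not on the midsagittal plane "
            f"x={midsagittal_x:.2f} mm")
    values = vol.values[::-1].copy()
    if vol.kind == "vector3":
        values[..., 0] = -values[..., 0]
    return Volume(vol.grid, values, vol.kind)


def tumor_presence(vol: Volume) -> Volume:
    """Binarize a (possibly probabilistic) segmentation at 0.5."""
    if vol.kind == "mask":
        return vol.copy()
    if vol.kind != "scalar":
        raise ValueError("presence is defined for scalar/mask volumes")
    return Volume(vol.grid, (vol.values > PRESENCE_THRESHOLD).astype(np.uint8),
                  "mask")


def hemisphere_of(mask: Volume, midsagittal_x: float = 0.0) -> str:
    """'left' or 'right' by the mask centroid's world x (RAS: +x is right)."""
    idx = np.argwhere(mask.values > 0)
    if idx.size == 0:
        raise ValueError("empty mask has no hemisphere")
    cx = mask.grid.voxel_to_world(idx.mean(axis=0))[0]
    return "right" if cx > midsagittal_x else "left"
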