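"""Voxel-wise glioma frequency maps across the cohort and slice rendering.

A frequency map counts, per voxel, how many patients' masks cover it at a
given timepoint; rendered on an anatomical background with a red-to-yellow
colormap whose colorbar reads in number of patients, these are the cohort
heat maps.  A small quiver utility draws a 2-D slice of a displacement
field over the tumor outline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volume_io import TemplateGrid, Volume


@dataclass
class FrequencyMap:
    grid: TemplateGrid
    counts: np.ndarray  # int, patients per voxel
    timepoint: str = "T1"
    region: str = "all"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != self.grid.shape:
            raise ValueError("counts must match grid shape")
        if c.min() < 0:
            raise ValueError("counts must be non-negative")
        self.counts = c.astype(np.int32)

    @property
    def n_max(self) -> int:
        return int(self.counts.max())

    def to_volume(self) -> Volume:
        return Volume(self.grid, self.counts.astype(np.float32), "scalar")


def frequency_map(masks: Sequence[Volume], timepoint: str = "T1",
                  region: str = "all") -> FrequencyMap:
    """Per-voxel sum of binary masks over patients."""
    masks = list(masks)
    if not masks:
        raise ValueError("frequency_map needs at least one mask")
    grid = masks[0].grid
    counts = np.zeros(grid.shape, dtype=np.int32)
    for m in masks:
        if m.kind != "mask":
            raise ValueError("frequency_map takes mask volumes")
        if not m.grid.same_as(grid):
            raise ValueError("masks are on different grids")
        counts += m.values
    return FrequencyMap(grid, counts, timepoint=timepoint, region=region)


def _slice2d(arr: np.ndarray, axis: int, index: int) -> np.ndarray:
    if not 0 <= index < arr.shape[axis]:
        raise ValueError(f"slice index {index} out of range on axis {axis}")
    return np.take(arr, index, axis=axis)


def render_overlay(fmap: FrequencyMap, background: Volume | None,
                   axis: int, index: int, path) -> None:
    """One slice: grayscale background, red-to-yellow patient-count overlay.

    Deterministic output: identical inputs produce identical image files.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colors

    if background is not None and not background.grid.same_as(fmap.grid):
        raise ValueError("background and frequency map grids differ")
    counts = _slice2d(fmap.counts, axis, index).T
    fig, ax = plt.subplots(figsize=(5, 5))
    if background is not None:
        bg = _slice2d(background.values, axis, index).T
        ax.imshow(bg, cmap="gray", origin="lower")
    n_max = max(fmap.n_max, 1)
    overlay = np.ma.masked_where(counts == 0, counts)
    im = ax.imshow(overlay, cmap="autumn", origin="lower",
                   norm=colors.Normalize(vmin=1, vmax=n_max),
                   interpolation="nearest")
    cb = fig.colorbar(im, ax=ax, fraction=0.046)
    cb.set_label("patients (N)")
    cb.set_ticks(np.unique(np.linspace(1, n_max, min(n_max, 8)).astype(int)))
    ax.set_title(f"{fmap.region} {fmap.timepoint} (axis {axis}, slice {index})",
                 fontsize=9)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "gliogrowth"})
    plt.close(fig)


def render_quiver(vectors: np.ndarray, mask_t1: Volume, outline: Volume | None,
                  axis: int, index: int, path, stride: int = 2) -> None:
    """2-D quiver of a displacement-field slice over the tumor outline."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if vectors.shape[:3] != mask_t1.grid.shape:
        raise ValueError("vector array does not match the mask grid")
    vsl = _slice2d(vectors, axis, index)
    in_plane = [c for c in range(3) if c != axis]
    u = vsl[..., in_plane[0]].T
    v = vsl[..., in_plane[1]].T
    fig, ax = plt.subplots(figsize=(5, 5))
    m1 = _slice2d(mask_t1.values, axis, index).T
    ax.imshow(np.ma.masked_where(m1 == 0, m1), cmap="Oranges", origin="lower",
              vmin=0, vmax=1, alpha=0.6, interpolation="nearest")
    if outline is not None:
        o = _slice2d(outline.values, axis, index).T
        ax.contour(o, levels=[0.5], colors="white", linewidths=0.8)
    yy, xx = np.mgrid[0:u.shape[0]:stride, 0:u.shape[1]:stride]
    ax.quiver(xx, yy, u[::stride, ::stride], v[::stride, ::stride],
              color="tab:blue", scale_units="xy", scale=1.0, width=0.004)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "gliogrowth"})
    plt.close(fig)
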