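"""Voxel-wise angular alignment of growth vectors with fiber orientations.

The central statistic: at every voxel where both a tumor growth vector and a
principal diffusion eigenvector are defined, the acute angle

    theta = arccos(|v . e| / (|v| |e|))  in [0, 90] degrees

measures how closely local growth follows the white-matter fiber axis.  The
eigenvector is an axis (sign-ambiguous), so the dot product is folded by the
absolute value; every quantity here is invariant to sign flips of either
argument.

Under isotropic growth — direction uniform on the sphere — the acute angle to
a fixed axis has density proportional to sin(theta) on [0, 90] degrees, hence

    P(theta < t) = 1 - cos(t),

giving p0 = 1 - cos(20 deg) ~= 0.0603 for the conventional 20-degree
alignment band.  The observed proportion h of pooled voxel angles below the
threshold is compared with p0 by an exact binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .volume_io import TemplateGrid, Volume

DEFAULT_THRESHOLD_DEG = 20.0
DEFAULT_N_BINS = 18  # 5-degree bins: keeps the 0-20 degree band bin-aligned


@dataclass
class EigenvectorField:
    """Sign-ambiguous unit 3-vector per voxel plus a validity mask.

    Vectors are re-normalized at construction; voxels with zero or non-finite
    vectors (atlas background) are marked invalid.
    """

    grid: TemplateGrid
    vectors: np.ndarray  # (i,j,k,3), world axes
    valid: np.ndarray    # (i,j,k) bool

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float32)
        if v.ndim != 4 or v.shape[3] != 3 or v.shape[:3] != self.grid.shape:
            raise ValueError("vectors must have shape grid.shape + (3,)")
        valid = np.asarray(self.valid, dtype=bool)
        if valid.shape != self.grid.shape:
            raise ValueError("valid mask must match grid shape")
        norms = np.linalg.norm(v, axis=-1)
        ok = np.isfinite(norms) & (norms > 1e-8)
        valid = valid & ok
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(ok[..., None], v / np.where(ok, norms, 1.0)[..., None], 0.0)
        self.vectors = v
        self.valid = valid

    @classmethod
    def from_volume(cls, vol: Volume,
                    valid: np.ndarray | None = None) -> "EigenvectorField":
        if vol.kind != "vector3":
            raise ValueError("eigenvector field requires a vector3 volume")
        if valid is None:
            valid = np.ones(vol.grid.shape, dtype=bool)
        return cls(vol.grid, vol.values, valid)


@dataclass
class MaskedVectorField:
    """A vector field with an explicit per-voxel validity mask (mm units)."""

    grid: TemplateGrid
    vectors: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.vectors.shape[:3] != self.grid.shape or self.vectors.shape[3] != 3:
            raise ValueError("vectors must have shape grid.shape + (3,)")
        self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class AngleMap:
    """Acute angle in degrees per voxel; NaN where undefined."""

    grid: TemplateGrid
    theta: np.ndarray
    transform_tag: str = "raw_theta"

    def __post_init__(self) -> None:
        t = np.asarray(self.theta, dtype=np.float32)
        finite = t[np.isfinite(t)]
        if finite.size and (finite.min() < -1e-4 or finite.max() > 90 + 1e-4):
            raise ValueError("angles must lie in [0, 90] degrees")
        self.theta = t

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.theta)

    def samples(self) -> np.ndarray:
        """Flat array of the finite angles."""
        return self.theta[self.valid].astype(float)


@dataclass
class AlignmentTestResult:
    n_total: int
    n_below: int
    h: float
    p0: float
    p_value: float
    threshold_deg: float
    alternative: str = "two-sided"

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total, "n_below": self.n_below,
            "h": self.h, "p0": self.p0, "p_value": self.p_value,
            "threshold_deg": self.threshold_deg,
            "alternative": self.alternative,
        }


def acute_angle(v: Sequence[float], e: Sequence[float]) -> float:
    """Acute angle (degrees) between two directions, folded to [0, 90].

    Invariant to rescaling and to sign flips of either argument; the
    eigenvector's sign is physically meaningless.
    """
    v = np.asarray(v, dtype=float)
    e = np.asarray(e, dtype=float)
    nv, ne = np.linalg.norm(v), np.linalg.norm(e)
    if nv < 1e-12 or ne < 1e-12:
        raise ValueError("acute_angle requires nonzero vectors")
    c = abs(float(np.dot(v, e))) / (nv * ne)
    return float(np.degrees(np.arccos(min(c, 1.0))))


def angle_map(growth: MaskedVectorField, eig: EigenvectorField) -> AngleMap:
    """Voxel-wise acute angles where both fields are valid."""
    if not growth.grid.same_as(eig.grid):
        raise ValueError("growth and eigenvector fields are on different grids")
    both = growth.valid & eig.valid
    theta = np.full(growth.grid.shape, np.nan, dtype=np.float32)
    if both.any():
        g = growth.vectors[both].astype(np.float64)
        e = eig.vectors[both].astype(np.float64)
        gn = np.linalg.norm(g, axis=1)
        ok = gn > 1e-12
        cosv = np.zeros(len(g))
        cosv[ok] = np.abs(np.einsum("ij,ij->i", g[ok], e[ok])) / gn[ok]
        vals = np.degrees(np.arccos(np.clip(cosv, 0.0, 1.0)))
        vals[~ok] = np.nan
        theta[both] = vals
    return AngleMap(growth.grid, theta)


def isotropic_p_below(threshold_deg: float) -> float:
    """P(acute angle < t) for a uniformly random 3-D direction: 1 - cos t."""
    if not 0.0 <= threshold_deg <= 90.0:
        raise ValueError("threshold must be in [0, 90] degrees")
    return float(1.0 - np.cos(np.deg2rad(threshold_deg)))


def isotropic_density(theta_deg):
    """Acute-angle density (per degree) under isotropic growth.

    f(theta) = (pi/180) sin(theta), theta in [0, 90] degrees; integrates to 1.
    """
    t = np.asarray(theta_deg, dtype=float)
    if np.any(t < 0) or np.any(t > 90):
        raise ValueError("theta must be in [0, 90] degrees")
    out = (np.pi / 180.0) * np.sin(np.deg2rad(t))
    return float(out) if np.isscalar(theta_deg) else out


def alignment_test(angles: np.ndarray,
                   threshold_deg: float = DEFAULT_THRESHOLD_DEG,
                   null_p: float | None = None,
                   alternative: str = "two-sided") -> AlignmentTestResult:
    """Exact binomial test of the below-threshold proportion vs the null.

    Pools voxel angles as independent trials: n_below successes out of
    n_total, against ``null_p`` (defaults to the analytic isotropic
    probability at the threshold).
    """
    angles = np.asarray(angles, dtype=float)
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        raise ValueError("alignment_test needs at least one finite angle")
    if null_p is None:
        null_p = isotropic_p_below(threshold_deg)
    n_total = int(angles.size)
    n_below = int((angles < threshold_deg).sum())
    res = stats.binomtest(n_below, n_total, null_p, alternative=alternative)
    return AlignmentTestResult(n_total=n_total, n_below=n_below,
                               h=n_below / n_total, p0=float(null_p),
                               p_value=float(res.pvalue),
                               threshold_deg=float(threshold_deg),
                               alternative=alternative)


class AngleAggregator:
    """Streaming voxel-wise mean of angle maps across patients.

    At each voxel only patients with tumor presence there and a finite angle
    contribute, keeping the average specific to tumor growth.  Also pools the
    flat angle samples per region for histograms and tests.
    """

    def __init__(self, grid: TemplateGrid):
        self.grid = grid
        self._sum = np.zeros(grid.shape, dtype=np.float64)
        self._count = np.zeros(grid.shape, dtype=np.int32)
        self.pooled: dict[str, list[np.ndarray]] = {}

    def add(self, amap: AngleMap, presence: Volume, region: str) -> None:
        if not amap.grid.same_as(self.grid) or not presence.grid.same_as(self.grid):
            raise ValueError("angle map / presence grid mismatch")
        use = amap.valid & (presence.values > 0)
        self._sum[use] += amap.theta[use]
        self._count[use] += 1
        self.pooled.setdefault(region, []).append(amap.theta[use].astype(float))

    def mean_map(self) -> AngleMap:
        theta = np.full(self.grid.shape, np.nan, dtype=np.float32)
        has = self._count > 0
        theta[has] = (self._sum[has] / self._count[has]).astype(np.float32)
        return AngleMap(self.grid, theta)

    def region_samples(self) -> dict[str, np.ndarray]:
        return {r: (np.concatenate(chunks) if chunks else np.empty(0))
                for r, chunks in self.pooled.items()}

    def all_samples(self) -> np.ndarray:
        samples = self.region_samples()
        if not samples:
            return np.empty(0)
        return np.concatenate(list(samples.values()))


def aggregate_angles(per_patient_maps: Iterable[AngleMap],
                     presence: Iterable[Volume],
                     regions: Iterable[str] | None = None,
                     ) -> tuple[AngleMap, dict[str, np.ndarray]]:
    """Average angle maps across patients and pool per-region samples.

    Per voxel, the mean runs over patients with tumor presence and a finite
    angle there; voxels with no contributing patient stay invalid.
    """
    maps = list(per_patient_maps)
    pres = list(presence)
    if regions is None:
        regs = ["all"] * len(maps)
    else:
        regs = list(regions)
    if not (len(maps) == len(pres) == len(regs)):
        raise ValueError("maps, presence and regions must have equal length")
    if not maps:
        raise ValueError("no angle maps to aggregate")
    agg = AngleAggregator(maps[0].grid)
    for m, p, r in zip(maps, pres, regs):
        agg.add(m, p, r)
    return agg.mean_map(), agg.region_samples()


@dataclass
class AngleHistogram:
    edges: np.ndarray
    density: np.ndarray
    analytic: np.ndarray  # isotropic density at bin centers
    n: int
    threshold_deg: float = DEFAULT_THRESHOLD_DEG

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def mode_bin(self) -> tuple[float, float]:
        i = int(np.argmax(self.density))
        return float(self.edges[i]), float(self.edges[i + 1])


def angle_histogram(angles: np.ndarray,
                    n_bins: int = DEFAULT_N_BINS,
                    threshold_deg: float = DEFAULT_THRESHOLD_DEG) -> AngleHistogram:
    """Density-normalized histogram of acute angles on [0, 90] degrees."""
    angles = np.asarray(angles, dtype=float)
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        raise ValueError("angle_histogram needs at least one angle")
    density, edges = np.histogram(angles, bins=n_bins, range=(0.0, 90.0),
                                  density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AngleHistogram(edges=edges, density=density,
                          analytic=isotropic_density(centers),
                          n=int(angles.size), threshold_deg=threshold_deg)


def plot_angle_histogram(hist: AngleHistogram, path, title: str = "") -> None:
    """Histogram with the analytic isotropic curve and the 0-20 degree band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(hist.centers, hist.density,
           width=np.diff(hist.edges), color="#79a7c7",
           edgecolor="white", label=f"observed (n={hist.n})")
    tt = np.linspace(0, 90, 361)
    ax.plot(tt, isotropic_density(tt), "k:", lw=1.5, label="isotropic null")
    ax.axvspan(0, hist.threshold_deg, color="red", alpha=0.12,
               label=f"alignment band (<{hist.threshold_deg:g}°)")
    ax.set_xlabel("acute angle θ (degrees)")
    ax.set_ylabel("probability density (1/°)")
    ax.set_xlim(0, 90)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
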