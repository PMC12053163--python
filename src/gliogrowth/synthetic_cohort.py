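"""Synthetic two-timepoint tumor cohorts over known fiber fields.

No patient imaging can be redistributed, so every downstream stage is
exercised on simulated data with known ground truth: a fiber (principal
eigenvector) field with a chosen geometry, and tumors grown from small seed
balls by stochastic boundary accretion whose direction preference is
controlled.  A regime growing *along* the fiber axis must be recovered as an
excess of small growth-fiber angles, one growing *perpendicular* to it as a
deficit with the angle histogram piling up near 90 degrees, and an isotropic
regime as agreement with the analytic null — which is exactly what the
pipeline tests.

Growth model: per step, every voxel adjacent to the mask is accreted with
probability ``min(1, magnitude * w)`` where the weight ``w`` depends on the
angle psi between the local accretion direction — the outward surface normal
of the current mask, estimated as the negated gradient of the Gaussian-
smoothed mask indicator — and the regime's preferred axis:

    isotropic            w = 1
    along_fiber          w = cos^2 psi   (sign-folded; axis, not direction)
    perpendicular_fiber  w = sin^2 psi
    toward_target        w = ((1 + cos psi) / 2)^2   (signed: attraction)

Angular jitter of SD ``noise_deg`` is added to psi per candidate.  This is
deliberately not a biophysical (reaction-diffusion) model: it is a seedable
generator of controllable anisotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .angular_alignment import EigenvectorField
from .volume_io import TemplateGrid, Volume, write_volume

REGIONS = ("allocortex", "mesocortex", "isocortex")

#: Named left-hemisphere bounding boxes (world mm, RAS) standing in for the
#: temporomesial cortex, insula, and superior frontal gyrus.  Anatomy is
#: irrelevant to the statistics; only the grouping matters.
REGION_BOXES: dict[str, tuple[tuple[float, float], ...]] = {
    "allocortex": ((-36.0, -20.0), (-25.0, 5.0), (-30.0, -10.0)),
    "mesocortex": ((-42.0, -26.0), (-8.0, 20.0), (-4.0, 14.0)),
    "isocortex": ((-28.0, -8.0), (8.0, 44.0), (32.0, 60.0)),
}

#: study-condition defaults for cohort generation
DEFAULT_N_PER_REGION = 10
DEFAULT_SEED_RADIUS_VOX = (4.0, 6.0)
DEFAULT_STEPS = (20, 60)
DEFAULT_MAGNITUDE_MM = 0.3
DEFAULT_NOISE_DEG = 10.0
DEFAULT_INTERVAL_DAYS = (14, 1500)  # inclusion floor of two weeks
_BASE_DATE = date(2020, 1, 1)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class FiberPattern:
    """Geometry of a synthetic principal-eigenvector field."""

    kind: str  # {uniform, radial, concentric, crossing}
    direction: tuple[float, float, float] | None = None
    center: tuple[float, float, float] | None = None
    validity_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "radial", "concentric", "crossing"):
            raise ConfigurationError(f"unknown fiber pattern kind {self.kind!r}")
        if self.kind in ("uniform", "crossing"):
            if self.direction is None or np.linalg.norm(self.direction) < 1e-12:
                raise ConfigurationError(f"{self.kind} pattern needs a nonzero direction")
        if self.kind in ("radial", "concentric") and self.center is None:
            raise ConfigurationError(f"{self.kind} pattern needs a center (world mm)")
        if not 0.0 <= self.validity_fraction <= 1.0:
            raise ConfigurationError("validity_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GrowthRegime:
    """Direction preference and step schedule for boundary accretion."""

    mode: str  # {isotropic, along_fiber, perpendicular_fiber, toward_target}
    magnitude: float = DEFAULT_MAGNITUDE_MM  # mm expected boundary advance/step
    steps: int = 40
    target: tuple[float, float, float] | None = None
    noise_deg: float = DEFAULT_NOISE_DEG

    def __post_init__(self) -> None:
        if self.mode not in ("isotropic", "along_fiber", "perpendicular_fiber",
                             "toward_target"):
            raise ConfigurationError(f"unknown growth mode {self.mode!r}")
        if self.magnitude <= 0:
            raise ConfigurationError("magnitude must be positive")
        if self.steps < 0:
            raise ConfigurationError("steps must be non-negative")
        if self.noise_deg < 0:
            raise ConfigurationError("noise_deg must be non-negative")
        if self.mode == "toward_target" and self.target is None:
            raise ConfigurationError("toward_target regime needs a target")


@dataclass
class SyntheticPatient:
    patient_id: str
    region: str
    mask_t1: Volume
    mask_t2: Volume
    interval_days: int
    true_regime: GrowthRegime
    seed: int
    hemisphere: str = "left"
    date_t1: date = _BASE_DATE

    @property
    def date_t2(self) -> date:
        return self.date_t1 + timedelta(days=int(self.interval_days))


def make_fiber_field(grid: TemplateGrid, pattern: FiberPattern,
                     seed: int = 0) -> EigenvectorField:
    """Generate a unit eigenvector field with per-voxel random sign.

    The random sign flip emulates the inherent sign ambiguity of principal
    eigenvectors; downstream consumers must be sign-invariant.
    """
    rng = np.random.default_rng(seed)
    shape = grid.shape
    vec = np.zeros(shape + (3,), dtype=np.float32)
    if pattern.kind == "uniform":
        d = np.asarray(pattern.direction, dtype=float)
        vec[...] = d / np.linalg.norm(d)
    elif pattern.kind == "crossing":
        # two interleaved orthogonal populations by voxel parity
        d1 = np.asarray(pattern.direction, dtype=float)
        d1 = d1 / np.linalg.norm(d1)
        helper = np.array([0.0, 0.0, 1.0]) if abs(d1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        d2 = np.cross(d1, helper)
        d2 = d2 / np.linalg.norm(d2)
        ii, jj, kk = np.indices(shape)
        parity = (ii + jj + kk) % 2 == 0
        vec[parity] = d1
        vec[~parity] = d2
    else:
        ii, jj, kk = np.indices(shape)
        ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        world = grid.voxel_to_world(ijk).reshape(shape + (3,))
        rel = world - np.asarray(pattern.center, dtype=float)
        if pattern.kind == "radial":
            v = rel
        else:  # concentric: tangent circles about the vertical axis of center
            v = np.stack([-rel[..., 1], rel[..., 0], np.zeros(shape)], axis=-1)
        n = np.linalg.norm(v, axis=-1)
        ok = n > 1e-9
        vec[ok] = (v[ok] / n[ok][..., None]).astype(np.float32)
    signs = np.where(rng.random(shape) < 0.5, -1.0, 1.0).astype(np.float32)
    vec *= signs[..., None]
    valid = np.linalg.norm(vec, axis=-1) > 1e-6
    if pattern.validity_fraction < 1.0:
        valid &= rng.random(shape) < pattern.validity_fraction
    return EigenvectorField(grid, vec, valid)


def _ball_mask(grid: TemplateGrid, center_world, radius_vox: float) -> Volume:
    values = np.zeros(grid.shape, dtype=np.uint8)
    c = grid.world_to_voxel(center_world)
    r = int(np.ceil(radius_vox))
    lo = np.maximum(np.floor(c).astype(int) - r, 0)
    hi = np.minimum(np.floor(c).astype(int) + r + 2, grid.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    ii, jj, kk = np.mgrid[sl]
    d2 = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2
    values[sl] = (d2 <= radius_vox ** 2).astype(np.uint8)
    return Volume(grid, values, "mask")


_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def grow_tumor(seed_mask: Volume, field: EigenvectorField,
               regime: GrowthRegime, seed: int = 0) -> Volume:
    """Grow a mask by direction-weighted stochastic boundary accretion.

    Returns a superset of ``seed_mask``; deterministic given ``seed``.
    Candidate voxels where the fiber field is invalid accrete with the
    regime's mean weight (0.5 for the fiber-relative modes), so holes in the
    field do not bias the shape.
    """
    if seed_mask.kind != "mask" or seed_mask.values.sum() == 0:
        raise ValueError("grow_tumor needs a nonempty seed mask")
    if not field.grid.same_as(seed_mask.grid):
        raise ValueError("fiber field and seed mask are on different grids")
    rng = np.random.default_rng(seed)
    grid = seed_mask.grid
    mask = seed_mask.values.astype(bool)
    mag_vox = regime.magnitude / float(np.mean(grid.spacing))
    target_w = (np.asarray(regime.target, dtype=float)
                if regime.target is not None else None)

    for _ in range(regime.steps):
        # work in a window around the mask for speed on template-size grids
        idx = np.argwhere(mask)
        lo = np.maximum(idx.min(axis=0) - 3, 0)
        hi = np.minimum(idx.max(axis=0) + 4, grid.shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        sub = mask[sl]
        cand = ndimage.binary_dilation(sub, structure=_STRUCT) & ~sub
        cidx = np.argwhere(cand)
        if cidx.size == 0:
            break
        cidx_full = cidx + lo
        # local accretion direction: outward surface normal of the mask,
        # from the gradient of its smoothed indicator (world axes)
        smooth = ndimage.gaussian_filter(sub.astype(np.float32), 1.5)
        grads = np.gradient(smooth)
        d = -np.stack([g[tuple(cidx.T)] / s
                       for g, s in zip(grads, grid.spacing)], axis=-1)
        dn = np.linalg.norm(d, axis=1)
        ok_n = dn > 1e-8
        # degenerate normals: fall back to the centroid direction
        cen = idx.mean(axis=0)
        dc = (cidx_full - cen) * grid.spacing
        dcn = np.linalg.norm(dc, axis=1)
        dcn[dcn < 1e-9] = 1.0
        d[~ok_n] = dc[~ok_n] / dcn[~ok_n, None]
        d[ok_n] = d[ok_n] / dn[ok_n, None]

        if regime.mode == "isotropic":
            w = np.ones(len(cidx))
        else:
            if regime.mode == "toward_target":
                pref = target_w - grid.voxel_to_world(cidx_full)
                pn = np.linalg.norm(pref, axis=1)
                pn[pn < 1e-9] = 1.0
                pref = pref / pn[:, None]
                cosp = np.einsum("ij,ij->i", d, pref)
                psi = np.degrees(np.arccos(np.clip(cosp, -1.0, 1.0)))
                if regime.noise_deg > 0:
                    psi = np.clip(psi + rng.normal(0, regime.noise_deg, len(psi)),
                                  0.0, 180.0)
                w = ((1.0 + np.cos(np.deg2rad(psi))) / 2.0) ** 2
            else:
                e = field.vectors[tuple(cidx_full.T)]
                ok = field.valid[tuple(cidx_full.T)]
                cosp = np.abs(np.einsum("ij,ij->i", d, e))
                psi = np.degrees(np.arccos(np.clip(cosp, 0.0, 1.0)))
                if regime.noise_deg > 0:
                    psi = np.clip(psi + rng.normal(0, regime.noise_deg, len(psi)),
                                  0.0, 90.0)
                c2 = np.cos(np.deg2rad(psi)) ** 2
                w = c2 if regime.mode == "along_fiber" else 1.0 - c2
                w[~ok] = 0.5  # invalid fiber voxel: no directional information
        p = np.clip(mag_vox * w, 0.0, 1.0)
        accept = rng.random(len(p)) < p
        mask[tuple(cidx_full[accept].T)] = True
    return Volume(grid, mask.astype(np.uint8), "mask")


def patient_seed(master_seed: int, index: int) -> int:
    """Per-patient seed: child ``index`` of the master SeedSequence."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _check_boxes(boxes: dict) -> None:
    names = list(boxes)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ba, bb = boxes[names[a]], boxes[names[b]]
            if all(ba[d][0] < bb[d][1] and bb[d][0] < ba[d][1] for d in range(3)):
                raise ConfigurationError(
                    f"region boxes {names[a]} and {names[b]} overlap")


def make_cohort(n_per_region: int,
                regimes: dict[str, GrowthRegime],
                grid: TemplateGrid,
                seed: int = 0,
                fiber: EigenvectorField | None = None,
                fiber_pattern: FiberPattern | None = None,
                region_boxes: dict | None = None,
                seed_radius_vox: tuple[float, float] = DEFAULT_SEED_RADIUS_VOX,
                steps_range: tuple[int, int] = DEFAULT_STEPS,
                interval_days: tuple[int, int] = DEFAULT_INTERVAL_DAYS,
                out_dir: str | Path | None = None,
                ) -> tuple[list[SyntheticPatient], pd.DataFrame]:
    """Generate a reproducible cohort of two-timepoint synthetic patients.

    One master seed fans out to per-patient seeds via
    :func:`patient_seed`; the cohort (mask voxels, intervals, manifest) is a
    pure function of (parameters, seed).  If ``out_dir`` is given, masks are
    written as NIfTI and a manifest CSV referencing them is produced.
    """
    if n_per_region < 1:
        raise ConfigurationError("n_per_region must be >= 1")
    boxes = dict(region_boxes or REGION_BOXES)
    _check_boxes(boxes)
    unknown = set(regimes) - set(boxes)
    if unknown:
        raise ConfigurationError(f"regimes reference unknown regions: {unknown}")
    if fiber is None:
        fiber = make_fiber_field(
            grid, fiber_pattern or FiberPattern("uniform", direction=(1, 0, 0)),
            seed=patient_seed(seed, 10_000))
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    patients: list[SyntheticPatient] = []
    rows = []
    index = 0
    for region in sorted(regimes):
        box = boxes[region]
        regime = regimes[region]
        for j in range(n_per_region):
            pseed = patient_seed(seed, index)
            rng = np.random.default_rng(pseed)
            center = [rng.uniform(lo, hi) for lo, hi in box]
            radius = rng.uniform(*seed_radius_vox)
            steps = int(rng.integers(steps_range[0], steps_range[1] + 1))
            interval = int(rng.integers(interval_days[0], interval_days[1] + 1))
            mask_t1 = _ball_mask(grid, center, radius)
            regime_j = GrowthRegime(mode=regime.mode, magnitude=regime.magnitude,
                                    steps=steps, target=regime.target,
                                    noise_deg=regime.noise_deg)
            mask_t2 = grow_tumor(mask_t1, fiber, regime_j, seed=pseed)
            pid = f"synth-{region[:3]}-{j:03d}"
            pat = SyntheticPatient(patient_id=pid, region=region,
                                   mask_t1=mask_t1, mask_t2=mask_t2,
                                   interval_days=interval,
                                   true_regime=regime_j, seed=pseed)
            patients.append(pat)
            row = {"patient_id": pid, "region": region,
                   "date_t1": pat.date_t1.isoformat(),
                   "date_t2": pat.date_t2.isoformat(),
                   "hemisphere": pat.hemisphere}
            if out_dir is not None:
                p1 = out_dir / f"{pid}_t1.nii.gz"
                p2 = out_dir / f"{pid}_t2.nii.gz"
                write_volume(mask_t1, p1)
                write_volume(mask_t2, p2)
                row["path_mask_t1"] = str(p1)
                row["path_mask_t2"] = str(p2)
            rows.append(row)
            index += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return patients, manifest
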