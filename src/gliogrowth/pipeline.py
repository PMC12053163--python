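"""End-to-end workflow: simulate a cohort, analyze it, report the results.

Five stages per patient: (1) load/harmonize the two masks onto the analysis
grid and mirror right-hemisphere tumors to the left; (2) register T1 to T2
for the displacement field and the +/-1 differential map; (3) intersect
growth vectors with the fiber field to get voxel-wise acute angles;
(4) volumetric growth metrics; (5) cohort-level pooling — alignment tests
overall and per region, voxel-wise frequency maps per timepoint, angle
histograms, and region comparisons.

All randomness flows from one master seed in the config; rerunning with the
same config and seed reproduces every number.  A resolved-config snapshot is
written alongside the results of each run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import angular_alignment as aa
from . import cohort_maps as cm
from . import deformation_field as df
from . import growth_metrics as gm
from . import synthetic_cohort as sc
from . import volume_io as vio

log = logging.getLogger("gliogrowth")

REGIME_MODES = ("isotropic", "along_fiber", "perpendicular_fiber",
                "toward_target")


@dataclass
class PipelineConfig:
    """Resolved parameters for one pipeline run."""

    # analysis grid
    grid_shape: tuple[int, int, int] = (181, 217, 181)
    grid_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_origin: tuple[float, float, float] = (-90.0, -126.0, -72.0)
    # fiber field (synthetic) or a path to a 4-D NIfTI eigenvector file
    fiber_kind: str = "uniform"
    fiber_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    fiber_center: tuple[float, float, float] | None = None
    fiber_validity_fraction: float = 1.0
    fiber_path: str | None = None
    # cohort simulation block
    n_per_region: int = sc.DEFAULT_N_PER_REGION
    regimes: dict = field(default_factory=lambda: {
        "allocortex": "perpendicular_fiber",
        "mesocortex": "perpendicular_fiber",
        "isocortex": "perpendicular_fiber",
    })
    magnitude_mm: float = sc.DEFAULT_MAGNITUDE_MM
    noise_deg: float = sc.DEFAULT_NOISE_DEG
    seed_radius_vox: tuple[float, float] = sc.DEFAULT_SEED_RADIUS_VOX
    steps_range: tuple[int, int] = sc.DEFAULT_STEPS
    interval_days: tuple[int, int] = sc.DEFAULT_INTERVAL_DAYS
    growth_target: tuple[float, float, float] | None = None
    # registration
    reg_levels: int = 3
    reg_iterations: int = 50
    reg_sigma_image: float = 1.0
    reg_sigma_fluid: float = 1.5
    reg_sigma_diffusion: float = 1.0
    reg_step_cap: float = 0.5
    reg_convergence_tol: float = 1e-4
    # angle analysis
    threshold_deg: float = 20.0
    min_magnitude_mm: float = 0.2
    support_mode: str = "union"  # or "t21"
    n_bins: int = 18
    midsagittal_x: float = 0.0
    write_pooled_angles: bool = True
    # provenance
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold_deg < 90:
            raise ValueError("threshold_deg must be in (0, 90)")
        for region, mode in self.regimes.items():
            if mode not in REGIME_MODES:
                raise sc.ConfigurationError(
                    f"unknown growth mode {mode!r} for region {region!r}")
            if region not in sc.REGION_BOXES:
                raise sc.ConfigurationError(f"unknown region {region!r}")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_shape", "grid_spacing", "grid_origin",
                    "fiber_direction", "fiber_center", "seed_radius_vox",
                    "steps_range", "interval_days", "growth_target"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    # -- derived objects ---------------------------------------------------
    def grid(self) -> vio.TemplateGrid:
        return vio.TemplateGrid.from_origin(self.grid_shape, self.grid_spacing,
                                            self.grid_origin)

    def fiber_pattern(self) -> sc.FiberPattern:
        return sc.FiberPattern(kind=self.fiber_kind,
                               direction=self.fiber_direction,
                               center=self.fiber_center,
                               validity_fraction=self.fiber_validity_fraction)

    def regime_for(self, region: str) -> sc.GrowthRegime:
        return sc.GrowthRegime(mode=self.regimes[region],
                               magnitude=self.magnitude_mm,
                               noise_deg=self.noise_deg,
                               target=self.growth_target)

    def registration_params(self) -> df.RegistrationParams:
        return df.RegistrationParams(
            levels=self.reg_levels, iterations=self.reg_iterations,
            sigma_image=self.reg_sigma_image, sigma_fluid=self.reg_sigma_fluid,
            sigma_diffusion=self.reg_sigma_diffusion,
            step_cap=self.reg_step_cap,
            convergence_tol=self.reg_convergence_tol)


def load_fiber_field(config: PipelineConfig,
                     grid: vio.TemplateGrid) -> aa.EigenvectorField:
    """Load the eigenvector field from disk or synthesize it."""
    if config.fiber_path:
        vol = vio.read_volume(config.fiber_path)
        if not vol.grid.same_as(grid):
            vol = vio.harmonize_to_grid(vol, grid)
        return aa.EigenvectorField.from_volume(vol)
    return sc.make_fiber_field(grid, config.fiber_pattern(),
                               seed=sc.patient_seed(config.seed, 10_000))


def simulate(config: PipelineConfig, out_dir: str | Path) -> pd.DataFrame:
    """Generate and serialize a synthetic cohort plus its fiber field."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = config.grid()
    t0 = time.time()
    fiber = load_fiber_field(config, grid)
    regimes = {r: config.regime_for(r) for r in config.regimes}
    log.info("simulate: %d patients/region, regimes=%s, seed=%d",
             config.n_per_region, config.regimes, config.seed)
    _, manifest = sc.make_cohort(
        config.n_per_region, regimes, grid, seed=config.seed, fiber=fiber,
        seed_radius_vox=config.seed_radius_vox, steps_range=config.steps_range,
        interval_days=config.interval_days, out_dir=out_dir)
    vio.write_volume(vio.Volume(grid, fiber.vectors, "vector3"),
                     out_dir / "fiber_field.nii.gz")
    config.to_yaml(out_dir / "resolved_config.yaml")
    log.info("simulate: wrote %d patients to %s in %.1fs",
             len(manifest), out_dir, time.time() - t0)
    return manifest


def _load_patient_masks(row, grid: vio.TemplateGrid,
                        midsagittal_x: float) -> tuple[vio.Volume, vio.Volume]:
    m1 = vio.tumor_presence(vio.read_volume(row["path_mask_t1"]))
    m2 = vio.tumor_presence(vio.read_volume(row["path_mask_t2"]))
    if not m1.grid.same_as(grid):
        m1 = vio.harmonize_to_grid(m1, grid)
    if not m2.grid.same_as(grid):
        m2 = vio.harmonize_to_grid(m2, grid)
    hemi = str(row.get("hemisphere", "")).lower()
    if not hemi or hemi == "auto":
        hemi = vio.hemisphere_of(m1, midsagittal_x)
    if hemi == "right":
        m1 = vio.mirror_to_left(m1, midsagittal_x)
        m2 = vio.mirror_to_left(m2, midsagittal_x)
    return m1, m2


def analyze(config: PipelineConfig, manifest: pd.DataFrame | str | Path,
            out_dir: str | Path) -> dict:
    """Run registration, angle, growth and map analysis over a cohort.

    A failing patient is logged and skipped; the run fails only if every
    patient fails.  Returns the summary dictionary that is also written as
    ``results.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    grid = config.grid()
    fiber = load_fiber_field(config, grid)
    params = config.registration_params()
    days = None
    if {"date_t1", "date_t2"} <= set(manifest.columns):
        days = (pd.to_datetime(manifest["date_t2"])
                - pd.to_datetime(manifest["date_t1"])).dt.days

    agg = aa.AngleAggregator(grid)
    records: list[gm.GrowthRecord] = []
    diagnostics: dict[str, dict] = {}
    freq_masks: dict[tuple[str, str], list[vio.Volume]] = {}
    conservation = []
    failures = []
    pooled_path = out_dir / "pooled_angles.csv"
    if config.write_pooled_angles:
        pooled_path.write_text("patient_id,region,i,j,k,theta\n")

    for _, row in manifest.iterrows():
        pid, region = row["patient_id"], row["region"]
        t0 = time.time()
        try:
            m1, m2 = _load_patient_masks(row, grid, config.midsagittal_x)
            interval = int(days.loc[row.name]) if days is not None else int(
                row["interval_days"])
            field, diag = df.register(m1, m2, params)
            dmap = df.differential_map(m1, m2)
            support = df.angle_support(m1, dmap, config.support_mode)
            gv = df.growth_vectors(field, support, config.min_magnitude_mm)
            amap = aa.angle_map(gv, fiber)
            agg.add(amap, support, region)
            rec = gm.compute_growth(m1, m2, interval, patient_id=pid,
                                    region=region)
            records.append(rec)
            vv = gm.voxel_volume_mm3(m1)
            conservation.append({
                "patient_id": pid,
                "differential_mm3": (dmap.n_positive - dmap.n_negative) * vv,
                "absolute_growth_mm3": rec.absolute_growth,
            })
            diagnostics[pid] = {**diag, "n_angles": int(amap.valid.sum()),
                                "seconds": round(time.time() - t0, 2)}
            for tp, m in (("T1", m1), ("T2", m2)):
                freq_masks.setdefault((region, tp), []).append(m)
            if config.write_pooled_angles:
                idx = np.argwhere(amap.valid)
                th = amap.theta[amap.valid]
                chunk = pd.DataFrame({"patient_id": pid, "region": region,
                                      "i": idx[:, 0], "j": idx[:, 1],
                                      "k": idx[:, 2], "theta": th})
                chunk.to_csv(pooled_path, mode="a", header=False, index=False)
            log.info("analyze %s (%s): dice=%.3f angles=%d %.1fs", pid, region,
                     diag["dice_after"], int(amap.valid.sum()),
                     time.time() - t0)
        except Exception as exc:  # noqa: BLE001 - per-patient isolation
            failures.append({"patient_id": pid, "error": str(exc)})
            log.warning("analyze %s failed: %s", pid, exc)
    if not records:
        raise RuntimeError("analysis failed for every patient")

    # ---- cohort level ----------------------------------------------------
    region_samples = agg.region_samples()
    all_angles = agg.all_samples()
    tests: dict[str, dict] = {}
    histograms: dict[str, dict] = {}
    p0 = aa.isotropic_p_below(config.threshold_deg)
    strata = {"overall": all_angles, **region_samples}
    for name, angles in strata.items():
        if angles.size == 0:
            tests[name] = {"n_total": 0, "note": "no valid growth vectors"}
            continue
        res = aa.alignment_test(angles, config.threshold_deg, null_p=p0)
        tests[name] = res.as_dict()
        hist = aa.angle_histogram(angles, config.n_bins, config.threshold_deg)
        histograms[name] = {"mode_bin": list(hist.mode_bin),
                            "density": hist.density.tolist(),
                            "edges": hist.edges.tolist()}
        aa.plot_angle_histogram(hist, out_dir / f"angles_{name}.png",
                                title=f"{name} (n={res.n_total})")

    gm.records_table(records).to_csv(out_dir / "growth_records.csv",
                                     index=False)
    region_tests = {}
    by_region = {}
    for rec in records:
        by_region.setdefault(rec.region, []).append(rec)
    if len(by_region) >= 2 and all(len(v) >= 3 for v in by_region.values()):
        for metric in ("growth_per_day", "growth_factor"):
            region_tests[metric] = gm.compare_regions(records, metric)
        region_tests["interval_days"] = gm.compare_regions(records,
                                                           "interval_days")

    for (region, tp), masks in sorted(freq_masks.items()):
        fmap = cm.frequency_map(masks, timepoint=tp, region=region)
        vio.write_volume(fmap.to_volume(),
                         out_dir / f"frequency_{region}_{tp}.nii.gz")
    all_t1 = [m for (r, tp), ms in freq_masks.items() if tp == "T1" for m in ms]
    all_t2 = [m for (r, tp), ms in freq_masks.items() if tp == "T2" for m in ms]
    for tp, ms in (("T1", all_t1), ("T2", all_t2)):
        fmap = cm.frequency_map(ms, timepoint=tp, region="all")
        vio.write_volume(fmap.to_volume(),
                         out_dir / f"frequency_all_{tp}.nii.gz")
        axis = 1
        idx = int(np.argmax(fmap.counts.sum(axis=(0, 2))))
        cm.render_overlay(fmap, None, axis, idx,
                          out_dir / f"frequency_all_{tp}.png")

    vio.write_volume(vio.Volume(grid, agg.mean_map().theta, "scalar"),
                     out_dir / "mean_angle_map.nii.gz")

    summary = {
        "n_patients": len(records),
        "n_failures": len(failures),
        "failures": failures,
        "threshold_deg": config.threshold_deg,
        "p0": p0,
        "alignment_tests": tests,
        "histograms": histograms,
        "region_comparisons": region_tests,
        "conservation": conservation,
        "diagnostics": diagnostics,
        "seed": config.seed,
    }
    with open(out_dir / "results.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    config.to_yaml(out_dir / "resolved_config.yaml")
    return summary


def report(results_dir: str | Path, out_path: str | Path | None = None) -> str:
    """Render a markdown summary of an analysis results bundle."""
    results_dir = Path(results_dir)
    path = results_dir / "results.json"
    if not path.exists():
        raise FileNotFoundError(f"no results bundle at {results_dir}")
    with open(path) as fh:
        summary = json.load(fh)
    lines = ["# Glioma growth alignment report", ""]
    lines += [f"Patients analyzed: {summary['n_patients']} "
              f"(failed: {summary['n_failures']})",
              f"Alignment threshold: {summary['threshold_deg']:g} deg, "
              f"isotropic null p0 = {summary['p0']:.4f}", ""]
    lines += ["## Alignment tests", "",
              "| stratum | n | below | h | p0 | p-value |",
              "|---|---|---|---|---|---|"]
    for name, t in summary["alignment_tests"].items():
        if not t.get("n_total"):
            lines.append(f"| {name} | 0 | n/a | n/a | n/a | n/a |")
            continue
        lines.append(f"| {name} | {t['n_total']} | {t['n_below']} | "
                     f"{t['h']:.4f} | {t['p0']:.4f} | {t['p_value']:.3g} |")
    lines.append("")
    for name, h in summary.get("histograms", {}).items():
        lo, hi = h["mode_bin"]
        lines.append(f"- {name}: histogram mode in [{lo:g}, {hi:g}] deg "
                     f"(figure: angles_{name}.png)")
    lines.append("")
    if summary.get("region_comparisons"):
        lines += ["## Region comparisons", ""]
        for metric, rep in summary["region_comparisons"].items():
            kw = rep["kruskal_wallis"]
            lines.append(f"- {metric}: Kruskal-Wallis H = {kw['H']:.3g}, "
                         f"p = {kw['p_value']:.3g}")
            for pair, mw in rep["mann_whitney_pairwise"].items():
                lines.append(f"    - {pair}: U = {mw['U']:.3g}, "
                             f"p = {mw['p_value']:.3g}")
        lines.append("")
    lines += ["## Growth records", "",
              "See `growth_records.csv`; frequency maps and angle histograms "
              "are alongside this file.", ""]
    text = "\n".join(lines)
    if out_path is None:
        out_path = results_dir / "report.md"
    Path(out_path).write_text(text)
    return text
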