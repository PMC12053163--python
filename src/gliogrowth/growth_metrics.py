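"""Per-patient volumetric growth measures and cohort comparisons.

For a patient with tumor volumes v1 and v2 (mm^3) at the two timepoints,
separated by ``interval_days``:

    absolute growth  = v2 - v1                       (mm^3)
    growth per day   = absolute growth / interval    (mm^3/day)
    growth factor    = v2 / v1                       (unitless)
    pct increase     = (growth factor - 1) * 100     (%)

Volumes are voxel counts times the voxel volume from the grid affine.
Negative growth is permitted (segmentation variability).  Cohort
comparisons use rank tests from scipy (Shapiro-Wilk per group,
Kruskal-Wallis across regions, pairwise Mann-Whitney U); the contribution
here is the metric definitions and the report, not the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import Volume


@dataclass(frozen=True)
class GrowthRecord:
    patient_id: str
    region: str
    v1: float
    v2: float
    interval_days: int
    absolute_growth: float
    growth_per_day: float
    growth_factor: float
    pct_increase: float

    def as_dict(self) -> dict:
        return asdict(self)


def voxel_volume_mm3(vol: Volume) -> float:
    return float(abs(np.linalg.det(vol.grid.affine[:3, :3])))


def compute_growth(mask_t1: Volume, mask_t2: Volume, interval_days: int,
                   patient_id: str = "", region: str = "") -> GrowthRecord:
    """Volumetric growth record for one patient."""
    if mask_t1.kind != "mask" or mask_t2.kind != "mask":
        raise ValueError("growth metrics require mask volumes")
    if not mask_t1.grid.same_as(mask_t2.grid):
        raise ValueError("masks are on different grids")
    if interval_days <= 0:
        raise ValueError("interval_days must be positive")
    vv = voxel_volume_mm3(mask_t1)
    v1 = float(mask_t1.values.sum()) * vv
    v2 = float(mask_t2.values.sum()) * vv
    if v1 == 0:
        raise ValueError("growth factor undefined for an empty T1 mask")
    absolute = v2 - v1
    factor = v2 / v1
    return GrowthRecord(patient_id=patient_id, region=region, v1=v1, v2=v2,
                        interval_days=int(interval_days),
                        absolute_growth=absolute,
                        growth_per_day=absolute / interval_days,
                        growth_factor=factor,
                        pct_increase=(factor - 1.0) * 100.0)


def records_table(records: Sequence[GrowthRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


def compare_regions(records: Sequence[GrowthRecord],
                    metric: str = "growth_per_day") -> dict:
    """Region-wise comparison of one growth metric.

    Shapiro-Wilk normality per region, Kruskal-Wallis H across regions, and
    pairwise Mann-Whitney U tests (two-sided, scipy's default tie and
    continuity handling).  Needs >= 2 regions with >= 3 records each.
    """
    table = records_table(records)
    if metric not in table.columns:
        raise ValueError(f"unknown metric {metric!r}")
    groups = {r: g[metric].to_numpy(dtype=float)
              for r, g in table.groupby("region")}
    if len(groups) < 2 or any(len(v) < 3 for v in groups.values()):
        raise ValueError("compare_regions needs >= 2 regions with >= 3 "
                         "records each")
    shapiro = {}
    for region, vals in groups.items():
        if np.ptp(vals) == 0:  # constant sample: normality test undefined
            shapiro[region] = {"statistic": float("nan"), "p_value": float("nan")}
        else:
            s = stats.shapiro(vals)
            shapiro[region] = {"statistic": float(s.statistic),
                               "p_value": float(s.pvalue)}
    kw = stats.kruskal(*groups.values())
    pairwise = {}
    for a, b in combinations(sorted(groups), 2):
        mw = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        pairwise[f"{a}-{b}"] = {"U": float(mw.statistic),
                                "p_value": float(mw.pvalue)}
    return {
        "metric": metric,
        "n_per_region": {r: int(len(v)) for r, v in groups.items()},
        "shapiro_wilk": shapiro,
        "kruskal_wallis": {"H": float(kw.statistic), "p_value": float(kw.pvalue)},
        "mann_whitney_pairwise": pairwise,
        "notes": "rank tests via scipy defaults (tie correction and, for "
                 "Mann-Whitney, continuity correction applied)",
    }
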