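"""Pairwise segmentation agreement metrics (rater quality control).

Dice = 2|A∩B| / (|A|+|B|) and Jaccard = |A∩B| / |A∪B| on binary masks.
The two are algebraically tied: jaccard = dice / (2 - dice).  Two empty
masks count as perfect agreement (dice = jaccard = 1); empty vs nonempty
is 0 — the standard convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .volume_io import Volume


@dataclass(frozen=True)
class OverlapResult:
    dice: float
    jaccard: float
    n_a: int
    n_b: int
    n_intersection: int


def overlap(a: Volume, b: Volume) -> OverlapResult:
    """Dice and Jaccard between two masks on the same grid."""
    if a.kind != "mask" or b.kind != "mask":
        raise ValueError("overlap is defined for mask volumes")
    if not a.grid.same_as(b.grid):
        raise ValueError("masks are on different grids")
    av = a.values > 0
    bv = b.values > 0
    n_a = int(av.sum())
    n_b = int(bv.sum())
    n_i = int(np.logical_and(av, bv).sum())
    n_u = n_a + n_b - n_i
    if n_a == 0 and n_b == 0:
        dice = jaccard = 1.0
    else:
        dice = 2.0 * n_i / (n_a + n_b)
        jaccard = n_i / n_u
    return OverlapResult(dice=dice, jaccard=jaccard,
                         n_a=n_a, n_b=n_b, n_intersection=n_i)


def pairwise_overlap(masks: Sequence[Sequence[Volume]],
                     labels: Sequence[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All unordered rater pairs across patients, with per-pair mean/SD.

    ``masks[r][p]`` is rater r's mask for patient p.  Returns a long table
    (patient, pair, dice, jaccard) and a summary with mean and SD per pair.
    """
    if len(masks) < 2:
        raise ValueError("pairwise_overlap needs at least 2 raters")
    if len(labels) != len(masks):
        raise ValueError("one label per rater required")
    n_patients = len(masks[0])
    if any(len(m) != n_patients for m in masks):
        raise ValueError("every rater must cover the same patients")
    rows = []
    for (ia, la), (ib, lb) in combinations(enumerate(labels), 2):
        for p in range(n_patients):
            r = overlap(masks[ia][p], masks[ib][p])
            rows.append({"patient": p, "pair": f"{la}-{lb}",
                         "dice": r.dice, "jaccard": r.jaccard})
    table = pd.DataFrame(rows)
    summary = (table.groupby("pair")[["dice", "jaccard"]]
               .agg(["mean", "std"]))
    summary.columns = ["_".join(c) for c in summary.columns]
    return table, summary.reset_index()
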