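# gliogrowth

Does a tumor grow *along* white-matter fiber tracts, or not? `gliogrowth`
answers that question quantitatively for longitudinal imaging cohorts: it
turns pairs of serial binary tumor segmentations into dense displacement
fields, compares the per-voxel growth direction with the local principal
diffusion eigenvector, and tests the pooled acute angles against the
analytic expectation under direction-free (isotropic) growth.

It is aimed at neuroimaging researchers studying growth patterns of
low-grade glioma and similar slowly progressing lesions, where the
along-tract dissemination hypothesis is routinely assumed but rarely
measured.

## The statistic

For each patient, masks at two timepoints on a common 1 mm template grid
are registered (demons on signed distance transforms) to give a growth
displacement field `v(x)`. At every voxel where growth and a fiber axis
`e(x)` are both defined, the acute angle

    θ(x) = arccos( |v·e| / (|v||e|) )  ∈ [0°, 90°]

is computed; the absolute value folds out the eigenvector's sign ambiguity.
Under isotropic growth θ has density `(π/180)·sin θ`, so

    p₀ = P(θ < 20°) = 1 − cos 20° ≈ 0.0603.

The observed proportion `h` of pooled voxel angles below 20° is compared
with `p₀` by an exact binomial test: `h` significantly above `p₀` indicates
growth along tracts, significantly below indicates perpendicular growth
(angle histogram piling up near 90°).

Because patient MRI cannot be redistributed, the package ships a synthetic
cohort generator — two-timepoint tumors grown with controlled direction
preference (isotropic / along-fiber / perpendicular / toward a target) over
synthetic eigenvector fields — so the entire pipeline is testable with
known ground truth.

## Worked example

Simulate a small cohort growing perpendicular to a uniform left-right
fiber field, analyze it, and read off the alignment test:

```python
import tempfile
from pathlib import Path
from gliogrowth import PipelineConfig, simulate, analyze

cfg = PipelineConfig(
    grid_shape=(72, 88, 104), grid_origin=(-52.0, -36.0, -40.0),
    n_per_region=2, steps_range=(20, 30),
    regimes={"allocortex": "perpendicular_fiber",
             "mesocortex": "perpendicular_fiber",
             "isocortex": "perpendicular_fiber"},
    seed=42, write_pooled_angles=False)

with tempfile.TemporaryDirectory() as td:
    manifest = simulate(cfg, Path(td) / "cohort")
    summary = analyze(cfg, Path(td) / "cohort" / "manifest.csv",
                      Path(td) / "results")

t = summary["alignment_tests"]["overall"]
print(f"pooled angles : {t['n_total']}")
print(f"h (< 20 deg)  : {t['h']:.4f}")
print(f"p0 (isotropic): {t['p0']:.4f}")
print(f"p-value       : {t['p_value']:.3g}")
print(f"mode bin      : {summary['histograms']['overall']['mode_bin']}")
```

Output:

```
pooled angles : 35298
h (< 20 deg)  : 0.0001
p0 (isotropic): 0.0603
p-value       : 0
mode bin      : [85.0, 90.0]
```

Of 35 298 pooled voxel angles, essentially none fall below 20° — far below
the 6.03% an isotropic tumor would show (p ≈ 0 to double precision) — and
the angle histogram peaks in the 85–90° bin: the pipeline correctly
identifies growth perpendicular to the fiber field. The results directory
also contains per-region histograms (PNG), voxel-wise cohort frequency maps
(NIfTI + PNG), growth-rate records (CSV), and a `results.json` bundle that
`gliogrowth report` renders as markdown.

The same workflow runs from the shell:

```sh
gliogrowth simulate --config cfg.yaml --out cohort/
gliogrowth analyze  --config cfg.yaml --manifest cohort/manifest.csv --out results/
gliogrowth report results/
```

Real data enters through the same manifest: a CSV with columns
`patient_id, region, date_t1, date_t2, path_mask_t1, path_mask_t2,
hemisphere` pointing at NIfTI masks, plus an eigenvector field
(`fiber_path` in the config) as a 4-D NIfTI with three components per
voxel. Volumes are reoriented to canonical RAS at read time; grids one
voxel larger than the analysis grid (e.g. a 182×218×182 atlas against the
181×217×181 MR grid) are truncated by world-coordinate comparison, and
right-hemisphere tumors are mirrored to the left.

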