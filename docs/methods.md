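# Methods

`gliogrowth` quantifies whether longitudinal tumor growth follows local
white-matter fiber orientation. This note documents the models, the
numerical choices, and what the synthetic validation does and does not
establish.

## The alignment statistic

For one patient, two binary tumor masks on a common 1 mm template grid
(timepoints T1 and T2) are registered to produce a dense displacement field
`v(x)` (mm, world axes) describing where T1 tissue moved by T2. At every
voxel where a growth vector and a principal diffusion eigenvector `e(x)` are
both defined, the acute angle

    theta(x) = arccos( |v . e| / (|v| |e|) )  in [0, 90] degrees

measures local alignment of growth with the fiber axis. Eigenvectors are
axes, not directions — their sign is arbitrary — so the dot product is
folded by the absolute value, and every downstream quantity is invariant to
sign flips of either field (this is tested).

Voxel angles are pooled across patients (overall and per anatomical region)
and summarized by the proportion `h` of angles below a threshold, 20 degrees
by default. Growth *along* fibers inflates `h`; growth *perpendicular* to
them depletes it.

### The isotropic null

If growth direction is uniform on the sphere, the acute angle to any fixed
axis has density

    f(theta) = (pi/180) sin(theta),   theta in [0, 90] deg,

hence `P(theta < t) = 1 - cos(t)`, giving `p0 = 1 - cos(20 deg) = 0.0603`.
The observed count below threshold is compared with `p0` by an exact
binomial test (two-sided by default; one-sided variants by flag).

Voxels are pooled as independent trials. They are not independent — angles
at neighboring voxels are strongly correlated through the registration — so
with large pooled `n` the test will flag even tiny systematic deviations.
This pooling is deliberate (it is the estimand of interest at cohort scale),
but p-values should be read as descriptive at large `n`. The per-patient
route (compute `h` per patient, then test patients as units) is available by
aggregating region samples per patient and is a more conservative check.

## Registration: distance-transform demons

The displacement field is recovered by a demons-style registration of the
Gaussian-smoothed *signed distance transforms* of the two masks (positive
outside, negative inside). Distance maps convert a binary matching problem
into a smooth monomodal intensity problem whose gradient is the surface
normal — exactly the geometry a boundary displacement field needs. Per
iteration the classic demons force

    u = (F - M∘phi) grad(M∘phi) / (|grad|^2 + (F - M∘phi)^2)

is capped at `step_cap` voxels, smoothed at `sigma_fluid`, composed
additively, and the field re-smoothed at `sigma_diffusion`; the scheme runs
coarse-to-fine over a multiresolution pyramid. Defaults (3 levels, 50
iterations/level, `sigma_image` 1.0, `sigma_fluid` 1.5, `sigma_diffusion`
1.0 voxels, `step_cap` 0.5 voxel, relative-cost tolerance 1e-4) are standard
demons practice and are validated against closed forms: a concentric-sphere
expansion must yield radial vectors (median angular error < 15 degrees in
the acceptance check; measured ~0.2 degrees) and a pure translation must be
recovered within a voxel.

Implementation points:

- Registration runs on a crop around the union mask plus a margin; the
  field is identically zero beyond a `support_radius` (default 5 voxels)
  from the union, since displacement far from the tumor is unconstrained
  by mask geometry.
- The internal demons field maps T2-frame voxels back to T1; the returned
  growth field is its negation (points T1 -> T2). The acute angle is
  invariant to this sign, but radial/translation oracles are not, so the
  convention is fixed and tested.
- Diagnostics per patient: warped-mask Dice against T2 after each pyramid
  level (non-decreasing in practice), and the fraction of union-support
  voxels with positive Jacobian determinant (>= 0.99 with defaults).
- Displacements below `min_magnitude` (default 0.2 mm) are excluded from
  angle analysis: sub-noise displacements have meaningless directions.
- The angle support defaults to the union of the T1 mask and the +1 region
  of the differential map; a `t21` mode restricts to newly grown voxels
  only. Both give concordant results on synthetic cohorts.

This registers *masks*, not images: it recovers boundary-driven motion and
is blind to internal texture. For the alignment statistic — which only uses
growth directions in and around the tumor — that is sufficient, and it
makes the whole pipeline testable against closed-form fields.

## Synthetic cohorts

No patient imaging is distributable, so validation runs on simulated
cohorts with known ground truth.

**Fiber fields.** Unit eigenvector fields with uniform, radial, concentric,
or crossing geometry; each voxel's sign is randomized to emulate the
eigenvector sign ambiguity, and a `validity_fraction` knocks out voxels to
emulate atlas background.

**Tumor growth.** Masks grow from ball seeds by stochastic boundary
accretion: per step, each voxel adjacent to the mask joins with probability
`min(1, magnitude * w)`. The weight `w` compares the local accretion
direction — the outward surface normal, taken from the gradient of the
Gaussian-smoothed mask indicator (sigma 1.5 voxels) — with the regime's
preferred axis via `cos^2 psi` (along-fiber), `sin^2 psi` (perpendicular),
`((1+cos psi)/2)^2` signed (toward a world-coordinate target), or uniformly
(isotropic). Angular jitter (`noise_deg`, default 10 degrees SD) is added to
psi per candidate. The surface normal, rather than the direction from the
mask centroid, is used because the weight is meant to gate *local* boundary
advance; with centroid directions, perpendicular growth produces a thick
rounded rim whose normals spread over tens of degrees of tilt, washing out
the near-90-degree concentration that perpendicular growth should produce.

**Cohort defaults** (the study conditions for all shipped checks): 10
patients per region x 3 regions; ball seeds of radius 4-6 voxels placed
uniformly in fixed left-hemisphere bounding boxes standing in for the
temporomesial allocortex, insular mesocortex, and superior frontal
isocortex (anatomy is irrelevant to the statistics — only the grouping
matters); 20-60 growth steps at 0.3 mm expected boundary advance per step;
inter-scan intervals uniform on 14-1500 days (14 is the two-week inclusion
floor; the upper end reflects the years-long intervals seen in untreated
low-grade glioma cohorts). One master seed fans out to per-patient seeds
via `SeedSequence(master, spawn_key=(index,))`, so the entire cohort is
reproducible from one integer.

**What the simulation does not emulate:** MR acquisition and segmentation
noise, non-convex cortical geometry, biophysical (reaction-diffusion)
growth, mass effect on the fiber field, and registration error against real
anatomy. Passing tests therefore establish that the *pipeline* recovers
known directional regimes through its own registration and statistics — not
that any biological claim holds in real data.

## Numerical and convention choices

- **Canonical orientation.** All volumes are reoriented to RAS at read
  time (axis permutations/flips only, never resampling). Vector volumes
  carry components in world axes, so reorientation is a pure index
  permutation.
- **Grid harmonization.** A volume on a grid exceeding the analysis grid
  (e.g. the 182x218x182 atlas grid vs the 181x217x181 MR grid) is truncated
  by world-coordinate comparison against the target bounds — never by
  hard-coded trailing-slice removal — with retained voxels required to map
  to the same world coordinate within 0.1 mm. Spacing mismatches are
  errors; resampling is out of scope.
- **Mirroring.** Right-hemisphere tumors are reflected across the
  midsagittal plane so the cohort shares one hemisphere; vector fields also
  negate their left-right component. Requires a grid symmetric about the
  plane to within half a voxel; the operation is an involution (tested).
- **Binarization.** Probabilistic segmentations are thresholded at 0.5.
- **Overlap conventions.** Empty-vs-empty masks score Dice = Jaccard = 1;
  empty-vs-nonempty scores 0.
- **Histogram.** 18 bins of 5 degrees on [0, 90], density-normalized, so
  the 0-20-degree alignment band is bin-aligned.
- **Degenerate inputs.** Empty masks are rejected by registration and
  growth; a cohort in which no voxel passes the magnitude filter produces
  an explicit "no growth" result rather than an error.

## Known limitations and observed artifacts

- **Discretization bias of pooled angles.** On an integer lattice, exact
  radial direction fields already deviate slightly from the continuum sine
  law (the top 5-degree bin is depleted by ~3% relative to the adjacent
  bin), and registration adds its own smoothing. Isotropically grown
  synthetic cohorts therefore show `h` within about 0.003 of `p0 = 0.0603`
  rather than exactly at it; with hundreds of thousands of pooled voxels
  this is a statistically visible (if practically negligible) deviation.
  The type-I-error calibration of the binomial test itself is checked with
  continuum-sampled directions, where it holds at nominal level.
- **Registration accuracy on elongated shapes.** Warped-mask Dice on
  strongly anisotropic synthetic tumors is typically 0.8-0.9, lower than
  on spheres (~1.0). The recovered *directions* remain accurate enough for
  the angle statistic (the regime signatures separate by orders of
  magnitude in `h`), but per-voxel magnitudes on thin protrusions are
  smoothed.
- **Scale.** All shipped checks run at desk scale (the full 181x217x181
  template grid with 30-patient cohorts completes in minutes on one core,
  because every per-patient operation is cropped to the tumor
  neighborhood). Cohort sizes and tumor extents are package defaults chosen
  for stable angle histograms, not fitted to any dataset.
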