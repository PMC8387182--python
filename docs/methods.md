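# Methods

`asdmetry` implements a complete "virtual measurement" chain for atrial
septal defects (ASD) in 3D echocardiography: simulate the acquisition of a
known digital heart, reconstruct and clean the volume, segment the blood
pool, and measure the defect — then ask how well the measured sizes track
the truth. This note records the models, the parameters that matter, and
the design choices made where the design was genuinely open.

## The phantom

The phantom is the simplest geometry that carries the quantities under
study: a spherical blood-filled chamber (radius `chamber_radius`, default
14 mm) embedded in a solid block of echogenic tissue, split into two
"atria" by a planar septum slab (`septum_thickness`, default 3 mm) with an
elliptical through-hole of full axes `defect_long` × `defect_short` at
orientation `defect_angle`. A `wall_thickness` shell (3 mm) marks the
myocardium proper in the label volume; the tissue block outside shares the
myocardial gray level (180) against blood at 30, so the image is a genuine
two-class problem while labels still distinguish background. Default grid:
120 × 120 × 64 voxels at 0.5 mm.

What the phantom does **not** model: chamber anatomy, valve and wall
motion, ECG gating, beam physics (point-spread anisotropy, attenuation,
shadowing). Passing tests therefore demonstrate the numerical chain
recovers geometry under speckle-like noise — not performance on clinical
images.

## Acquisition simulation

*Rotational (TTO-style)*: a `slice_width` × `slice_depth` planar image
(default 240 × 128) is resampled trilinearly from the volume at rotation
angles `i · angular_step` about the central depth axis; steps of 1/2/3°
give 180/90/60 slices, each spanning the full diameter so 180° of plane
angles covers the full 360° sweep. *Full volume*: four 15° azimuthal
wedges (0–60°) are produced independently, each with its own noise stream
and an optional rigid in-plane jitter (`jitter_mm`) standing in for
inter-cycle misalignment.

Speckle is multiplicative unit-mean Gamma noise — `pixel ← pixel · n`,
`n ~ Gamma(k, 1/k)` with `sd = speckle_sigma` — followed by salt-and-pepper
impulses (`impulse_prob`) and quantisation to `gray_levels` (256). The
defaults `speckle_sigma = 0.3`, `impulse_prob = 0.01` are the fixed study
conditions: strong enough that raw thresholding fails visibly, consistent
with envelope statistics of coherent imaging. Gamma was preferred over
truncated-Gaussian multiplicative noise for positivity and right skew.

## Scan conversion

Each output voxel of the `W × W × D` grid maps to polar coordinates
(signed radius `R`, angle `alpha ∈ [0°, 180°)`, exact row `z`); the value
is bilinear in `(alpha, R)` between the two bracketing slices, with the
wrap at 180° interpolating against slice 0 with `R` negated (the same
plane mirrored). Outside the scanned disc the volume is 0. Bilinear
weights are convex, so the output range never exceeds the input range, and
inputs constant along the angle reconstruct exactly; on a smooth radial
profile the reconstruction error is far below one gray level, and it
decreases monotonically as the angular step shrinks 3° → 2° → 1°.

## Despeckling

Single scale: the explicit scheme

    u ← u + dt · [ div( c(|∇u|) ∇u ) + gamma · (med(u) − u) ]

with Perona–Malik conductance `c(s) = 1/(1 + (s/kappa)²)`, face-flux
differencing (exact mean conservation for `gamma = 0` under zero-flux
boundaries), and a 3³ median attachment. Stability requires
`dt ≤ 1/(2·ndim)`; defaults `dt = 0.125`, `kappa = 15` gray levels,
`gamma = 0.5`, 20 iterations (the pipeline uses 10 — see below). The
update is a convex combination of neighbour values and the local median,
so the output range is contained in the input range.

Two-resolution variant: the volume is downsampled by 2, filtered there
(speckle blobs shrink toward single-voxel impulses, which the median term
removes cheaply), the fine-scale detail residual is re-added, and a
half-length diffusion pass finishes at full resolution. On spatially
correlated speckle this beats the single-scale filter at an equal total
iteration budget; on strictly i.i.d. voxel noise it does not — correlated
speckle is the regime the scheme targets. Filter quality is scored as the
sample standard deviation of gray levels over a homogeneous region
(`histogram_width`): narrower after filtering means less residual noise.

## Segmentation

Fuzzy c-means on gray levels (computed on the histogram — identical to
per-voxel FCM and much faster on quantised data) yields memberships
`u ∈ [0, 1]` for two clusters; the darker centroid is the blood pool by
default. The membership field is used twice:

* **Initialisation** `phi0 = −c0(2u − 1)` (`c0 = 2`): the contour starts
  essentially on the fuzzy boundary, so few evolution iterations are
  needed — in paired runs the membership start reaches Dice 0.90 in
  strictly fewer iterations than a cold box start.
* **Stop function** `S = g · (1 − 4u(1−u))` with the edge indicator
  `g = 1/(1 + |∇(G_sigma * I)|²/kappa_g²)` (`sigma = 1.5` voxels,
  `kappa_g = 5` gray levels): S vanishes at strong edges *and* where the
  fuzzy classification is ambiguous, and a single S field weights both the
  length and area terms.

The evolution is the distance-regularised flow

    phi_t = mu · div(dp(|∇phi|) ∇phi)
          + lam · delta_eps(phi) · div(S ∇phi/|∇phi|)
          + nu · S · delta_eps(phi)

where `dp = p'(s)/s` comes from the double-well potential (minima at
`s = 0` and `s = 1`). Near `s = 1` this matches the classical
`Δphi − div(∇phi/|∇phi|)` penalty that keeps `|∇phi| ≈ 1` without
reinitialization; in flat regions it stays forward-diffusive, where the
single-well form is anti-diffusive and blew up from the binary-step start
in 3D. Stability needs `mu·dt ≤ 1/(2·ndim)` (checked at run time against
the input dimension); defaults `mu = 0.03`, `dt = 5`.

Weights were chosen against the phantom's defining structure, the thin
septal neck: heavy length weighting (`lam ≈ 5`) drives a mean-curvature
widening of the hole (the in-plane convex curvature is outweighed by the
concave across-slab curvature), and a strong area term run long enough
pushes through weak edges and collapses the cavity entirely. The package
defaults are deliberately light — `lam = 0.5`, `nu = 1.0` (positive sign:
shrink from outside), `epsilon = 1.5`, 60 iterations standalone and 20 in
the measurement pipeline, where the FCM initialisation has already done
most of the work. The discretised energy is tracked every iteration and is
non-increasing within `1e-6·|E0|` in the tests; after evolution the mean
`|∇phi|` over the `|phi| ≤ epsilon` band stays in [0.8, 1.2].

## Measurement

The cavity mask is resampled (bilinear) on each atrial face of the septum
slab — the slab surface nudged one voxel inward, clear of the
partial-volume layer. Connected components are labelled; the through-hole
is the component containing the septum centre, falling back to the largest
component not touching the sampling border (the dark ring outside the scan
sector always touches it). Its traced contour is smoothed by a circular
moving average over a ~1.5-voxel arc: max-type statistics on a voxel
staircase are biased outward, and this smoothing removes that bias without
moving the mean boundary. The rim is then projected on its least-squares
plane (SVD); **long diameter** is the maximum Feret diameter over the
convex hull, **short diameter** the minimum Feret width by rotating
calipers, **area** the shoelace polygon area — planar-projected, not
geodesic. An intact septum returns an explicit no-defect result rather
than raising.

Surfaces for export are extracted by marching cubes on a Gaussian
pre-smoothed (sigma = 1 voxel) copy of the binary field: the iso-surface
then sits at sub-voxel positions and a voxelised 10 mm sphere's area is
within 0.5% of 4πr², versus ~+9% for raw binary extraction. Structures so
thin that smoothing erases them are extracted from the raw field instead.

## Validation statistics

Per metric and face, the study pairs ground truth ("real" arm — the
stand-in for caliper measurement) with pipeline output ("virtual" arm) and
reports n/min/max/mean/sample-SD per arm plus Pearson `r` and `L`, the
two-sided p-value of the t-test of zero correlation on n−2 degrees of
freedom (`L < 0.05` read as a meaningful association). The replication
study draws long diameters uniformly on 6–14 mm, short/long ratios on
0.45–0.95 and orientations on 0–180°, runs the full pipeline per model,
and emits summary/agreement tables. All randomness derives from one seed.

At the default conditions (10 models, 120×120×64 at 0.5 mm, 1° step,
default speckle) the recovered long diameter correlates with truth at
r ≈ 0.99; per-measurement errors stay within ±10% for diameters and ±15%
for area across the 6–14 mm range. Module-level study invariants
(noise-degradation of r, determinism) run at a reduced size — 80×80×48,
3° steps, 6 models — chosen to exercise the same code paths at a fraction
of the cost.

## Diagnosis module

Naive Bayes on categorical records: additive smoothing (default 1) for
priors and per-feature conditionals, log-space scoring, posteriors
normalised by the evidence. With zero smoothing an unseen value emits a
zero-probability warning, and if every class is annihilated the priors are
returned. Continuous features can be discretised by equal-frequency
binning.

The genetic algorithm searches binary feature masks. Fitness is k-fold
cross-validated accuracy mapped through a sigmoid; both sigmoid
orientations are provided because the decreasing form `1/(1+e^a)` appears
in print, but selection must reward accuracy, so the GA defaults to the
increasing form. Selection copies individuals by rounded expected counts
`round(N·f_x/Σf)` with largest-remainder correction (population size exact
by construction), then one-point crossover (p = 0.8), bit-flip mutation
(p = 0.02 per bit), empty-mask repair, and single-elite preservation —
which makes the best-so-far fitness trace monotone. Population 30,
generations 50 by default; the tests use smaller settings that already
select the informative feature on synthetic data.

## Degenerate inputs and numerical guards

Constant volumes: rejected by FCM (undefined distances), fixed points of
the filter. Defect axes of zero produce an intact septum (two disconnected
blood pools) and a no-defect measurement. A defect that does not fit the
septum footprint, a non-odd median window, an unstable `dt`, a non-{1,2,3}
angular step, fewer or misordered DICOM elements, unknown file extensions
and empty meshes all raise typed errors that the CLI maps to exit codes
2/3/4. NaNs appearing during level-set evolution abort with the iteration
index.

## Known limitations

* The phantom's septum is planar and the defect elliptical; irregular rim
  shapes are exercised only via the generic polygon metrology tests.
* The level-set weights are tuned for thin-slab geometry at ~0.5 mm
  voxels; markedly different spacings warrant re-tuning `kappa_g` and the
  iteration budget.
* The full-volume path models wedge misalignment as rigid in-plane shift
  only; no motion correction is attempted.
* Tables of the companion diagnosis component are synthetic; no clinical
  claim attaches to it.
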