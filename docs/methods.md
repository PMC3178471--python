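# Methods

## Problem and model

At an arterial bifurcation a parent vessel of radius `r_CCA` splits into
daughters `r_ICA` and `r_ECA` (the common, internal and external carotid
arteries in the application this package targets).  The junction exponent
`n` is defined by the power law

    r_CCA^n = r_ICA^n + r_ECA^n .

Two values carry physical meaning: `n = 2` preserves luminal
cross-sectional area (constant mean velocity through the junction), and
`n = 3` is the minimum-work optimum.  The latter follows from minimising,
per unit vessel length, the sum of the Poiseuille pumping power
`8 mu Q^2 / (pi r^4)` and a metabolic cost `b pi r^2` proportional to the
blood volume maintained; the stationary radius satisfies `Q ∝ r^3`, and
flow conservation then forces the cube law at every junction.  The model
assumes steady laminar Poiseuille flow in straight rigid tubes and a
volume-proportional metabolic cost; pulsatility, wall elasticity and
reflection losses are outside it (and outside this package).

`murray_optimal_radius` implements the closed form
`r* = (16 mu Q^2 / (pi^2 b))^(1/6)`;
`murray_optimal_radius_numeric` finds the same optimum by Brent
minimisation over log-radius followed by a bracketing root-find of the
stationarity condition `dE/dr = 0`.  The polish step exists because a
value-based minimiser alone cannot do better than ~sqrt(machine epsilon)
in the flat bottom of the cost; the derivative root-find restores full
double precision while remaining a numerical (not algebraic) solution,
so the closed form can be cross-checked rather than assumed.

## Geometry pipeline

The imaging half of the package consumes binary vessel masks on regular,
possibly anisotropic voxel grids (world coordinates in mm, origin at the
mask corner, array axes = world axes).

**Distance map.**  `scipy.ndimage.distance_transform_edt` with the voxel
spacing as sampling; the value at a centerline point is the radius of the
maximally inscribed sphere centred there.

**Centerlines.**  Minimal-cost paths on the 26-connected voxel graph with
edge cost `step_length / (1 + D(target))`, `D` the distance map.  The
denominator rewards steps into the lumen interior, so shortest paths run
along the medial axis; the +1 keeps costs finite at the boundary.  Voxel
paths are resampled at 0.5 x min(spacing) and smoothed with a 5-point
moving average (edge-replicated).  Tortuosity `(L/D) - 1` is computed on
this smoothed, resampled polyline — `L` depends on discretisation, so the
convention matters and is fixed here.

**Bifurcation splitting.**  Both daughter paths are traced from the
parent's free end in a single Dijkstra pass.  Two failure modes of the
naive "last shared voxel" rule shaped the design.  First, inside a wide
parent lumen many equal-cost paths coexist, so the shortest-path tree can
branch long before the junction while both paths still follow the axis in
adjacent voxel lanes; the trunk is therefore identified on the smoothed
paths as the region where they stay within one voxel diagonal of each
other.  Second, past the geometric junction both paths hug the centre of
the merged lumen, so the last close point systematically overshoots into
the daughters by about one parent radius worth of arc.  The reported
bifurcation point is therefore refined geometrically: a straight line is
fitted (total least squares) to the first well-separated ~8 mm of each
daughter path and the midpoint of the two lines' closest approach is
taken, falling back to the last close point if either clean segment is
missing or the lines are near parallel.  On phantoms this reduces the
localisation error from ~2 mm to ~0.4-0.7 mm.  All three branch curves
are rebuilt to share the refined point as their terminus, so arc lengths
used by the measurement windows start at the junction.

**Radius measurement.**  Method A reads the distance map along the
centerline (inscribed-sphere radius; underestimates non-circular lumens).
Method B estimates the lumen area in the plane perpendicular to the local
tangent — central differences on the smoothed curve, a square sampling
grid of pitch 0.2 x min(spacing) and extent 4 branch radii, trilinear
mask interpolation thresholded at 0.5 — and reports the equivalent radius
`sqrt(A/pi)`.  The two agree on circular sections; B exceeds A on
elliptical ones (inscribed circle = minor semi-axis vs `sqrt(ab)`).

**Measurement windows.**  Branch summaries follow per-artery windows
expressed in units of the branch's own radius: parent radius read at 2
units from the junction; ICA as the median over 6-12 units (skipping the
carotid sinus); ECA as the median over 2-7 units (skipping its downstream
branching).  The "unit" is circular if taken literally, so it is fixed
operationally as the median method-A radius over the branch's full
profile, computed once before windowing — stable and deterministic.
Medians over an even sample count are the mean of the middle two.
Profiles are sampled at every resampled centerline point
(0.5 x min(spacing)).

## Phantoms and synthetic cohorts

No clinical CTA segmentations ship with the package; phantoms with
analytic ground truth exercise every imaging stage.  A voxel belongs to a
phantom iff its centre lies within the local tube radius of the sampled
centerline (voxel-centre inclusion, no partial volume — the same contract
assumed of input masks).  Tubes may be bent sinusoidally
(`y = A sin(2 pi t / L)`) to set tortuosity; bifurcations are unions of
three constant-radius tubes meeting at a point, with no fillet at the
junction (the measurement windows avoid it by construction), an optional
carotid-sinus bulge on the ICA confined to arc lengths [0, 5 r_ICA]
(a sin^2 bump peaking at `bulge_factor x r_ICA`), and default branch
lengths of 14 radii so every window fits.  Default spacing is the
CTA-like anisotropic (2, 0.5, 0.5) mm; accuracy-critical tests also use
0.5 mm isotropic grids.  Phantoms are deliberately clean: no greyscale,
no segmentation noise, no wall irregularity, no junction fillet.
Passing tests therefore demonstrate correctness of the measurement
chain on known geometry, not robustness to segmentation error in real
angiograms.

Cohort tables are generated per subject and side: ICA/CCA and ECA/CCA
ratios from truncated normals on (0, 1) with means/SDs 0.67 (0.074) and
0.61 (0.087) (the published method-A cohort values; correlation between
the two ratios defaults to 0 and is exposed), and the absolute CCA radius
from a lognormal with median 4 mm and log-SD 0.15 — published tables
report only ratios, so the absolute scale is this package's choice of a
typical adult common carotid; only ratios enter the power law.  With
`exact_exponent = n*` both daughter ratios are rescaled by
`(a^n* + e^n*)^(-1/n*)` so the law holds exactly (to ~1e-15 relative);
`noise_sd` then applies independent multiplicative Gaussian jitter to
each radius.  ICA tortuosity is drawn from a lognormal with median 0.122
and log-SD 0.5, calibrated so roughly a third of sides fall under the
0.1 straightness threshold, matching the proportion reported for the
clinical cohort.

## Exponent estimation

**Per bifurcation.**  With `a = r_ICA/r_CCA`, `e = r_ECA/r_CCA` in
(0, 1), `g(n) = a^n + e^n - 1` is strictly decreasing from +1 toward -1,
so the root is unique; it is found by Brent's method in the bracket
(0.05, 50) at tolerance 1e-10.  If a daughter is at least as large as the
parent there is no positive root and the record is flagged `no_root`;
such records are excluded from averages and counted, never imputed.
The solver is scale invariant (only ratios enter).

**Cohort regression.**  A single exponent is fitted by Gauss-Newton with
step halving (start 2.0, relative tolerance 1e-8, max 50 iterations) in
either of two model forms, because the two weight the data differently
and their discrepancy on noisy cohorts is itself of interest:
`parent_radius` (default) fits `r_CCA,i = (r_ICA,i^n + r_ECA,i^n)^(1/n) + eps`;
`power_sum` fits `r_CCA,i^n = r_ICA,i^n + r_ECA,i^n + eps`.
The mean of per-bifurcation roots is reported alongside; on noiseless
exact cohorts both estimators agree with the generating exponent to
1e-6, while under noise they separate (a Jensen-type gap plus different
weighting) — mirroring the gap between cohort-level and mean-individual
estimates reported for the clinical data.

**Confidence intervals.**  Default is the linearised standard error with
a Student-t quantile; a seeded case-resampling bootstrap (percentile,
2000 resamples) is available because linearised intervals on scalar
nonlinear fits can be poor.  Calibration caveat: when measurement noise
enters all three radii, the daughters are noisy predictors and the fit
is an errors-in-variables problem; simulation shows ~85-90% empirical
coverage for nominal 95% intervals at 5% relative noise (linearised,
sandwich and bootstrap alike), with a small upward bias of the estimate.
With noise confined to the parent radius (the model's response) coverage
is nominal (~95-98%).  Interval widths should therefore be read as
slightly optimistic for jointly noisy radius measurements.

**Other outputs.**  The ICA adjustment
`100 ((r_CCA^n - r_ECA^n)^(1/n) - r_ICA)/r_ICA` quantifies how much the
ICA would need to change, holding the other radii fixed, to satisfy the
law at a given `n`.  Ratio summaries are means of per-record ratios (not
ratios of means); the junction area ratio is reported under both the
quadratic definition `(r_ICA^2 + r_ECA^2)/r_CCA^2` and the radius-sum
definition `(r_ICA + r_ECA)/r_CCA` — the latter is the convention that
reproduces published carotid bifurcation tables.  Left/right asymmetry
is tested with paired t-tests on ICA radius and exponent; identical
sides are reported as t = 0, p = 1 rather than undefined.  The
low-tortuosity subset uses a strict `< 0.1` cut on ICA tortuosity.

## Numerical choices and problem sizes

Voxelisation samples centerlines at 0.4 x min(spacing); distance from a
voxel centre to the sampled polyline then approximates distance to the
curve far below voxel size.  Dijkstra runs once per bifurcation over the
explicit sparse voxel graph (~10^4-10^5 vessel voxels for the phantom
sizes used).  Analyses and tests use 45-subject (90-bifurcation) cohorts
— the scale of the clinical study — and phantom grids of at most a few
hundred thousand voxels; the full test suite completes in about a
minute on one core.  Degenerate inputs fail loudly with named causes:
empty masks, markers outside or disconnected from the vessel, coincident
path endpoints, branches shorter than their measurement window, cohorts
with non-positive radii.

## Known limitations

- Method B assumes a locally planar, simply connected cross-section; at
  sharp junctions the perpendicular plane can clip a neighbouring branch
  (the measurement windows avoid these regions).
- The junction refinement fits straight lines to the proximal daughters;
  strongly curved daughters within ~8 mm of the junction would bias it
  toward the fallback behaviour.
- Exponent CIs under-cover when all radii are noisy (errors-in-variables;
  see above).
- Phantom realism: no partial-volume, intensity or segmentation noise;
  conclusions about real CTA robustness require real segmentations.
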