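# Methods

## The metric

A deformable registration solution is a displacement field
u(x) = (u, v, w) in millimetres on a regular voxel grid with per-axis
spacing, origin and an orthonormal direction matrix. The QA quantity is
the curl

∇ × u = (∂w/∂y − ∂v/∂z, ∂u/∂z − ∂w/∂x, ∂v/∂x − ∂u/∂y),

the local rate of microscopic rotation of the field. The underlying
physical assumption is that organs are solids that deform smoothly:
compression, inflation and bulk displacement are all (near-)curl-free,
while spinning or tearing voxel motion — which no plausible anatomy
performs — produces localised curl. The metric is a property of the
solution alone and is independent of the algorithm that produced it.

### Discretisation

Partial derivatives use second-order central differences
(f[i+1] − f[i−1]) / 2h at interior voxels and first-order one-sided
differences at the two boundary slabs, with h the physical spacing of
the axis in mm. Consequences that the tests rely on:

- exact on fields affine in the coordinates, everywhere including
  boundaries — so the calibration field u = ω × r yields a vortex map
  identically 2|ω| on any anisotropic grid;
- central differences are exact on quadratics, so gradient fields of
  quadratic potentials are curl-free to rounding in the interior (the
  one-sided boundary stencils are only first-order there);
- anisotropic spacing is honoured per axis.

The derivative kernel is `numpy.gradient` with `edge_order=1`, which
implements exactly this scheme; the test suite pins the behaviour
against a hand-written triple-loop evaluation (≤ 1e-12) rather than
trusting the library.

### Units

Displacements are stored in mm and differentiated over mm positions, so
the curl — and everything derived from it — is **dimensionless**. Band
thresholds and reported statistics are therefore unitless numbers even
though they are sometimes colloquially quoted with mm attached in
clinical discussion of displacement-field QA. A CLI flag
(`--field-units voxels`) converts voxel-unit fields to mm on load by
multiplying each component by its axis spacing.

### Vortex map and statistics

The vortex map is the voxelwise Euclidean norm of the curl vector. The
norm (rather than any single component) is used because it is invariant
to rigid reorientation of the patient axes; a 90°-axis-permutation test
asserts this exactly. Curl *vectors* are reported in the image axis
frame; derivative computation works in index space scaled by spacing, so
no resampling ever happens for non-identity direction matrices.

Statistics over the map (optionally within a mask) are min, max, mean
and the 99th percentile (linear interpolation between order statistics).
The maximum is the primary reported value; p99 is added because the max
is a single-voxel statistic and fragile to isolated speckle.

NaNs are rejected at container construction rather than propagated:
every field and map is finite by invariant, so there are no silent holes
in any statistic.

## Hotspot detection and plausibility

Visual "vortex identification" is operationalised as thresholded
connected components: voxels with map value strictly above a threshold
(default 5.0, the nonphysical band edge) are labelled at 26-connectivity
(6 available), components below 3 voxels are discarded as speckle, and
each region is summarised by voxel count, physical volume, peak value
and position, and intensity-weighted centroid in mm. Region lists are
sorted by peak descending with ties broken by ascending scan-order
label, for determinism.

The global verdict is a pure function of the vortex-map maximum:

| category    | condition                       | default |
|-------------|---------------------------------|---------|
| plausible   | max < borderline_min            | 3.0     |
| borderline  | borderline_min ≤ max < valid_max| 5.0     |
| nonphysical | max ≥ valid_max                 |         |

These defaults encode observed clinical behaviour (valid solutions
0–5, nonphysical 5–10, trouble above 3). A global band cannot capture
location: hotspots far from the target and critical structures may be
clinically acceptable. `structure_report` therefore gives, per named
structure mask, the peak map value inside the mask, whether any detected
region intersects it, and the minimum region-centroid-to-mask distance
(mm, via an exact Euclidean distance transform with anisotropic
sampling; infinite sentinel when no regions exist). The classification
stays band-based; the location-based judgement is surfaced, not
automated. Whether the bands should apply to per-region peaks instead of
the global maximum is an open design point; the global maximum was
chosen as the more conservative reading.

## Synthetic data

The generators define the study conditions under which the package is
validated; they are first-class, tested code.

**Phantom** (`make_phantom`): constant-HU cylinder and cube inserts on a
−1000 HU (air) background, default spacing 1 × 1 × 2.5 mm (a typical CT
slice thickness), voxel-centre inclusion rule (deterministic, testable
counts: a cylinder's voxel count matches πr²h/Δz within 3%). Modelled on
commercial rigid QA body phantoms. It deliberately omits CT physics:
no noise, no partial-volume blur, no scatter.

**Analytic fields**: translation, rigid rotation ω × (r − c), compact
radial expansion m·(r − c)·max(0, 1 − |r − c|/R) (the simplest
tumour-growth/shrinkage surrogate that is identity far away; linear
falloff), and gradients of quadratic potentials (curl-free by
construction). Each has closed-form curl against which the
implementation is verified.

**Random smooth fields** (`bspline_random_field`): node displacements
drawn uniformly in [−A, A] per component on a coarse lattice (node
spacing ≥ 2 voxels), interpolated to the voxel grid by cubic B-splines —
the parametric registration model in miniature. Wider node spacing =
stronger regularisation; a paired-seed test asserts the vortex maximum
never increases when the lattice coarsens. Bit-reproducible given a
seed.

**Defect injection** (`inject_vortex`): adds ω × (r − c) · (1 − t²)²
with t = |r − c|/radius. The bump has a flat top, so the curl at the
centre is exactly 2ω, and vanishes with its derivative at the support
edge. This is the ground-truth "unnatural rotation" used in recovery
tests: strength 2|ω| = 8 over radius 8 mm on a background field with
baseline max curl < 2.

**Artifacts** (`inject_artifact`): a crosshair streak (two orthogonal
in-plane lines of given arm length/width/HU on one slice) and an
HU-offset (constant shift inside a mask) — the two corruption modes that
make cone-beam CT violate the intensity-constancy assumption of
monomodality registration.

**Warping** (`warp_image`): backward warping output(x) = image(x + u(x))
with nearest or linear interpolation; out-of-volume samples take the
background value (image minimum by default). `invert_field` provides a
fixed-point approximate inverse used as a round-trip oracle.

**Demons fixture** (`demons_register`): plain Thirion-style demons — per
iteration the force
Δu = (f − m∘(id+u))·∇f / (|∇f|² + (f − m∘(id+u))²),
zeroed where the denominator < 1e-9 (standard stabilisation against
division blow-ups in flat regions), accumulated into u, with optional
Gaussian smoothing of each component after every iteration as the
regulariser. Deterministic; no multi-resolution, no diffeomorphic
(exponential-map) update. The sign convention follows from the backward
warping model: with m = f shifted by t, the force contracts u toward t.
A full diffeomorphic implementation is out of scope on purpose — the
metric is algorithm-independent, and the fixture only needs to produce
realistic smooth-versus-jagged field contrasts, which it does: the
smoothing-on/off comparison changes the vortex maximum by an order of
magnitude on the translated-sphere fixture.

The translated-sphere recovery fixture uses *soft-edged* spheres
(Gaussian-blurred boundaries, σ = 2 mm): a hard binary sphere has
intensity gradients only in a single voxel shell and constant interior,
so demons forces never reach the interior and recovery is poor — the
blur emulates a real soft-tissue boundary and is the condition under
which the fixture recovers ~80–85% of a 3 mm translation inside the
sphere (asserted within 30%).

## Phantom QA protocol (`phantom_study`)

A scaled-down, fully synthetic version of a registration QA experiment,
at 64³ voxels, 1 × 1 × 2.5 mm:

- moving volume: three inserts (cylinder r 8 mm HU 0, cube side 12 mm
  HU 100, cylinder r 9 mm HU 50);
- fixed volume: the first two inserts expanded by ~2 mm (genuine
  "anatomical" change the registration should model), plus a crosshair
  streak (arm 10 voxels, HU 500) and a +300 HU offset on the third
  insert — intensity defects with no corresponding motion;
- registration: 80 demons iterations *without* field smoothing (the
  weakly regularised regime in which vortex defects develop);
- scoring: vortex map, region detection at threshold 5, and peak map
  values inside the artifact masks dilated by 3 voxels versus inside the
  (dilated) cleanly-expanded insert masks.

Expected and observed behaviour: the two highest-peak regions sit inside
the artifact masks (the registration invents rotational motion to
conjure intensity from nowhere), while genuine expansion — though it
also stresses the solver, particularly at cube corners — stays clearly
below both artifact peaks. Sizes were chosen to keep all deformations
under ~10 voxels and the whole protocol in a few seconds.

## Problem sizes and tolerances

Calibration identities run at 64³ (tolerance 1e-10 absolute); oracle
comparisons at 16³ over 10 seeds (1e-12); defect recovery at 48³ over 10
seeds; demons contrasts at 48³ with 40 iterations over 5 configurations;
the phantom protocol at 64³ with 80 iterations. I/O round trips assert
1e-6 agreement (the formats store float32 by default in some dialects;
all tested paths preserve float64 exactly, 1e-6 is the contract).

## Known limitations

- The curl sees rotation only: volume-folding defects with negative
  Jacobian determinant but low vorticity are invisible to this metric
  (Jacobian maps are a complementary, out-of-scope check).
- Band thresholds derive from a small number of clinical observations
  and are exposed as parameters, not validated cut-offs.
- The demons fixture is monomodality and single-resolution; it is a
  test-bed for the metric, not a clinical registration.
- The synthetic phantom has no noise or scanner physics, so passing the
  protocol shows the metric localises *induced* defects, not that the
  bands transfer to any particular scanner or site.
- Grids must match between field, anatomy and masks; resampling is the
  caller's job.
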