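# Methods

## Problem setting

In an MRI-only radiotherapy workflow the planning CT is replaced by a
synthetic CT (sCT) generated from MRI, and the reference images used
for daily patient positioning — the reference volume matched against a
cone-beam CT (CBCT), or the digitally reconstructed radiographs (DRRs)
matched against orthogonal kV projections — derive from that sCT.  The
question this package's pipeline evaluates is whether sCT-based
positioning yields the *same couch correction* as CT-based positioning:
for each case the correction is computed twice, once against each
reference, and the paired difference (sCT-based minus CT-based, sign
preserved) is analysed per direction.

No patient imaging ships with the package.  The synthetic-data module
generates every input with known ground truth, so each downstream
stage is testable against an analytic oracle; what passing tests
demonstrate about real data is discussed at the end.

## Coordinate and parameter conventions

Right-handed LPS-like patient axes everywhere: x along right→left
(R-L), y along anterior→posterior (P-A), z along inferior→superior
(I-S); all coordinates in mm, voxel arrays indexed `[ix, iy, iz]` with
`world = origin + index * spacing` at voxel centres.

A setup correction is a `SixDoF`: translations tx, ty, tz (mm) and
rotations pitch (about R-L), yaw (about P-A), roll (about I-S) in
degrees.  The homogeneous matrix is built as extrinsic rotations about
the fixed patient axes, composed `Rz(roll) · Ry(yaw) · Rx(pitch)`,
applied about an explicit rotation centre (the plan isocenter; the
volume centre when unstated), followed by the translation.  Clinical
systems do not publish their rotation-order convention; at the ≤2°
magnitudes of setup corrections the order changes point positions by
under 0.01 mm, but one order must be fixed for matrices to compose and
compare — this one is used consistently by every module and test.
Degrees at all interfaces, radians internally.  Near yaw = ±90° the
Euler decomposition is gimbal-degenerate; `params_from_matrix` warns
and returns one valid solution (setup corrections never approach this).

2D orthogonal-projection positioning cannot correct roll;
`restrict_to_5dof` pins it to exactly 0, and all 5-DoF code paths
return roll = 0 identically.

## The phantom and its surrogates

The head-and-neck phantom is a soft-tissue ellipsoid (default semi-axes
70 × 80 × 90 mm, 40 HU) in a −1000 HU air background, containing three
kinds of analytic bone solids (900 HU, inside the clinical 200–1700 HU
bone window): a skull-like spherical shell (radii 44–50 mm), five
stacked cylinders for the cervical vertebral column (radius 10 mm,
10 mm high, 2 mm gaps, posterior of centre), and a mandible-like
anterior half-annulus slab (radii 35–45 mm, 14 mm high).  The solids
are mutually disjoint and strictly inside the body, so the total bone
volume is the plain sum of closed-form solid volumes — the oracle for
rasterization tests.  Solid end-planes deliberately avoid the default
voxel-centre lattice: an end plane coinciding exactly with voxel
centres double-counts that plane and biases the voxelized volume by a
full voxel layer.

The default grid is 128 × 128 × 96 at 1.5 × 1.5 × 2.0 mm, echoing the
clinical pattern of finer in-plane resolution than slice thickness;
registration tests use coarser grids (96³ at 2 mm; 48³ at 4 mm for
unit tests) to bound runtime — parameters, not code paths, change with
problem size.

The sCT surrogate models the qualitative defects seen in CNN-generated
synthetic CT — softer, blurrier bone — as a minimal three-parameter
degradation: bone voxels (≥200 HU) pulled toward soft tissue by a
contrast scale s ∈ (0, 1] (`v → 40 + s·(v − 40)`), Gaussian blur with
σ in mm, and additive Gaussian HU noise.  Defaults are s = 0.8,
σ = 1.5 mm, 15 HU.  No quantitative intensity-error model of real sCT
is claimed; these are free surrogate knobs, and the registration
recovery tests characterize the engine's tolerance to them rather than
any particular sCT product.

Eight labelled landmarks sit on bone features (mandibular condyles,
mastoid region, mentum, spinal-canal points at two vertebral levels,
hyoid region), with a configurable `LandmarkDefinition` list mapping
"horizontal"/"vertical" clinical measures onto RL/IS axis differences
or Euclidean separations.

## Registration

The protocol mirrors bone-based clinical practice.  The reference
image is thresholded to 200–1700 HU inside an optional volume of
interest; the resulting mask is dilated by 2 voxels (configurable)
before metric evaluation, because on a near-piecewise-constant image
the bone/soft-tissue *edges* — not the bone interior, which is nearly
uniform — carry the alignment information.

Similarity is mutual information in nats, MI = H(A) + H(B) − H(A,B),
from a dense joint histogram (64 bins per channel by default) over the
masked reference voxels paired with trilinear samples of the moving
image at the transformed positions; samples falling outside the moving
grid are excluded rather than padded.  Inside the optimizer the moving
intensities are *soft-binned*: each sample is split linearly between
its two neighbouring bins (partial-volume interpolation).  With hard
binning the metric is piecewise constant over transform changes that
do not push any sample across a bin edge — on the piecewise-constant
phantom these plateaus are ~0.3 mm wide and stall the simplex well
above the intended 0.1 mm accuracy; soft binning restores a smooth
response at negligible cost.  The public `mutual_information` function
keeps the plain dense-histogram definition, which is also what the
acceptance checks of MI properties use.

Optimization is deterministic Nelder–Mead (downhill simplex) from an
explicit initial simplex with 2 mm / 1° steps, converged at 0.01
(mm/degrees) parameter and 1e−6 nats function tolerance, restarted
once from the incumbent with halved steps.  An optional 2-level
multi-resolution schedule (×2 downsampling) widens the capture range;
it is off by default and unit tests run single-level.  Fixed inputs
and configuration give bit-identical results.

2D positioning drives five volume DoF through re-projection: the
candidate transform moves the volume, parallel-ray attenuation-sum
projections (attenuation ∝ max(HU + 1000, 0), frontal along P-A,
lateral along R-L) are recomputed, and the summed MI against the two
acquired projections is maximized.  Both views are coupled in a single
correction, as in a clinical couch shift; divergent-beam (point
source) DRR geometry is out of scope.  No claim of equivalence to any
commercial implementation is made — binning, sampling and simplex
settings of clinical systems are proprietary; this is protocol-level
fidelity.

## Difference statistics and equivalence testing

`dof_differences` produces a long-format table of sCT-minus-CT
differences per case, observer, modality and direction; roll is
recorded as missing for 2D rows.  Summaries report mean, sample SD
(n − 1), min and max per direction.

Equivalence uses the paired two one-sided t-tests (TOST) procedure on
the interval (−1, +1) mm: t_lower = (m − low)/(s/√n) against the upper
tail of t(n−1) and t_upper = (m − high)/(s/√n) against the lower tail;
equivalence is declared when both one-sided p-values fall below
α = 0.05, i.e. p_overall = max(p_lower, p_upper) < α.  By the usual
duality this is equivalent to the 90% CI lying inside the bounds; the
phrase "95% confidence" sometimes attached to TOST conflicts with that
duality, so both the 90% and 95% CIs are reported and α is stated
explicitly.  With all differences identical the t statistics are
degenerate; the implementation then decides by whether the exactly
known mean lies strictly inside the bounds, with p reported 0/1 and a
warning.  The headline test pools the three translation axes per
modality into one sample (axes treated as exchangeable and
independent), giving exactly one 3D and one 2D verdict; per-direction
TOSTs are reported as diagnostics, and rotations are summarized but
not equivalence-tested.  Statsmodels' `ttost_paired` serves as the
independent oracle in tests only.

## PTV distance metric and overlap

When corrections include rotations, per-axis parameter differences are
hard to interpret clinically.  The distance metric makes the effect on
the target explicit: both registration matrices are applied to the
*original* PTV contour points and d_i = ‖A p_i − B p_i‖ is reported
for every point, correspondence strictly by index (no nearest
neighbour matching).  Closed forms anchor the tests: a pure relative
translation gives d_i = ‖t‖ exactly (a histogram spike whose offset
reads off the translation), a pure relative rotation δ gives
d_i = 2 r_i sin(δ/2), and composing the same extra rigid transform
onto both matrices changes nothing.  Histograms use 0.25 mm bins from
0 to ⌈max⌉.  Duplicated contour-closure points are dropped on input so
each vertex counts once.

Dice overlap is computed volumetrically in 3D by default: the original
contour stack is rasterized once on an isotropic grid (1 mm by
default; each grid plane takes the nearest contour polygon within half
the contour pitch, point-in-polygon via even-odd test), and each
registered copy's mask is obtained by inverse-mapping voxel centres of
a shared grid into that base mask — rotations tilt contour planes off
the grid axes, so transformed stacks are never re-rasterized directly.
A 2D projected variant (`project_mask` + `dice`) is provided since
planar workflows could be read either way; the 3D default is
documented here.

Per-case observer pooling reports the mean ± SD of per-observer mean
distances, identifies the worst observer by largest per-observer mean
(quoting that observer's mean ± SD), and the global maximum distance.

## Deformation QA and landmarks

The Jacobian determinant of x → x + u(x) is det(I + ∇u) with
derivatives by central finite differences using voxel spacing in mm,
falling back to one-sided differences at mask borders so that
out-of-mask values (undefined or garbage) cannot produce spurious
negative determinants at the body surface; voxels with no in-mask
neighbour along an axis contribute a zero derivative for that term.
JD > 1 is local expansion, < 1 contraction, ≤ 0 non-invertible folding;
a field is flagged `realistic` iff JD > 0 everywhere in the mask.  On
smooth synthetic fields the finite differences converge at second
order to the attached analytic determinant (verified across two grid
resolutions).  Synthetic fields: identity, anisotropic affine scaling
(constant JD = sx·sy·sz), a Gaussian bump displacing along one axis
(JD = 1 + ∂u_k/∂x_k in closed form), and a "folding" bump whose
amplitude exceeds σ√e so the analytic minimum JD = 1 − (A/σ)e^(−1/2)
is negative by construction.

Landmark placement reproducibility is the Euclidean distance of each
repeated placement to the centroid of all repeats (mean and max
reported); a pairwise-distance variant is available via `method=`, the
choice being documented rather than standardized.  Landmark offsets
evaluate each configured definition within each image and difference
the two images (A − B), pooling mean ± SD across cases.

## Demo pipeline and problem sizes

`run_pipeline` chains all stages at a desk-scale default: 4 cases, 2
observers, 64³ volumes at 3 mm.  The 3D arm is fully computational —
each case's known uniform(±2 mm, ±1°) setup displacement is applied to
the phantom and recovered by the MI engine against both references.
The 2D arm emulates the manual-observer design by sampling paired
5-DoF results at configured per-direction moments (defaults: means
(0.0, −0.2, −0.3) mm / (0.1, −0.1) °, SDs (0.7, 0.7, 0.8) mm /
(0.6, 0.5) °, the scale observed for bone-based head-and-neck
positioning); the actual 2D registration engine is exercised by its
own tests and the acceptance script rather than per observer in the
demo, keeping the demo under a minute.  Every output embeds the seed
and a hash of the scientific configuration (output paths excluded);
two runs with the same configuration are byte-identical.

## What the synthetic data does and does not show

The phantom is piecewise constant, noise-free by default, perfectly
rigid, and its "CBCT" is the phantom itself resampled — no scatter,
cupping, truncation, or anatomy change between imaging sessions.
Recovery tolerances met here (≤0.5 voxel / 0.5° against the exact
reference, ≤1 voxel / 1° against the degraded surrogate) therefore
demonstrate correctness of the transform/metric/optimizer chain and
its robustness to the modelled degradations — not clinical accuracy on
real images, where neck flexion, immobilization-mask variability and
observer strategy dominate.  Equivalence-test calibration (type-I
error at the bound, power at zero mean) is exact in the Gaussian
setting simulated; pooling axes assumes exchangeability that real
per-axis variances only approximately satisfy.

## Known limitations

- No deformable registration is performed; only QA of displacement
  fields supplied to it.
- Parallel-ray projections only; no divergent-beam DRR geometry.
- The sCT surrogate is qualitative; its parameters are not calibrated
  to any sCT generator.
- Capture range is not studied beyond ±10 mm / ±5°; the optimizer is
  local and initialization within a few voxels is assumed (the
  optional multi-resolution level widens this somewhat).
- The interobserver 2D arm of the demo pipeline is statistical, not a
  per-observer rerun of the 2D engine.
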