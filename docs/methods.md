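# Methods

This note documents the models, parameter choices and numerical decisions
behind `fetalshear`, in the spirit of a methods supplement: what is assumed,
what the defaults mean physically, what the synthetic data can and cannot
stand in for, and where design latitude was exercised.

## Study window and stage physiology

The pipeline models wildtype fetal mouse great arteries from E14.5 to E18.5,
in five one-day stages. Each stage carries:

| quantity | E14.5 | E18.5 | source of the schedule |
|---|---|---|---|
| heart rate (beats/min) | 216 | 286 | linear between measured anchors |
| ejection ratio (fraction of cycle) | 0.44 | 0.38 | linear |
| hematocrit (fraction) | 0.306 | 0.412 | linear through (E10.5, 0.20) and (term = E19.5, 0.438) |
| dimension scale (× near-term) | 0.55 | 1.00 | linear; anchored by the 0.573 mm near-term DAo width |

The angular frequency ω = 2π·HR/60 enters only the Womersley number.
"Term" is taken as E19.5 (mouse gestation); the hematocrit schedule is the
only place the convention matters, and the viscosity calibration below
absorbs it.

## Blood properties

Fetal blood is treated as Newtonian (valid at these shear rates), with
kinematic viscosity an exponential function of hematocrit,

    nu(Hct) = A exp(B Hct)   [cSt],

the standard low-shear form for fetal blood. A and B are fixed analytically by
requiring nu = 1.87 cSt at E11.5 and 2.53 cSt at E18.5 under the hematocrit
schedule — the two published reference values for prenatal mouse blood — which
gives A = 1.292 cSt and B = 1.633 per hematocrit fraction. Dynamic viscosity
uses a fixed density of 1.06 g/cm³ (mu [mPa·s] = nu [cSt] · rho [g/cm³]).
Hematocrits outside [0.15, 0.55] trigger a warning (extrapolation) but still
return a value.

## The synthetic vessel tree

Each stage's tree is a parametric swept-ellipse model of the wildtype
topology: ascending aorta and arch (a circular arc) carrying the innominate,
left common carotid and left subclavian arteries; the aortic isthmus; the
descending aorta; the pulmonary trunk with left/right pulmonary arteries; and
the ductus arteriosus (a Hermite curve) inserting into the descending aorta.
Key constructions:

* **Absolute scale.** Only one dimension is published numerically: the
  near-term DAo width, 0.573 mm. All other near-term radii are plausible
  choices (innominate 0.15, carotid/subclavian 0.12, pulmonary arteries
  0.10 mm), and everything scales linearly with age from 55% at E14.5 —
  chosen once so lumen areas roughly triple across the window, matching the
  observed monotone growth.
* **Murray-consistent internal radii.** Internal segment radii are *derived*
  from the outlet radii by cube-law flow conservation
  (r_internal³ = Σ r_outlet³ downstream). Equal plug velocities at the two
  roots then force equal root radii. Consequence: with Murray outlet splits,
  every segment carries Q ∝ R³ and Poiseuille wall shear τ = 4μQ/(πR³) is
  segment-independent — exactly. This is a modelling *choice* that encodes
  the homeostasis hypothesis in the geometry; the trend analysis then
  measures it, it does not discover it.
* **Ductus insertion angle** opens linearly from 100° (nearly perpendicular)
  at E14.5 to 150° (toward a parallel merge; 180° = parallel) at E18.5,
  reproducing the observed remodeling direction. The convention reports
  180° − (geometric angle between the arriving branch tangent and the
  parent's downstream tangent).
* **Cross sections** are ellipses of constant area πr² with aspect ratio
  0.9 away from branches, dipping to 0.7 within one branch radius of each
  ostium, elongated toward the branch — the measured branch-zone pattern.
  The descending aorta is kept circular so its maximum width equals the
  0.573 mm anchor exactly.
* **Seeded jitter** (±2%) perturbs branch directions and lengths, never
  radii, so determinism contracts and the exact Murray algebra both hold.
  Non-physical parameter combinations are rejected by a pairwise clearance
  check that exempts junction neighborhoods (vessels legitimately meet
  there).

## Synthetic imaging and Doppler

**Image stacks** emulate serial block-face imaging: the tree is voxelized
(voxel-center-in-ellipse test, per-segment so adjacent vessels cannot shadow
each other), lumen and tissue get mean intensities 0.75 / 0.35, and mean-one
lognormal speckle of cv 0.15 multiplies everything. The exact voxel mask is
retained as ground truth. Default spacing for full trees is 20–25 µm
(desk-scale; the numerical phantoms used for accuracy oracles go to
12–15 µm). Real block-face data differ in ways the generator does not model:
spatially correlated speckle, illumination drift, neighboring organs touching
the vessels, and partial-volume gradients at the wall. Passing segmentation
tests (Dice ≥ 0.95) therefore demonstrates the pipeline's correctness on its
stated noise model, not performance on real stacks.

**Doppler velocimetry** reports peak velocities per subject (4 subjects/age by
default, matching typical cohort sizes) for the DAo, both roots, and two
branch arteries. Noise is a subject-level mean-one lognormal factor (cv 0.113)
shared across a subject's vessels — inter-animal physiological variability of
the magnitude reported for such cohorts — times a per-measurement lognormal
(cv 0.04); total cv 0.12. Because both factors are mean-one, quadratic refits
of the velocity-age curve are unbiased (verified by Monte Carlo).

**The velocity-age curve.** The ground-truth quadratic is defined once: peak
DAo velocity 133 mm/s near term (within published UBM ranges), with age
dependence proportional to R(t)/ν(t) — the growth law under which wall shear
stress is exactly level. A quadratic fits those five stage values with <1%
residual. The trend analysis (`run_stage_sweep`) drives boundary conditions
with this single canonical curve, mirroring the original procedure of using
one published fitted curve for all CFD cases; `velocity_model="fit"` instead
re-fits the quadratic to the sweep's own noisy cohort, which adds
sampling-noise wiggle to the stage contrasts.

## Boundary conditions and flow solutions

DAo flow anchors everything: Q_dao = V(t)·πR²/2 (parabolic profile, mean =
half peak). Murray's law distributes total flow over outlets; parabolic outlet
profiles give branch peak velocities; the two roots receive equal plug
velocities balancing the outflow exactly (the velocities measured at the two
roots are equal, motivating this closure).

Three solution layers, in increasing resolution:

1. **Poiseuille network** (the workhorse): per-segment Δp = 8μLQ/(πR⁴),
   τ = 4μQ/(πR³), V_max = 2Q/(πR²), with exact junction mass balance.
   Justified because viscous forces dominate (Re < 30). Pressures are
   bookkeeping under imposed flows, not a pressure solve.
2. **Axisymmetric steady Navier-Stokes** for straight tubes:
   streamfunction-vorticity on a uniform (z, r) grid, Thom wall vorticity,
   first-order upwind convection with second-order diffusion, Picard
   iteration (under-relaxation 0.35, tolerance 1e-6 on the relative velocity
   change). Validation gates, all tested: exit profile within 1% of
   Poiseuille, wall shear within 3% (second-order one-sided gradient), mass
   conservation within 0.1% (the discrete streamfunction flux is exact;
   the velocity-quadrature check is the reported number), observed
   convergence order ≈ 2, Stokes-limit linearity within 1%.
3. **Dean perturbation** for curved tubes: at the low Dean numbers of the
   fetal arch (De ≈ 3–6), the secondary flow obeys a linear biharmonic
   balance whose single Fourier mode is solved as a 1D two-point boundary
   value problem (second-order differences, clamped rim, regular center).
   The classical closed-form series is the independent oracle (agreement
   ~1e-4). The embedded 3D field carries the torus volume metric for
   helicity integrals. Fully developed flow is assumed along the bend;
   junction neighborhoods are not resolved by any 3D solve — segment-wise
   composition with network flows is the stated fidelity level.

Meshes are structured tube blocks; outlets are extended 9 diameters and roots
1 diameter before solving, and two refinement levels (×2 per dimension)
support grid-independence reporting.

## Image processing and morphometry

* **Speckle filter**: classic Perona-Malik diffusion on the 6-neighborhood,
  exponential conductance g(d) = exp(−(d/κ)²), κ defaulting to 60% of the
  lumen/tissue contrast, step 1/6 (the stability bound, which also yields a
  discrete maximum principle and exact intensity conservation under the
  zero-flux borders). 12 iterations by default.
* **Segmentation**: Otsu global threshold + largest 6-connected component +
  one closing pass. Parameter-free by design. Single-mode histograms are
  rejected (smoothed-histogram mode count < 2) rather than returning an
  arbitrary mask. Closing can add a few voxels in junction crevices; on
  simple two-level stacks the noiseless segmentation is exact.
* **Surfaces**: marching cubes at the 0.5 level of the one-voxel-Gaussian
  smoothed mask (sub-voxel accuracy: sphere area within 3%, cylinder volume
  within 2%); tiny masks fall back to the raw binary surface. Branch
  clipping removes faces beyond an ostial plane (offset 0.4 branch radii)
  within a catch cylinder, then fan-caps each boundary loop; caps are flat.
* **Centerlines**: Euclidean distance transform, minimum-cost path between
  declared endpoints with cost 1/edt⁴, spline smoothing, then a ridge
  re-centering step (quadratic fit of the EDT on an in-plane 3×3 stencil,
  step to its maximum) that removes the corner-cutting bias of the path
  step — bend radii of curved phantoms are recovered within 2%. The
  per-point radius is the inscribed-sphere radius (EDT value), which
  underestimates the nominal radius by up to ~1 voxel; stage-sweep Reynolds
  numbers use the parametric ground-truth radii instead.
* **Cross sections**: the mask is sampled on the tangent-orthogonal plane
  (rotation-minimizing frames; pixel = half the voxel spacing), lightly
  smoothed, and the 0.5-level contour measured: shoelace area, maximum Feret
  diameter from the contour hull, and d_min as the support width
  perpendicular to the max-Feret axis (equal to the minimum Feret width for
  convex near-elliptical sections, and free of the low bias a
  min-over-directions search picks up from boundary jitter). Aspect-ratio
  accuracy ~0.5% on elliptical phantoms; rotation invariance within 3%.
  Feret measures are extreme-value statistics — the in-plane smoothing
  exists precisely to keep voxel jitter from biasing them.
* **Profile alignment**: subject arclengths are normalized and warped
  piecewise-linearly so each named junction landmark lands on the
  cross-subject mean position; values are resampled on a 200-point grid.

## Statistics

Trends pool the three vessel territories (ascending aorta + arch, descending
aorta, pulmonary trunk + ductus analysed jointly) and report Pearson ρ plus
the p-value for zero regression slope, per quantity against age and against
mean lumen area. Constant covariates yield an explicit "undefined" note.

The Murray validation compares, per age and branch artery, branch velocities
predicted from each subject's *own* DAo measurement via Murray's law against
that subject's directly measured branch velocity, with a two-sided
Mann-Whitney U test computed by exact permutation enumeration (group sizes
3–20; ties handled by midranks within the enumeration; normal approximation
with tie correction beyond enumeration range). Because predicted and measured
values share the subject-level factor, the test is conservative against false
rejection, as the paired design of the comparison intends.

## Degenerate inputs and tie-breaks

Empty masks, constant stacks, disconnected lumens, rank-deficient velocity
fits, non-positive radii, overlapping vessel territories and junction
mismatches all raise explicit errors rather than returning silently wrong
values. Helicity normalization floors |V| and |ω| at 1e-9 (working units) and
reports 0 there. When two junctions nearly coincide, landmarks are assigned
to the nearest; the generator's branch spacing keeps this unambiguous.

## Problem sizes

Defaults are desk-scale by choice: full-tree stacks at 20–25 µm (~1–3 M
voxels), accuracy phantoms at 12–15 µm, pipe-solver grids up to 49×161, Dean
mode at 201 radial points, 200-refit Monte Carlo for the velocity model, and
exact permutation tests up to C(n, k) ≈ 4·10⁵. All headline properties
(viscosity anchors, Re < 30, shear constancy, chirality balance) are stable
under refinement of these sizes.

## Known limitations

Rigid, impermeable walls (no diastole-systole distension, reported at ~13%
in vivo); steady peak-flow solutions only (justified by Re < 30 and low
Womersley numbers, but no oscillatory shear metrics); no 3D resolution of
junction flow (so the local shear elevation distal to ostia is outside the
model); synthetic geometry rather than subject-specific anatomy; and the
shear-constancy result is, by construction, a property of the
Murray-consistent generator — the pipeline demonstrates that the analysis
recovers it faithfully, not that real vessels obey it.
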