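# Methods

## Model

The growing skeletal element is idealised as a right circular cylinder
of an elastic, homogeneous, isotropic material. Growth is slow compared
with any mechanical relaxation time, so each growth increment is a
static small-strain problem: find the displacement u with

  −∇·σ(u) = f,  σ = λ tr(ε) I + 2µ ε,  ε = ½(∇u + ∇uᵀ),

where the body force f models the push of dividing cells. The cylinder
is partitioned into axial regions (default five slabs at fractions
0, 0.15, 0.35, 0.65, 0.85, 1 — epiphysis / metaphysis / diaphysis /
metaphysis / epiphysis), and each region k carries a constant force
density with an axial and a radial component,

  f(x) = f_a(k) **e**_z + f_r(k) **e**_r(x),

with **e**_r the unit vector from the bone axis to x (zero on the axis
itself). "Internal pressure" from proliferation is therefore read as a
volumetric force density, the reading consistent with a force field
that has separate axial and radial components; a surface-traction mode
exists only for verification problems.

Two scenarios encode the biology:

* **regeneration** — every region has the same (f_a, f_r): cartilage
  expands freely along the whole shaft (ossification is delayed);
* **development** — radial moduli are graded by a symmetric
  piecewise-linear ramp in region index, equal to a centre fraction
  c·f_r0 at the mid-shaft (default c = 0.2) and f_r0 at both end
  regions: early cortical ossification of the diaphysis mechanically
  suppresses transversal expansion there. Axial moduli are the same in
  both scenarios.

Scenario comparisons are made at matched total radial impulse
Σ_k |f_r(k)|·V_k, so shape differences reflect the *distribution* of
radial drive, not its amount.

## Discretisation and solver

Linear (P1) tetrahedra; element stiffness K_e = V BᵀDB with the
standard Voigt strain-displacement matrix; consistent load integration
(an element-wise constant body force contributes f·V/4 to each vertex,
a constant traction t·A/3). The global system is solved by sparse LU
(deterministic); a Jacobi-preconditioned CG fallback with relative
tolerance 1e-8 is available. Solutions are rejected if the relative
residual on the free equations exceeds 1e-8.

The mesh is structured: concentric node rings per axial layer, disk
triangulations extruded to prisms, each prism split into three
tetrahedra with the smallest-global-index diagonal rule so the mesh is
conforming; the boundary surface is extracted from single-owner tet
faces and is watertight by construction. The lateral wall is the
inscribed regular polygon, so the mesh volume is below πR²L by the
factor (n/2π)·sin(2π/n); the default resolution 60×10×20
(axial × radial × angular) gives 68,400 elements — the ~65k scale at
which the shaping simulations were designed to run — and a 1.6% area
deficit. External NETGEN-style meshes are accepted through the VTU/VTK
readers.

### Boundary conditions

Defaults: u_z = 0 across the proximal face (roller), u_x = u_y = 0 on
the on-axis vertex line, and one tangential pin on an off-axis proximal
node. The straight-axis condition is the appropriate symmetry statement
for axisymmetric growth loads, and it is not optional in practice: a
slender rod held only by point pins has lateral bending eigenvalues
three to four orders below the typical stiffness scale, and the
unavoidable asymmetry of any tetrahedral connectivity then turns an
axisymmetric load into a large spurious lateral deflection (and makes
incremental growth diverge). For meshes without an on-axis node line
the solver falls back to the point-pin scheme with a warning.

### Parameters

| parameter | default | units | note |
|---|---|---|---|
| L, R | 10, 1 | mm | zeugopod-like aspect ratio |
| E | 1 | kPa | soft-cartilage scale; results scale as f/E |
| ν | 0.40 | — | nearly incompressible tissue; warning ≥ 0.49 (P1 locking) |
| f_a0, f_r0 | 0.05, 1 | kPa/mm | pre-normalisation moduli |
| c (centre fraction) | 0.2 | — | development ramp minimum |
| normalisation | 0.2 | ·R | target max displacement |

Load magnitudes are not physical measurements; they are normalised
after the fact so the regeneration run's maximum displacement is 0.2 R,
keeping the small-strain assumption honest while leaving the
development run at matched impulse. Because the model is linear this
is a pure rescale and does not change any ratio-type readout.

Growth can be iterated (`incremental_growth`): solve, advect vertices
by u, re-assemble on the deformed geometry. One step equals the single
static solve; steps whose maximum displacement exceeds 0.3 R trigger a
small-strain warning, and element inversion aborts with the step index.

## Shape quantification

* **Diameter profile** — lateral-surface vertices (cap planes excluded)
  are binned along the axis; each bin reports the mean and max distance
  to the axis. Empty bins are flagged, never interpolated.
* **Bulge index** — count-weighted mean effective radius over the
  central 20% of the covered length divided by the same over the two
  15% end bands. The band fractions are this package's
  operationalisation of "bulky mid-shaft" and are configurable.
* **Deviation map** — one-sided nominal/actual comparison: every vertex
  of the test ("actual") surface gets its exact closest-point distance
  to the reference ("nominal") triangle set (vertex/edge/interior cases
  handled exactly; a KD-tree candidate bound keeps it fast without
  approximation), signed by the side of the nearest reference triangle.
  Both unsigned and signed fields are emitted. Band localisation uses
  the binned *mean signed* deviation: the per-vertex unsigned maximum is
  dominated by rim vertices whenever the two parts elongate unequally,
  which says nothing about where the heat-map band lies, whereas the
  outward (positive) band is exactly the feature a nominal/actual heat
  map highlights. No automatic registration is applied — simulated
  surfaces share a frame; a rigid pre-alignment hook exists for
  imported surfaces and is off by default.
* **Labeled volumes** — voxel-centre-in-solid counting times voxel³.
  The rasterisation error is oscillatory in voxel size (a Gauss-circle
  effect), so convergence should be judged across the fine-voxel regime
  (≤ 0.04 mm here) rather than from a single halving at coarse voxels.

## Orientation statistics

Division orientations are axial data: a doublet (a, b) and its
reversal are the same event, so the angle to the bone axis is
arccos(|(b−a)·**e**_z|/‖b−a‖) ∈ [0°, 90°]. Summaries report mean,
median, quartiles (linear interpolation), SD and the fraction above a
transversal threshold (default 45°, the fold midpoint). Group
comparison offers the Welch (unequal-variance) t test and a label
permutation test on the difference of means with the add-one corrected
two-sided p = (b+1)/(m+1); permutation resampling is chunked so very
large resample counts (needed to resolve p below ~1e-4) stay within
memory. 2-D section data are accepted by zero-padding the third
coordinate, with the axis in-plane.

## Synthetic data

Generators emulate, with full determinism under a seed and the analytic
ground truth emitted beside the data:

* **doublets** — polar angle from a normal(mean, sd) truncated to
  [0°, 90°] (chosen for its closed-form moments), azimuth uniform,
  midpoints uniform in the cylinder, fixed pair separation. Recovery is
  judged against the truncated-normal mean — truncation shifts it away
  from the location parameter (e.g. 20° → 22.7° at sd 15°).
* **profile volumes/surfaces** — axisymmetric radius profiles
  (constant, gaussian bulge/waist, linear taper) rasterised by
  voxel-centre inclusion and/or triangulated as watertight surfaces of
  revolution, with the exact ∫πr(z)²dz alongside.
* **surface pairs** — concentric cylinders (constant deviation ΔR) and
  bulge-vs-straight (deviation r(z) − R) for deviation-map testing.

What the generators do *not* emulate: imaging noise and PSF, partial
volume effects, segmentation error, anatomical asymmetry, and any
coupling of load moduli to the simulated ossification state. Passing
tests therefore demonstrate correctness of the computational machinery
on idealised geometry, not robustness to real micro-CT or microscopy
artefacts.

## Verification strategy

The solver is checked against a closed-form problem with a genuinely
nonzero, deterministic error: a fixed axial force F = σπR² spread over
the discretized distal cap. The P1 solution is exact for the meshed
(polygonal) cylinder, so the measured tip and lateral errors equal the
cap-area discretization error 2π/(n sin(2π/n)) − 1 — about 1.7% at the
default n_angular = 20 — and shrink strictly monotonically under
angular refinement. Element-level exactness is checked against two
independent formulations (a finite-difference energy oracle and the
closed-form tensor expression from face-normal shape gradients), and
the deviation map against an independent all-triangle closest-point
implementation.

## Known limitations

Small-strain linear elasticity only (no multiplicative growth
decomposition, no contact, no separate cortical shell material); the
incremental mode is a quasi-static update, not a finite-growth theory.
Material and load magnitudes are stand-ins on a normalised scale, so
only dimensionless readouts (bulge index, band location, ratios) carry
meaning across parameter choices. The development ramp shape is a
modelling choice (linear in region index); alternative ramps can be
supplied via custom scenarios. Statistical tests assume independent
doublets — clustering by animal or section is not modelled.
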