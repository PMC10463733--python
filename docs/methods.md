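# Methods

This note documents the models, numerical methods and design choices
behind the package, stage by stage, together with what the synthetic
data does and does not emulate.

## Synthetic chamber geometry and motion

The generator replaces segmented, phase-resolved cardiac CT with an
idealized 2D cross-section of the left heart. Coordinates are in mm; a
cross-section of area `A` represents a chamber of volume `A × depth`,
with an out-of-plane extrusion depth of 40 mm chosen so that clinically
scaled volumes (LA 40–130 ml, LV 40–160 ml) map to plausible planar
dimensions (LA radius ≈ 17–26 mm, LV long axis ≈ 70–100 mm). A
`dimension = 3` mode extrudes the cross-section to a watertight prism
for the volume/voxelization layers; the flow solver itself is 2D.

**Layout.** The mitral valve plane is `y = 0` with commissures at
x = ±12 mm. The LA body is a circle clipped by the valve plane and by
two chords near the roof (the pulmonary-vein inlets, width 8 mm, at 70°
and 110° from the LA centre). The appendage is a neck (4 × 5 mm by
default, shrunk proportionally for small appendages) plus a circular
pouch attached at 168°; the ostium plane is the line through the
attachment point perpendicular to the neck axis. The LV is an ellipse
(semi-axis a = 28 mm; b solved for the end-diastolic area) below the
valve plane, with a vertical aortic cut (9 mm) at its right equator.
The body radius, pouch radius and LV semi-axis are solved by 1D root
finding so the phase-0 areas match the prescribed end-diastolic /
minimum volumes.

**Volume waveforms.** The study type this emulates reports only extreme
volumes, not waveforms, so the curves are a documented synthetic choice:
piecewise half-cosine segments (zero slope at every knot, hence C¹ and
periodic). Timing landmarks, as fractions of the RR interval: end of
ventricular systole 0.35 (LV minimum, LA reservoir maximum), end of
early filling 0.65, diastasis 0.65–0.85, atrial contraction onset 0.85.
65 % of LV filling (and of LA emptying) is passive; the remaining 35 %
is the atrial kick. Phase 0 is end diastole (LV maximum, LA minimum),
and phase 1.0 coincides with phase 0 by construction.

**Deformation.** Each phase is produced by a smooth map applied to the
reference vertices: radial scaling about the mitral centre with an
atrial factor above the valve plane and a ventricular factor below,
blended across a ±8 mm band so the two chambers meet continuously, plus
an extra scaling of the appendage about its (moving) ostium, blended
along the neck and restricted to the atrial side of the valve plane.
The three factors are solved per phase (Newton-type root find) so the
LA (including LAA), LAA, and LV areas match the waveforms essentially
exactly — prescribed EFs round-trip through the descriptor layer to
well under 1 %. The map is deterministic; vertex correspondence across
phases holds by construction, which also defines the ground-truth
motion field used to validate tracking.

**Cohorts.** Subjects are drawn from independent normals per group over
the parameters such studies tabulate: BSA, heart rate, BSA-indexed
LA/LAA/LV volumes and EFs (control: LA max 41 ± 7 ml/m², LA EF
53 ± 7 %, …; AF-like: 66 ± 15 ml/m², 43 ± 9 %, …), with the appendage
shape label drawn as a Bernoulli (chicken-wing fraction 7/8 control,
16/21 AF) and carried as metadata only. Absolute volumes are formed as
indexed value × BSA at draw time. Draws violating the spec invariants —
including plausibility bounds (EFs within (0.05, 0.85) for the LA,
LV EF within (0.2, 0.85), heart rate 30–150 bpm, BSA 1–3.5 m²) that
exclude physically meaningless tail draws — are rejected and redrawn,
at most 100 times before an error.

**What the synthetic data does not emulate.** Real pulmonary-vein
anatomy (2 planar inlets instead of 4–9 three-dimensional ones), LAA
trabeculation (unresolvable even in CT), shape-class-specific appendage
topology, beat-to-beat variability, fibrillating (non-periodic) motion,
and segmentation noise beyond voxelization error. Passing tests
therefore demonstrate correctness of the pipeline's mechanics and the
direction of physiologic effects, not patient-level accuracy.

## Wall-motion tracking

Tracking deforms the phase-0 boundary onto each phase's segmentation
(a contour, or a binary mask whose 0.5 iso-contour is extracted) by
non-rigid ICP: closest-point correspondences on the target polyline
alternate with a linear solve `(I + αL) d = c − x` per coordinate,
where `L` is the closed-polyline graph Laplacian. The smoothness weight
α decreases over outer iterations (default schedule 100, 10, 1, 0.1),
so rigid-scale motion is captured before local deformation; an optional
rigid (Kabsch) initialization precedes. Defaults: tolerance 0.1 mm mean
surface-to-target distance, at most 50 correspondence updates;
non-convergence is reported by a warning plus the residual, never
silently. Phase k is initialized from phase k−1 (chaining). Deformed
surfaces are checked for inversion (signed area) and self-intersection;
violations raise — no repair is attempted. Displacements are
interpolated in time by a periodic cubic spline, giving C¹ wall
velocities whose cycle integral vanishes identically.

Recovery properties on the default geometry: identity → 0 displacement;
a 3–4 mm rigid translation recovered to < 1 %; a 10 % dilation's volume
effect to < 2 %; volume curves tracked from 0.5 mm masks match the
generator's to < 3 % (in practice ≈ 0.3 %).

## Meshing

Triangulations are graded toward the wall: boundary edges at the wall
edge length, interior points on successive inward offsets with spacing
growing geometrically to the maximum edge length, a uniform triangular
lattice in the core, then a Delaunay pass restricted to the domain
polygon. The mitral chord is inserted as an interior point line so the
valve can close at the facet level. If a boundary node or edge ends up
uncovered (sharp concavity, locally stretched boundary), a helper point
is dropped just inside the boundary and the pass retried (at most 4
attempts) before erroring; boundary conformity is always verified.

Desk rescaling: the production-scale defaults (0.25 mm wall / 2 mm
interior, dt 5×10⁻⁴ s, remeshing every 50 steps = 0.025 s) remain the
`SolverConfig` defaults; the 2D desk presets scale edge lengths ~5×
(coarse: 1.4/2.8 mm) and the time step to 2×10⁻³ s (coarse) while
keeping the remeshing cadence fixed *in time* (every 0.03–0.05 s,
i.e. 15–25 steps), so meshes stay in the 1–3 k-cell range and a cardiac
cycle costs seconds. The CFL monitor warns (or errors, per config) if
the convective Courant number exceeds 0.9.

## Flow solver

Linear (P1) finite elements, incremental-pressure projection, ALE:

1. **Mesh motion.** Boundary and valve-line nodes follow the tracked
   wall by inverse-distance-weighted (power 2) interpolation of the 5
   nearest tracked vertices' displacements, with a distance-zero tie
   rule; in the pipeline the generator samples the boundary at the wall
   edge length so mesh boundary nodes coincide with tracked vertices
   and the interpolation is exact there. Anchor weights are fixed once
   at solver construction, making the prescribed motion exactly
   periodic. Interior nodes follow a harmonic (Laplace) extension of
   the boundary displacement, factorized once per remesh epoch. The
   nodal mesh velocity is the discrete position increment per step.
2. **Momentum predictor.** Implicit viscous terms, explicit convection
   with convecting velocity `u − w` in non-conservative ALE form (which
   preserves a uniform free stream under pure mesh motion exactly), and
   the old pressure gradient (incremental form — without it a
   steady-state splitting error of order ν·dt·h⁻² appears; with it the
   plane-Poiseuille benchmark is matched to 0.5 %). Walls and closed
   valves are Dirichlet at the local mesh velocity; openings are
   traction-free.
3. **Projection.** A pressure-Poisson problem for the increment with
   Dirichlet values at open pressure openings (0 Pa gauge everywhere by
   default — the flow is motion-driven, so only differences matter) and
   homogeneous Neumann at walls; the wall-motion flux enters the
   divergence functional, coupling opening flow to the rate of domain
   volume change. The correction is applied through the lumped mass
   matrix and iterated (default 2 passes). Linear systems are solved by
   direct sparse LU; the remaining weak-divergence residual is logged
   each step. Opening fluxes are evaluated variationally (divergence
   functional summed over each opening's pressure nodes), the
   discretely consistent flux definition; against the discrete rate of
   area change the contracting-box benchmark balances to ≲ 0.1 %.
4. **Stabilization.** On coarse meshes an isotropic cell-Péclet
   artificial viscosity `ν_e = max(ν, |a| h_e / 2)` keeps the explicit
   convection monotone; it is inactive wherever the cell Reynolds
   number is ≤ 2, so viscous benchmarks are unaffected. It is the
   dominant accuracy limit of the coarse desk mode and is the price of
   robustness at ~2 k cells.

Valves are facet-level: the mitral chord nodes (interior) and the
aortic opening's boundary nodes become moving no-slip walls while
closed — no topology change, at the cost of a small pressure leakage
across the one-node-thick closed valve, bounded by the logged mass
balance. The schedule derives from the LV waveform: aortic open during
ejection (dV_LV/dt < 0), mitral open otherwise; the synthetic waveform
has no finite isovolumic phases.

At each remesh the interior is re-triangulated on the current boundary
(boundary and valve nodes, with their motion anchors, are preserved
verbatim), nodal fields transfer by barycentric interpolation and cell
scalars by donor-cell lookup; an unchanged boundary reproduces the mesh
and the transfer is an identity.

## Residence-time transport

Cell-centred, donor-cell (first-order upwind) finite volumes on the
flow mesh. With D = 1.14×10⁻¹¹ m²/s the physical Péclet number is
O(10⁹), so stability and positivity must come from the scheme, not the
physics: upwinding is monotone, guarantees nonnegativity, and respects
`max(T_res) ≤ elapsed time` step by step (inflow faces carry fresh
blood, T_res = 0; outflow faces are zero-gradient; walls are no-flux
because the wall-relative velocity vanishes under no-slip). Fluxes use
the fluid velocity relative to the mesh; cell volumes evolve by the
discrete geometric conservation law (integral of the mesh-velocity
flux), so a closed stagnant domain ages exactly uniformly (T = t to
machine precision) and the unit source integrates exactly. Substeps
enforce the donor-cell CFL bound internally. The cost of first order is
numerical diffusion, quantified on the steady plug-flow benchmark: the
outlet age matches the transit time L/U to ≈ 1 %, with a spread of a
few percent of the transit time around the sharp analytic profile.

Regional stasis is the volume-weighted mean of T_res (volume weighting
is the physically consistent reading of an "average" over a region)
over: all cells above the mitral plane (LA including LAA), those beyond
the ostium plane (LAA), and the difference (LA body), divided by the RR
interval → cardiac cycles. The protocol runs 2 initialization cycles
without the scalar, then 6 cycles with it, evaluating at end systole of
the final cycle; both cycle counts and the evaluation phase are
arguments. Because the scalar grows with simulated time, values are
comparable only at matched cycle counts — the per-cycle regional means
are logged as a convergence trace.

## Cohort statistics

Two-sample t-tests (pooled variance by default, Welch by flag; the
pooled default is the textbook reading of an unqualified "two-sample
t-test"), significance at 5 %, no multiple-testing correction —
univariate analyses are reported individually, as is standard for
exploratory descriptor tables. Univariate OLS (statsmodels) provides
slope, R², two-sided slope p, and a 95 % confidence band for the mean
prediction; a leave-one-out refit report flags observations whose
removal flips significance (high-leverage points). Appendage-shape
subgroup tables emit a t-test only where both subgroups have n ≥ 2,
otherwise descriptive values only. Calibration is verified empirically:
under null cohorts at group sizes 8 vs 21 the pooled test rejects at
5 % ± 1 % over 5000 seeded replicates, and OLS recovers slopes within
3 standard errors.

## Problem sizes used by the test suite

Flow and transport oracles run on 10–20 mm benchmark domains with
400–1200 nodes in seconds. The end-to-end group-contrast test uses the
coarse desk preset (≈1.7 mm wall edges, dt 2.5 ms, ~1.5–2.5 k cells per
subject), cohorts of 3 control-like + 3 AF-like subjects over two
seeds, and 2 initialization + 3 residence cycles — enough cycles for
the group ordering and the appendage-vs-body ordering to be stable,
while a full cohort run stays under a few minutes per seed. These sizes
are the package's verification protocol; larger cohorts, more cycles
and finer meshes are plain arguments.

## Known limitations

- 2D planar flow with an extrusion-depth volume convention: absolute
  residence times are not comparable to 3D patient values; orderings
  and associations are the meaningful outputs.
- First-order upwind transport over-mixes the appendage relative to a
  higher-order scheme; reported LAA/body contrasts are conservative.
- Closed valves are one-node-thick no-slip lines, admitting a small
  leakage bounded by the logged mass balance.
- The pressure openings impose equal gauge pressures at all pulmonary
  veins; the inter-vein flow split is therefore geometric, not
  physiologic.
- Cohort draws are independent normals; no inter-parameter correlation
  (e.g. volume–EF coupling beyond group membership) is modelled.
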