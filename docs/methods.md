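# Methods

This note records the modeling choices behind `atriafiber`: what is
computed, under which assumptions, which knobs matter, and what the tests
do and do not establish.

## Harmonic anatomical coordinates

All anatomical structure derives from seven scalar fields, each the P1
finite-element solution of a Laplace problem on the wall volume Ω with
Dirichlet data on tagged boundary sets or landmark nodes and homogeneous
natural conditions elsewhere. The boundary data (dimensionless, almost all
in [0, 1]) make each field a normalized distance:

| field | data | reading |
|---|---|---|
| φ0 | endocardium 0, epicardium 1 | transmural coordinate; s = ∇φ0 |
| φ1 | appendage-tip node 0, fossa-ovalis node 1 | appendage↔septum sweep |
| φ2 | left PV rims 0, right PV rims 1 | lateral↔septal sweep |
| φ3 | superior PVs 1, inferior PVs 0, accessories intermediate | anterior/posterior separator |
| φ4 | MV ring 1, major PVs 0, right middle PVs 0.1, LAA and FO regions 0.5 | valve↔vein distance |
| φ5 | left PVs + MV ring 0, LAA 0.5, right PVs 1 | antral field |
| φ6 | left PVs + right inferior PV + MV ring 0, LAA 0.05, right PVs 1 | anterior-wall fiber field |

Solution order is φ0, φ1, then φ2…φ6, because the "LAA region" and "FO
region" data of φ4–φ6 are interior constraints on node sets defined by
thresholds on φ1 (closed intervals; defaults φ1 ≤ 0.05 for the LAA, φ1 ≥
0.95 for the FO, configurable). Two documented alternatives exist: the
φ4 LAA/FO datum can be set to 1/0 instead of 0.5/0.5, and the φ6 MV-ring
datum can be split into septal (1) / lateral (0) halves instead of the
uniform 0; the defaults are the first reading in both cases.

Landmark Dirichlet data default to single-node constraints. Point
constraints for the 3D Laplacian are not mesh-convergent, but on the thin
atrial shell the field behaves like a 2D logarithmic potential and varies
usefully at practical resolutions; an optional spherical patch radius
(`landmark_patch_radius`) is available to desensitize refinement studies.

Dirichlet conditions are imposed by symmetric elimination, so constrained
nodes are exact and the reduced operator stays SPD. Systems up to 2·10⁵
unknowns use a sparse direct factorization (fully deterministic); larger
ones fall back to ILU-preconditioned CG at 1e-10 relative tolerance. The
discrete maximum principle is not guaranteed by P1 on arbitrary meshes; on
the synthetic anatomies the generator keeps element quality high enough
that measured violations are zero, and the test suite asserts a 1e-8
ceiling rather than assuming it.

## Region decomposition

Subregions are defined per element (fields evaluated at centroids — the
mean of nodal values — because P1 gradients are element constants and
nodal labeling would be ambiguous on region borders). Each table row
carries a layer scope (endo/epi/both; an element is endocardial iff its
centroid φ0 < 0.5, a deliberately sharp midwall transition), strict
threshold constraints α < φᵢ < β, and a frame rule. Rows apply in order
with sequential subtraction; the final row has no constraints, making the
partition exhaustive, disjoint, and tie-free by construction.

The shipped default table has 17 rows: anatomical floors (A, B), appendage
(C), fossa ovalis split by layer (D endo circumferential, E epi
longitudinal), right inferior PV epi (F), right PVs (G), left PVs (H),
Bachmann's bundle (I), left/right roof (J, L), posterior septum (P),
endocardial anterior wall (N, O), left lateral ridge (K, both layers — its
endo and epi rules coincide, so one row serves both), posterior wall (Q),
and the lateral-wall catch-all (R). Threshold values are anatomy-dependent
tuning constants, not physical constants: the defaults were calibrated
once against the default synthetic anatomy's computed fields (the intended
semi-automated workflow — solve fields, inspect, set thresholds) and are
fully overridable via the YAML `regions:` table.

## Fiber frames

Per element, s is the normalized ∇φ0 (volume) or the outward surface
normal (surface mode). The region's chosen gradient g is projected onto
the plane orthogonal to s and normalized; the f-branch takes f = ĝ⊥
(fibers along the field's ascent: longitudinal/oblique regions), the
n-branch takes f = ĝ⊥ × s (fibers along the field's level sets:
circumferential regions). In both branches n is then re-derived as
n = f × s, which keeps every emitted triad right-handed with n = f × s
exactly; for the n-branch this flips the sign of the projected gradient,
which is immaterial because the conductivity tensor is built from outer
products. Degenerate cases (|g⊥| below 1e-8 of |g|, or zero gradient)
copy the frame of the nearest successfully assigned element and
re-orthogonalize it against the local s; the fallback count is reported
and the QC bound used in tests is 0.5 % of elements. On all shipped
anatomies the measured count is 0 — the generator explicitly absorbs
rim-only wedge elements (whose harmonic fields would be constant) into the
adjacent opening.

## Synthetic idealized LA

The generator emulates a preprocessed patient anatomy at desk scale: a
subdivided icosphere is deformed into an ellipsoidal chamber (default
semi-axes 30 × 25 × 22 mm, centered so the mitral orifice cut lies in the
z = 0 plane) with smooth tube protrusions for the PVs (radius 4.5 mm,
length 10 mm, open), optional accessory right PVs and a common left trunk,
and a closed appendage tube whose end-cap apex is the `laa_tip` landmark;
`fo_center` is the septal mid-posterior endocardial node. Faces are
removed at the mitral orifice and tube ends, and the surface is extruded
through the 2 mm wall along vertex normals into 3 prism layers, each prism
split into three tetrahedra by a smallest-vertex-index rule that keeps
shared quad faces conforming. Tube patches are checked for pairwise
angular separation and infeasible configurations fail loudly.

Defaults: 4 icosphere subdivisions (~2 mm surface edges, ~39 k tets), 3
elements through the wall. These sizes keep a full seven-field solve
under ~5 s and the EP harness in seconds-to-minutes while leaving every
asserted property resolution-robust; coarser (`refine_levels=3`) meshes
are used for simulation-heavy tests. What the generator does *not*
emulate: trabeculation, appendage lobes, wall-thickness variation,
fossa-ovalis geometry (landmark only), or statistical shape variation —
so passing tests demonstrate correctness of the construction machinery
and its variant handling, not anatomical fidelity on patient meshes,
where thresholds must be re-tuned per anatomy by design.

## Monodomain harness

The anisotropic monodomain equation is discretized with P1 elements
(consistent mass by default, lumping optional) and SBDF1: gating states
advance first (the two-current model uses an exact exponential gate
update), the ionic current is evaluated explicitly with new states and the
old potential, and the diffusion term is solved implicitly with a single
factorization reused across steps. No-flux conditions apply on the whole
boundary. Mesh coordinates convert mm→cm so the standard units (mS/cm,
µF/cm², cm⁻¹, ms) combine to µA/cm³.

The reaction term follows the normalized-potential convention common to
phenomenological cardiac models: the PDE advances u (0 rest, ~1 peak) and
an affine map (V = −80 + 100u mV) is applied for output and for activation
detection. Under this convention the default stimulus (1000 µA/cm³, 2 ms,
with χC_m = 1000 µF/cm³) injects Δu ≈ 2, safely supra-threshold. The
shipped two-current model (τ_in = 0.3, τ_out = 6, τ_open = 120, τ_close =
80 ms, u_gate = 0.13) gives a plane-wave speed of ≈0.39 mm/ms along fibers
at the default conductivities on a 0.2 mm bar; its rest state is an exact
equilibrium, so quiescence tests have zero tolerance pressure. Biophysical
atrial cell models plug in behind the same `IonicModel` contract (state
vector, I_ion, dy/dt, voltage map).

LAT is the first upward crossing of −40 mV (configurable), linearly
interpolated between steps and recorded streamingly; nodes that never
cross keep a NaN sentinel. CV is 1/|∇LAT| per element from the P1
gradient, with sentinels where any node is unactivated or the gradient
magnitude is below 1e-6 ms/mm. Both estimators are deliberately simple
and defined in the package, since neither has a canonical definition.
The default anterior-wall stimulus site is chosen in field coordinates —
the epicardial node minimizing |φ2 − 0.5| + |φ3 − 1|, i.e. the center of
the anterior wall at its superior margin, the top of Bachmann's bundle —
with a 2–2.5 mm spherical support; explicit coordinates override it. The
appendage-tip activation time is reported both at the landmark node and
as the maximum over the appendage region, since the probe definition is a
convention.

Time step defaults: 0.02 ms on fine benchmark bars, 0.05 ms on the LA
meshes — comfortably inside SBDF1's stability range for the two-current
kinetics (τ_in = 0.3 ms), as the dt-halving test (<2 % CV change)
confirms.

## Numerical and design notes

- Strict inequalities in the characteristic functions mean boundary
  values α, β never belong to a region; ties between regions cannot occur
  because subtraction is ordered.
- Accessory-PV φ3 values are evenly spaced in (0, 1), superior-most first
  (one accessory → 0.5); no canonical values exist, and the choice only
  shifts the anterior/posterior separator smoothly.
- `extract_layer_surfaces` orients both surfaces away from the chamber
  centroid so the surface-mode s is consistently endo→epi-like.
- All stages are deterministic: identical configs reproduce byte-identical
  VTU outputs, which the manifest checksums make checkable.
- Known limitations: two layers only (no continuous transmural rotation);
  MSH v4 is not read; the surface-mode region table reuses the volume
  thresholds, so per-layer tables may need retuning on strongly
  non-parallel surface pairs; CV from inverse LAT gradients is biased near
  wavefront collisions and stimulus sites (sentineled, not corrected).
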