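# Methods

This note records the modelling choices behind `breastsim`: what is
simulated, what the defaults mean, what the synthetic phantom does and
does not emulate, and where the genuinely open design decisions were
settled.

## Constitutive model and discretisation

The breast soft tissue is a homogeneous, compressible Neo-Hookean solid,

Ψ(F) = μ/2 (tr(FᵀF) − 3) − μ ln J + λ/2 (ln J)²,  J = det F,

discretised with linear tetrahedra and one quadrature point per element
(constant F).  This matches the mesh scale the tool targets (roughly
5,000–13,000 tets for planning, 1,000–2,000 for real-time navigation) and
keeps assembly fully vectorised.  The gravity volume integral is lumped
equally onto the four nodes of each tet, which is exact for the linear
displacement field of a P1 element; as a consequence the total gravity
force is exactly ρ g V for any state, a property the tests assert.

Material input is (E, ν, ρ) with derived μ = E/(2(1+ν)),
λ = Eν/((1+ν)(1−2ν)), and C₁ = μ/2 (the stiffness parameter the breast
literature reports).  Defaults: ν = 0.45 (nearly incompressible soft
tissue; ν → 0.5 is rejected because λ diverges), ρ = 1000 kg/m³ (water).
Only E is ever estimated: a single scan pair cannot identify a
heterogeneous or layered material without overfitting, so heterogeneity
is deliberately out of scope.

States with J ≤ 0 in any element are assigned infinite energy.  The ln J
terms act as a barrier, and the line search simply rejects inverting
steps; no explicit inversion-recovery scheme is used.

## Quasi-static solver

Equilibrium minimises elastic plus gravity potential over the free nodes;
rigid (chest-wall or applicator-engaged) nodes are eliminated from the
unknowns, so Dirichlet data is satisfied exactly, to the bit.  Newton
steps solve the reduced system with conjugate gradients (Jacobi
preconditioner, relative tolerance 1e-8, iteration cap 10× the unknown
count); element Hessians have negative eigenvalues clamped to 1e-12·μ so
CG always sees a positive semi-definite operator; steps are accepted under
an Armijo backtracking line search (factor 0.5, up to 20 halvings), which
makes the energy trace non-increasing.

Convergence is declared when the free-node force norm drops below
`grad_tol`.  The default is force-scale-relative: 1e-6 · ρ·9.81·V_total,
i.e. one millionth of the total weight of the simulated tissue, making
the criterion independent of mesh size and unit choices.  If the direct
solve stalls (large gravity rotations on soft meshes), the load is ramped
in 5 equal increments — a standard quasi-static continuation, triggered
automatically and invisible to callers.

## Gravity reference protocol

Surface/CT data is acquired supine, i.e. already gravity-loaded.  Rather
than estimating an unloaded rest shape, the supine geometry is treated as
stress-free and a target orientation is simulated by applying the gravity
*difference* g_target − g_supine.  Because the gravity potential is linear
in g, this single solve is identical to "apply negative supine gravity,
then add the rotated gravity".  The approximation ignores the pre-stress
stored in the supine configuration; the stiffness estimation partially
absorbs this error because it is calibrated through the same protocol.
Estimating rest shape and stiffness jointly would be more faithful but
adds many degrees of freedom and nonlinearity for little benefit when the
surgical posture is close to supine.

Bed angles map to gravity as g = R_lat(LAT) · R_ap(AP) · (0,0,−9.81) in a
patient frame with x left→right, y caudal→cranial, z posterior→anterior
(supine gravity −z).  AP rotates about x, LAT about y, applied AP-first.
Clinical sources rarely state these conventions; both the frame and the
composition order are fixed project-wide here and overridable by
constructing `GravitySpec` directly.  The "sitting" posture used for
estimation is a 90° rotation about x (gravity → −y, caudal); the true
patient posture ("relaxed sitting") is not standardised, and the angle is
configurable.

## Stiffness estimation

For each candidate E (searched in log₁₀ space over [0.05, 10] kPa,
bounded Brent minimisation, absolute tolerance 1e-3 in log₁₀E ≈ 0.23% in
E), the pipeline: solves the target configuration, pushes the reference
scan through the deformation by barycentric transfer, rigidly registers
the result to the target scan (point-to-point ICP with closed-form Kabsch
fitting), and scores the mean squared nearest-neighbour distance.
Registration must be rigid: any non-rigid step would absorb the elastic
deformation the parameter is being fitted to.  The one-sided residual
(transformed scan → target) tolerates partial scan coverage.  The
initialiser E = 0.609 kPa corresponds to the literature-average
C₁ = 0.105 kPa at ν = 0.45.  Candidates whose forward solve fails are
scored with a large finite penalty so the bracketing search continues.

On noise-free synthetic cases the estimator recovers the generating E to
well under 5% across 0.3–2.0 kPa (the range seen clinically), and the
sampled objective is unimodal in log E over that window — both are
asserted by tests.  With 0.5 mm scan noise recovery degrades gracefully
(about 1% at 2,000 tets in the shipped cross-validation pipeline).

## Scan transfer, signed distance, ROI

Scan points embed into their host tet with exact barycentric coordinates;
points just outside the mesh (scanner noise) snap to the nearest candidate
tet with clamped coordinates, rejected beyond 5 mm.  Transfer is exact
for affine deformations, which the tests exploit as an oracle.

Validation uses point-to-triangle signed distance with angle-weighted
pseudo-normals to disambiguate the sign at vertices and edges; the sign
flips globally if the reference orientation is inverted.  Errors are
summarised inside a 2-cm-radius surface patch centred on the skin point
nearest the tumor — the region where radiotherapy dose is planned and
accuracy actually matters.

## Navigation

The applicator is a rigid cylinder; nodes inside its volume at engagement
(capture tolerance 0.5 mm) are pinned to its frame and move rigidly with
every subsequent pose — bilateral coupling, a deliberate simplification
of tool–tissue contact (no separation, no sliding, no friction).
Engagement happens once per session.  Each pose update triggers a
warm-started quasi-static solve; a pose jump large enough to invert a
boundary sliver is subdivided automatically (rotation slerp + linear
translation, up to 6 halvings).  The tumor is a barycentrically embedded
material point.  Per-step wall time is logged, not asserted: real-time
budgets are hardware-dependent, and the right mesh size for interactive
use is chosen by the user (1,000–2,000 tets solve in tens of milliseconds
per step on a laptop-class CPU).

Quasi-static path independence — a 10-step path and a single jump to the
same final pose land on the same equilibrium — holds to ~1e-4 mm on the
phantom and is asserted to 0.01 mm.

## Synthetic phantom

The phantom is a hemisphere (default radius 60 mm) on a 160×160×10 mm
plate; plate nodes (z ≤ 0) are rigid, exposing the same free/rigid
structure as a segmented patient mesh.  Tetrahedralisation is Delaunay
over jittered interior grid points plus a Fibonacci lattice on the
spherical surface, filtered by centroid; grid spacing is calibrated so
the tet count lands within ±30% of the request.  Scans are the outward
boundary surface of the deformed mesh with isotropic Gaussian noise
(default σ = 0.5 mm, typical of consumer structured-light scanners) and
optional point dropout.  Everything is reproducible from a seed.

What the phantom does **not** emulate: anatomical breast shape and
ptosis, heterogeneous tissue (gland/fat/skin), partial scan coverage of a
real torso acquisition, scanner artefacts (outliers, holes,
registration bias between modalities), and chest-wall motion with
breathing.  Passing the synthetic cross-validation therefore demonstrates
the *pipeline* — solver, transfer, registration, estimation, error
metric — is correct and self-consistent at clinical noise levels, not
that a homogeneous Neo-Hookean model captures every real breast.

## Problem sizes used in the shipped checks

Unit and property tests run on 14-node random blobs and 400–900-tet
phantoms; discretisation-convergence checks compare ~2,000 against
~8,000 tets (apex displacement within 5%) and navigation tracking at
~1,600 against ~6,600 tets (tumor position within 2 mm).  The end-to-end
cross-validation runs at ~2,400 tets with σ = 0.5 mm noise.  These sizes
sit at the lower end of the clinically used range and were chosen so the
full validation suite completes in about a minute on one CPU core.

## Known limitations

- Gravity pre-stress in the supine reference is neglected (see protocol
  above); errors grow with the rotation angle away from supine.
- Bilateral applicator pinning cannot represent tissue separating from
  the applicator face.
- Homogeneous isotropic material; no skin shell, no viscoelasticity, no
  anisotropy.
- Chest wall is rigid and never re-posed between configurations.
- The Gmsh reader accepts MSH v2 ASCII only; VTU/VTK writers are ASCII.
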