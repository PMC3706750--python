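# Methods

`plantvem` simulates the growth of an elongated plant organ (the template is
the elongation zone of an *Arabidopsis thaliana* root) as a 2D longitudinal
section through the organ midline. This note documents the model, the
numerical choices, and what the synthetic test geometry does and does not
capture.

## Model

### Geometry and wall classes

Cells are simple polygons that share vertices and edges; the sharing is the
model's expression of symplastic growth (adjacent walls adhere and never
slide). Three wall classes are distinguished:

* **in-plane walls** — the wall material lying in the section plane,
  discretized into linear triangular elements (which may use Steiner
  vertices inside cells);
* **axial walls** — out-of-plane walls roughly parallel to the organ's long
  axis (edges within π/4 of the x-axis; the boundary case at exactly π/4 is
  classified cross so the rule is deterministic);
* **cross walls** — out-of-plane end plates of cells (the remaining edges).

Out-of-plane walls are 1D segments. Each edge is one geometric object, but
every cell incident on it owns its own *wall segment* with independent
rheological parameters — an interior edge carries two segments, an
organ-boundary edge one.

### Forces

Inertia is negligible at cell scale, so the total force on every free
vertex is zero at all times; the shootward (max-x) end of the organ is
pinned to remove rigid-body motion.

* **Turgor.** Each cell carries a uniform pressure p (default 0.3 MPa).
  Every anticlockwise boundary edge (i → j) contributes (p/2) R(x_j − x_i)
  to both endpoints, with R the rotation by −π/2 (outward normal times
  edge length). Steiner vertices receive no pressure load; when a boundary
  edge has been subdivided, each sub-edge is loaded independently (the sum
  over sub-edges of a straight edge equals the unsplit load).
* **In-plane walls.** Each triangle carries a viscous Cauchy stress
  resultant σ = σ_y + σ_a with no elastic part:
  σ_y = 2 μ_eff(ε) E with the Papanastasiou-regularized effective
  viscosity μ_eff = μ1 + (τ_w/ε)(1 − exp(−ε/ε*)), ε = |E| (Frobenius);
  σ_a adds two cellulose-microfibril families a_1, a_2 with extensional
  viscosity μ2 and fiber-shear viscosity μ3. Fibers are material lines:
  a_k = F A_k/|F A_k| where F is the deformation gradient from the stored
  reference configuration, so they rotate with the tissue as it stretches.
  Element edge tractions f_pq = −σ n_pq |x_q − x_p| are split half-and-half
  onto the edge endpoints.
* **Out-of-plane walls.** A segment's tensile stress resultant is
  σ_e = 2[μ + (τ/ε_e)(1 − exp(−ε_e/ε*))] ε_e + λ(l/l0 − 1), where the edge
  strain rate is computed from the endpoint velocities by projection,
  ε_e = (x_j − x_i)·(v_j − v_i)/l². Inside the regularization |ε_e| is used
  with the sign restored, so brief compressive transients are handled
  smoothly. Axial walls default to purely viscous (λ = 0), cross walls to
  viscoelastic (λ_cross = 100 MPa μm) — cross walls grow slowly and are
  not clearly yielded, and the elastic element keeps the transverse
  dynamics well-posed.

The regularized yield law reproduces both stated limits: pre-yield
(ε ≪ ε*) effective viscosity μ1 + τ_w/ε* (stiff), post-yield (ε ≫ ε*)
viscosity ≈ μ1 plus a constant plastic stress (extensible). The typeset
alternative (τ_w/ε*)(1 − exp(−ε*/ε)) shares those limits; the Papanastasiou
form was chosen for its standard use in regularizing Bingham flow.

### Default parameters

All defaults live in `plantvem.config.SimConfig` (μm / hr / MPa units, no
internal nondimensionalization): p = 0.3 MPa; μ1 = 0.15 MPa hr,
μ2 = 20 MPa hr, μ3 = 0, τ_w = 0, ε* = 0.05 hr⁻¹ (in-plane);
μ_axial = 1.5 MPa μm hr, τ_axial = 0, λ_axial = 0;
μ_cross = 0.05 MPa μm hr, λ_cross = 100 MPa μm, τ_cross = 0;
P_b = 2×10³ μm hr⁻¹, λ_b = 16 hr⁻¹, α_b = 2 nM hr⁻¹, k_b = 10⁻⁵ nM,
n_b = 2, τ_w⁰ = 0.1 MPa, τ_axial⁰ = 0.1 MPa μm; β = 0.1 hr⁻¹. The
viscosities follow the calibration μ1 = p/(4ε̇), μ_axial = H p/(8ε̇) at
ε̇ = 0.5 hr⁻¹ and H = 20 μm, which makes the in-plane and axial walls
resist elongation equally and gives an isolated cell the observed
elongation rate of the root elongation zone. Yield stresses default to 0
(the linear law); the growth-inhibitor model switches the non-linear law
on by modulating τ_w and τ_axial.

### Growth-inhibitor regulation

Concentrations b_m are uniform per cell and evolve by wall-limited
diffusion between neighbors (flux P_b S_{m,n}(b_n − b_m) through a shared
wall of length S_{m,n}), first-order decay λ_b, and production α_b in
quiescent-center (QC) cells only. Yield stresses are modulated by a Hill
function: τ = τ⁰ (1 + (b_m/k_b)^{n_b}) for the cell's in-plane wall and
its axial segments (cross walls are not modulated). The half-saturation
k_b sets where along the axis rapid elongation begins; n_b sets the
sharpness. Dilution of b_m by growth is deliberately absent from the ODE:
areas and shared-wall lengths are simply re-read every chemistry step. The
printed form of the modulation argument is ambiguous between k_b·b_m and
b_m/k_b; the ratio form is used here because k_b is a half-saturation
constant with concentration units and the division threshold is b_m > k_b.

### Cell division

Every cell has a timer advancing at rate β, initialized U[0, 1) from the
run's seeded generator. A cell divides when its timer exceeds 1 and
b_m > k_b (so division is confined to the meristem proxy and a cell waits
1/β between divisions; the population there doubles every 1/β). The
division wall passes through the cell centroid perpendicular to the
direction of maximum strain rate — the dominant eigenvector of the
area-weighted mean rate-of-strain tensor over the cell's elements. If that
tensor is isotropic or zero, the wall is placed perpendicular to the
cell's longest principal geometric axis (area-moment eigenvector). The two
crossed boundary edges are subdivided (an existing vertex within 10⁻³ μm
is reused); neighbors sharing those edges gain the vertex and are
retriangulated. Daughters inherit pressure, type, material, fibers and
b_m; timers reset to zero; the new wall gets per-class default segment
parameters with rest length equal to its current length. One division per
cell per step, in cell-id order.

## Discretization and solver

### Triangulation

`triangle`-style quality meshing is done in two stages: boundary edges
longer than the target spacing h = √(2·max_area) are subdivided tissue-wide
(shared edges once, so meshes conform across walls; wall segments split
with proportional rest lengths, which leaves all forces unchanged), then
each cell is meshed from its boundary points plus a deterministic
triangular lattice of interior Steiner points (kept a margin
h·max(0.3, sin(min_angle)) from the boundary) via Delaunay triangulation,
with triangles filtered to the polygon and checked to tile it exactly
(tolerance 10⁻⁹ relative). A constrained Delaunay triangulation of the
polygon vertices alone (GEOS) is the fallback for non-convex corner cases.
Default quality: min_angle 20°, max_area 60 μm² on the full-scale organ
(order 10⁴ elements on the full organ); the
reduced-scale experiment presets use 100–250 μm².

### Remeshing

As the organ elongates, elements stretch and the linear-element strain
rate degrades, which artificially stalls organ bending. Every
`remesh_every` steps (default 5, i.e. 0.5 hr) each cell is retriangulated
in its current configuration. Reference positions of new vertices are
assigned by barycentric interpolation over the old elements (exact for
affine fields; a point outside all old elements by more than ~10⁻⁶ is
snapped to the nearest one with a warning), and fiber directions are the
per-cell reference constants, so remeshing is invisible to the mechanics
up to interpolation error. Under strongly non-affine deformation (e.g.
walls that were straight in the reference but have bulged into arcs) a
new element's interpolated reference corners can come out collinear or
inverted; such an element's reference is reset to its current shape, a
local loss of fiber-advection history that only arises in regimes where
the fibers are mechanically irrelevant. Boundary edges stretched beyond h are
re-subdivided during remeshing: without this, strip-shaped cells (height
≲ h) would keep their elongated boundary triangles and remeshing would
not restore quality. The subdivision is force-neutral at the instant it
happens (collinear sub-segments with proportional rest lengths).

### Time integration

A split-timestep scheme with fixed Δt (default 0.1 hr): (1) the inhibitor
ODEs advance by one implicit-Euler step with geometry frozen (sparse
M-matrix solve; concentrations stay non-negative); (2) yield stresses are
updated from the new concentrations; (3) the mechanics advance by backward
Euler — solve residual((x_{n+1} − x_n)/Δt at x_{n+1}) = 0 for the
free-vertex velocities; (4) divisions are attempted; (5) periodic remesh.
Everything is deterministic given the config seed.

The nonlinear solve is Newton iteration on a sparse finite-difference
Jacobian: the sparsity pattern is the vertex adjacency through shared
elements/segments/pressure edges; columns are grouped by greedy coloring
of the column-conflict graph so one Jacobian costs (number of colors + 1)
residual evaluations — about 20–30 for these meshes, independent of organ
size. Forward differences use step 10⁻⁶(1 + |v_k|). The factorized
Jacobian is reused for up to 4 iterations (modified Newton); a fresh one
is built when a step needs damping.

Two solver details matter and were found necessary in practice:

* **Backtracking damping.** A slender organ is a viscous beam whose
  transverse tip compliance scales like (L/H)³; the Jacobian has
  correspondingly tiny singular values in organ-scale bending modes, where
  the residual is dominated by its quadratic terms. Undamped Newton
  overshoots and oscillates in those modes; step halving on the residual
  norm (up to 8 times per iteration) restores monotone convergence.
* **Stopping criterion.** For the same reason, forcing the force residual
  down to the absolute tolerance 10⁻⁸ MPa μm is not always possible: the
  bending-mode stiffness can fall below the finite-difference noise floor
  of the Jacobian, after which Newton's flat-mode direction is
  noise-limited. Newton therefore stops when the residual norm is below
  10⁻⁸ MPa μm *or* the weighted velocity update is below
  10⁻³ (1 + ‖v‖∞) μm hr⁻¹ (an IDA-style relative criterion: per-step
  position changes below ~10⁻³ of the velocity scale, orders of magnitude
  under the backward-Euler local error). If the iteration budget is
  exhausted with the residual already below 10⁻³ MPa μm — a force
  imbalance 4–5 orders below the working loads — the step is accepted
  rather than pointlessly re-halved.

On Newton failure the internal sub-step is halved (down to
Δt/2¹², about 10⁻⁴ hr at the default timestep) and re-doubled after easy
successes, so stiff fast transients — e.g. the bulge relaxation of nearly
inviscid walls, which initially needs ~10⁻⁴ hr resolution — cost a burst
of small sub-steps; reported output times never change. Warm starts carry
the previous step's
velocities by vertex id; vertices created by remeshing or division get an
affine least-squares fit of their cell's known boundary velocities — the
velocity field is nearly linear within a cell, and a poor guess there both
perturbs the soft bending modes and can transiently invert elements.

Cross-wall rest lengths are held at their creation values (elastic strain
accumulates); rest-length growth for cross walls is not modeled.

## Organ-scale metrics

* **Midline and tip angle.** The midline is traced by marching
  cross-section centroids from the pinned end: step half a cap-height
  along the current direction, cut the organ polygon with a transverse
  line, take the midpoint of the cross-section containing the candidate,
  repeat; the final segment is extended to the boundary. θ is the angle of
  the tip chord relative to the −x growth direction, positive upward. On a
  fabricated quarter-circle strip this reads θ = π/2 within 0.05 and the
  length within 1%. Sign convention: a softened *top* file makes the top
  grow faster, so the organ arcs concave-down and θ is negative; bending
  magnitude and shape, not sign, are the scientific readouts.
* **Mean fiber angle φ** — area-weighted mean over elements and both
  families of arccos|a_k·ŷ| ∈ [0, π/2].
* **Per-cell expansion rate** — (dA/dt)/A from the time-derivative of the
  shoelace formula over boundary vertex velocities.

## Synthetic geometry

The generator tiles an n_files × total_length rectangle (defaults 5 files
of 20 μm height, 2000 μm length). Within each file, cross walls are placed
from the rootward (min-x) end with spacings drawn U[L_x, 2L_x]
(L_x = 50 μm); the last cell is truncated to fit, and a truncated sliver
under 0.5 μm is merged into its neighbor. Files are sampled independently
(staggered walls); whether the real layout staggers or aligns walls is not
constrained by anything we reproduce. Cross-wall positions in adjacent
files closer than 1 μm are snapped together — micron-scale offsets would
otherwise create sliver edges on the shared interface that degrade the
mesh without changing the biology. Vertices at x = total_length are
pinned in both components.

What the synthetic organ does *not* emulate: curved outlines and the root
cap, per-tissue-type cell diameters and wall properties, spatially varying
fiber angles, non-uniform turgor, and the traced realistic apex geometry
(the generic tissue-JSON importer accepts such a geometry, but none is
bundled). Passing the reduced-scale experiments therefore demonstrates the
mechanics, regulation and numerics of the method — not a quantitative
prediction for any real root.

## Reduced-scale experiment presets

The scripted scenarios (`plantvem.scenarios`) run on a 1000 μm organ with
max_area 100–250 μm² so each completes in seconds-to-minutes on one CPU;
`full_scale=True` restores the 2000 μm organ and the fine mesh. The
bending comparison uses max_area 100 μm² so cells carry interior Steiner
points and remeshing can restore element quality. Bending magnitudes
scale with organ length, so reduced-scale tip angles are roughly half the
full-scale ones; the qualitative contrasts (anisotropy vs rounding,
remesh vs stall, fiber-reorientation deceleration, thin-file bending) are
unchanged.

## Known limitations

* No elastic stress in in-plane walls and no bending stiffness; wall
  thickness is constant (lumped into the viscosities).
* No cell–cell or self contact: in extreme rounding regimes bulged
  boundaries can overlap slightly (the run-time topology check tolerates
  a relative area mismatch up to 5×10⁻³ and warns above 10⁻⁶).
* The inhibitor is a single generic species; no dilution by growth, no
  hormone networks.
* Fixed-step backward Euler only (first order); no adaptive error
  control. The step-halving fallback guards robustness, not accuracy.
* Division is timer-driven; no size control or alternative plane rules.
* 2D only; out-of-plane structure enters only through the three wall
  classes.
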