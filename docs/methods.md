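# Methods

## Scope and model

`venoflow` computes four hemodynamic descriptors of cerebral venous outflow —
WSSmean, OSImean, the mean number of WSS critical points, and the total
vortex core-line length — on synthetic, idealized geometries, and compares
them bilaterally.  The flow model is incompressible Newtonian blood
(μ = 0.04 P, ρ = 1.06 g/cm³ by default; the standard values for
cerebrovascular CFD, overridable through `FluidProperties`) in rigid vessels
with no-slip walls, prescribed volumetric inflow and zero outlet pressure.
All quantities are CGS: cm, s, g, dyne/cm² (flow rates in mL/s; echo
quantities in their clinical units, mL and mL/min).

The package deliberately replaces patient-specific anatomy with constructs
whose answers are known in closed form: straight tubes, torus-segment bends,
Y bifurcations, a 2-D stenotic channel; Poiseuille/Womersley/Lamb–Oseen
fields; surface vector fields with planted critical points.  This makes every
downstream metric testable against an analytic oracle.

## Geometry and meshing

Tube-like volumes are meshed by sweeping a polar disk triangulation along the
centerline and splitting each prism into three tetrahedra with the
smallest-global-index diagonal rule, which guarantees face-conformity between
neighboring prisms.  Radial node positions follow r_k = R·sin(πk/2n_r),
grading the mesh toward the wall: wall-adjacent cells are thin, so the
cell-constant velocity gradients that feed the WSS recovery are sampled close
to the wall (the recovered Poiseuille WSS on a resolution-64 tube is within
1% of 4μQ/πR³; an ungraded mesh of the same size is ~3× worse).  The tradeoff
is a coarse interior: core-line extraction of a vortex far from any mesh node
line is unreliable on these meshes (see Limitations).

The wall surface is the boundary of the tet mesh (faces appearing exactly
once), oriented outward, with integer cell labels: 0 wall, 1 inlet, 2/3
outlets, 9 internal junction caps.  The Y bifurcation is three swept tubes
meeting at the trunk-top plane; the junction is geometrically open
(non-conforming), which is irrelevant for the per-branch analyses the
pipeline performs and is labelled so downstream code can exclude it.

Cross-sectional areas are computed by slicing every tetrahedron with the
plane and summing the cut polygons; disconnected cuts (a stenotic throat
splitting the lumen) are therefore summed naturally.  Nodes exactly on the
plane are perturbed to one side (simulation of simplicity) so planes through
mesh layers still cut once.  Regions of interest are slabs between two
planes (both normals pointing from the first plane to the second), minus,
optionally, the connected triangle component containing an exclusion seed —
the mechanism for excluding an occipital-sinus analog.

## Boundary conditions

Echo arithmetic is exact: SV = EDV − ESV, CO = HR × SV, excess (shunt) flow
= CO − reference CO, with the BSA-referenced reference treated as a clinical
input.  Negative excess is allowed but flagged.

Waveforms carry one cardiac cycle of flow-rate samples.  Because clinical
phase-contrast acquisitions have only 5–10 cardiac phases, periodic
interpolation is trigonometric (least-squares Fourier fit with
floor((n−1)/2) harmonics) for ≤ 10 samples and piecewise-linear above that;
linear interpolation at 5 phases visibly distorts cycle integrals.  Cycle
integrals use the trapezoidal rule with periodic closure.  Three samples is
the hard validity floor (resampling needs it); five is the documented
practical minimum, matching the coarsest acquisition.

`synth_waveform` builds a random band-limited waveform (harmonics with 1/k
amplitude decay, seeded phases) normalized on its sample grid so the cycle
mean and the pulsatility (max−min)/mean are exact.  Pulsatility is capped at
1, which guarantees non-negative flow.  Defaults used by the pipeline —
total inflow 8 mL/s (≈ 480 mL/min, the scale of a high-flow neonatal shunt),
pulsatility 0.4, period 0.5 s (HR 120), 10 phases — are fixed study
conditions, not tuning knobs.

## Flow fields

The Womersley sampler decomposes the driving waveform into Fourier harmonics
and superposes, per harmonic, the exact rigid-tube solution
u_n(r) ∝ [1 − J₀(β_n r/R)/J₀(β_n)] with β_n = i^{3/2}α_n, normalized so each
harmonic's cross-sectional flux equals the waveform harmonic; the zeroth
harmonic is the Poiseuille parabola.  The harmonic count is limited by the
waveform's own sampling.  Validated limits: α = 0.1 matches the quasi-steady
parabola to 0.01%, the flux error at any phase is < 0.01%, no-slip holds to
1e-10 of the centerline scale, and at α = 10 the oscillatory profile is blunt
(centerline/mean < 1.6).

The Lamb–Oseen sampler gives u_θ(r) = Γ/(2πr)(1 − e^{−r²/r_c²}) around an
arbitrary axis plus uniform axial flow — divergence-free, with the axis as
the unique swirl center, i.e. a known core line.

Planted surface fields put a critical point of prescribed class at a chosen
mesh node: the canonical 2×2 linearization (±I for nodes, rotation±growth
for foci, diag(1,−1) for saddles) acting on tangent-plane coordinates.  With
a nonzero background the pattern is blended in with the C¹ window
w(s) = (1−s²)², which leaves the zero and its Jacobian exact at the plant;
with zero background the linear pattern extends globally, because windowing
a zero background would null the far field and seed spurious zeros along the
window rim.  Inserting a +1 pattern into a nonzero background on a surface
of zero Euler characteristic necessarily creates a compensating −1 zero near
the window rim; the pipeline's planted-vortex scenario accounts for this
(its planted side shows the focus plus its companion saddle).

## 2-D solver

A Chorin projection method on a staggered MAC grid: first-order upwind
advection, explicit diffusion, and a prefactorized sparse pressure Poisson
solve with homogeneous Neumann conditions at walls and inlet and a
zero-pressure Dirichlet outlet — the smallest solver with the boundary
semantics of the venous CFD setup it emulates.  The inlet profile is
parabolic, scaled to the instantaneous waveform value (the contract
prescribes flow rate, not profile).  The reporting step is dt = 0.01 s over
two cycles (the second analysed); internally the solver sub-steps whenever
the advective CFL (limit 0.4) or diffusive (0.2 h²/ν) bound is tighter, so
reported snapshots stay on the configured cadence.  With sub-stepping
disabled a violated limit raises instead.  Measured behavior on a 128×32
channel: face divergence at machine precision, inlet/outlet mass balance to
1e-13, steady plane-Poiseuille centerline within 0.2% of 1.5× mean, cycles 2
and 3 of a pulsatile run agreeing to 0.01%, halving the spacing cuts the
profile error by more than 2×, and a 50% stenosis at Re = 200 produces a
downstream recirculation zone.

## WSS and cycle metrics

Velocity gradients are cell-constant (linear tetrahedra) and volume-weighted
onto wall nodes; the traction μ(∇u + ∇uᵀ)·n̂ is projected tangentially with
area-weighted node normals.  Nodes on cap rims mix wall and cap normals, so
ROIs should stay away from tube ends (the pipeline's ROI spans the central
70% of each branch).  TAWSS and OSI integrate over the cycle with periodic
trapezoid weights; OSI is clamped to [0, 0.5] and defined as 0 (with a
warning) where ∮|τ|dt = 0.  Spatial means are area-weighted per triangle —
node counting would bias graded triangulations.

## Topology metrics

Critical-point detection treats the nodal tangential vectors as a
barycentric-linear 2-vector field per element.  An element is examined when
its minimum nodal |τ| falls below the threshold (default 1e-5 dyne/cm²,
configurable) or its nodal vectors do not lie in a common open half-plane;
the half-plane test is exactly the condition for the linear field to vanish
inside the element, so the union is conservative — a pure magnitude filter
would miss zeros between large-magnitude nodes.  The zero is located by the
2×2 linear solve (exact for linear fields, hence position error < 1e-6 cm
for planted cases at any resolution) and classified by the Jacobian
eigenstructure: det < 0 saddle (index −1); complex pair source/sink focus by
sign of the real part, with |Re| ≤ 1e-6·|Im| reported as a center; real
eigenvalues of one sign source/sink node.  Near-singular Jacobians are
flagged degenerate and excluded from counts.  Zeros detected from several
elements sharing an edge or vertex are merged within 1e-4 of the local edge
length, keeping the classification from the element with the largest |det J|.
Index sums satisfy Poincaré–Hopf on closed surfaces (verified against a
winding-number enumeration on a sphere and a torus).

Core lines use the Sujudi–Haimes parallel-vectors criterion on linear tets:
elements whose velocity-gradient tensor has a complex eigenvalue pair
(|Im λ| > 1e-7·‖J‖, which also suppresses the spurious tiny imaginary parts
of nilpotent shear gradients) contribute the segment where the velocity is
parallel to the real eigenvector, clipped by the faces.  Degenerate cases —
the zero locus running along an element edge, as happens when the vortex
axis is a line of mesh nodes — are handled by accepting node/edge zeros, and
identical segments shared by several elements around such an edge are
counted once.  Segments are stitched into polylines within 1e-6 cm; the
total length (the corelen metric) is independent of stitching.  The mean
critical-point count and corelen are arithmetic means over the analysed
phases, restricted to the ROI (surface) or mesh region (volume) under study.

## Bilateral report and pipeline

Fold ratios are predicted-stenosis-side / contralateral.  A zero denominator
with a nonzero numerator is flagged "undefined (contralateral zero)" and the
raw pair is reported — the source tables print the pair, not a ratio — while
0/0 is reported as 1 (the sides are equal).  Area changes are
round(100·(before−after)/before) to the nearest integer (half away from
zero), with unrounded values recoverable from the stored pair.  The
lateralization call uses the mean critical-point count alone, the one metric
consistently greater on the stenosing side; all other metrics are reported
but not used for the call, and a tie yields "none".

`run_pipeline` models each outflow branch as a straight tube in its own
frame carrying its share of the synthesized inflow as a Womersley field,
recovers WSS, and computes the four metrics over a mid-branch ROI.  The
planted-vortex scenario superposes a Lamb–Oseen vortex along the branch axis
*and* plants a focus-type WSS pattern at the vortex wall footprint: an
axis-aligned vortex alone leaves no WSS zero, while a wall-impinging vortex
does, and the explicit plant is the controlled stand-in for that signature.
Reports are deterministic given (config, seed) — byte-identical JSON on
rerun — and carry the config hash, seed and package version as provenance.
Default problem sizes (resolution 16–24, 5–10 phases, branch length 3 cm)
are chosen so a full bilateral run completes in seconds on one core.

## What the synthetic data does and does not show

The generators emulate pulsatile cardiac-cycle inflow at clinical phase
counts, swirling/recirculating flow with known vortex cores, and WSS fields
with known topology.  They do not emulate patient anatomy (tortuosity,
confluences, caliber variation), image segmentation error, non-Newtonian
rheology, wall compliance, or measurement noise.  Passing tests therefore
demonstrate that the *metrics pipeline* is correct and that the published
bilateral arithmetic follows from its inputs — not that the clinical
absolute values are reproduced: those depend on patient meshes and boundary
conditions that are not public, and on fluid properties the methodology
leaves unstated.

## Known limitations

* Core-line extraction needs interior mesh resolution comparable to the
  vortex core radius; on wall-graded swept meshes a vortex far from any node
  line can be mislocated.  The oracles and the pipeline keep vortex axes on
  node lines.
* The 2-D solver is a contract-compatible stand-in for a 3-D clinical
  solver: it honors the same boundary-condition semantics and time
  discipline, not the same geometry class.
* Cap-rim wall nodes mix wall and cap normals in the WSS projection; keep
  ROIs off tube ends.
* The bifurcation junction is non-conforming; per-branch analyses avoid it,
  and metrics should not be evaluated across the junction caps.
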