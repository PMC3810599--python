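# Methods

## Governing equations and discretisation

Below ~MHz frequencies magnetic coupling is negligible, so the electric
field in tissue is the gradient of a potential. The cytoplasm (conductivity
`sigma`, default 1 S/m; parameterised per compartment) conducts well enough
that no static charge accumulates, giving `laplacian(Phi) = 0` in the
interior; the membrane is treated as a thin capacitor with specific
capacitance `C_spec` (default 0.01 F/m^2 = 1 uF/cm^2); the bath is earthed,
so all potentials are absolute with `Phi = 0` outside.

The potential is stored on mesh vertices and assumed linear inside each
tetrahedron. Each vertex owns a median-dual control volume: inside every
adjacent tetrahedron, the dual surface around vertex `p` consists of six
planar triangles through the edge midpoints, face centroids and the tet
centroid. For a tet with corners `p, a, b, c` (vectors from `p`,
right-handed) the summed area vector of those six triangles is

    x = (a x b + b x c + c x a) / 3,

and the current collected by `p` from this tet is `sigma * grad(Phi) . x/2`,
with `grad(Phi)` recovered from the inverse of the 3x3 coordinate matrix
with rows `a, b, c` (its inverse has columns `b x c`, `c x a`, `a x b`
divided by the determinant, i.e. six times the volume). Gathering the
coefficient of each neighbour potential yields the coupling conductances
`G_pq`; summed over tets they coincide algebraically with the piecewise-
linear Galerkin stiffness matrix times `sigma`, which the test suite
verifies against an independently assembled stiffness oracle at 1e-9
relative. On meshes with obtuse tetrahedra individual `G_pq` can be
negative; the assembly reports (`n_negative_couplings`) but does not alter
them, since the flux balance remains exact.

Membrane capacitance uses the same equal-area median subdivision: each
membrane triangle contributes `C_spec * area / 3` to each of its vertices;
interior vertices have `C_p = 0` and contribute purely algebraic rows.

## Time stepping and node ordering

Backward Euler over a step `dt` gives

    (C_p + dt * sum_q G_pq) V_p - dt * sum_q G_pq V_q = C_p V_p(t) + I_p dt,

a sparse symmetric-pattern system that is factorised once per `(G, dt,
clamp set)` and back-substituted every step. Matrix rows couple only mesh
neighbours, so after renumbering the vertices the system is banded; storage
and factor cost scale with the half-bandwidth `b`. Two orderings are
provided:

* principal-axis: vertices sorted by projection on the largest-variance
  eigenvector of the coordinate covariance (ties: second, third axis, then
  index). Near-optimal for elongated shapes; costs one eigendecomposition.
* breadth-first search with optional Cuthill-McKee refinement (within a
  front, neighbours enqueued by ascending degree; ties by index) and a scan
  over starting vertices. `start_fraction = 1` tries every start; below
  that a uniform seeded sample is scanned and the permutation with the
  smallest achieved bandwidth wins. Plain (not reverse) Cuthill-McKee is
  the default; a reverse option exists.

The banded path uses the LAPACK general-band factorisation (`dgbtrf` /
`dgbtrs`). Because back-substitution costs O(n * 3b) per step while sparse
LU stays near the factor fill, the automatic mode switches to SuperLU when
`b > 128` (measured crossover on the branched fixture: 18x in favour of
sparse LU at `b = 474`) or when the band would not fit in a configurable
memory cap. Orderings never change the solution — only cost — and can be
saved to a text file carrying the vertex count and an adjacency checksum
so a stale ordering cannot be applied to a different mesh.

Clamped vertices get identity rows (their columns stay, so neighbours see
the clamped value); injected current is divided over a vertex set either
equally or by the area of boundary triangles fully inside the set, which
reproduces a uniform current density over an end cap.

Passive leak (a constant conductance per area to a fixed reversal) is
folded into the matrix diagonal rather than treated as an explicit
current; for a linear membrane this removes an O(dt) splitting error at no
cost. Channel currents from the hybrid engine remain explicit, as the
communication scheme requires.

## Membrane kinetics

Channels are Markov schemes over named states; transition rates are
constants or voltage-dependent tables (default tabulation -150 to +100 mV
at 0.01 mV, linear interpolation, clamped — not extrapolated — outside the
grid; the table reproduces the closed-form Hodgkin-Huxley rates to <1e-6
of their range). Conducting states carry either an Ohmic current
`n g (V - E)` or a single-channel GHK current

    I_s = P_s z_s^2 (V F^2 / RT) ([S]_i - [S]_o e^(-u)) / (1 - e^(-u)),
    u = z_s V F / RT,

with V taken inside-minus-outside and positive current meaning outward
flux of positive charge. For `|u| < 1e-4` a second-order series removes
the 0/0 at V = 0 while keeping relative error below ~1e-9; the V -> 0
limit is `P z F ([S]_i - [S]_o)`. With equal concentrations the GHK
current is exactly linear with equivalent conductance `P z^2 F^2 S / RT`,
which is the precise sense in which an Ohmic current approximates it. A
"pure current" GHK mode carries charge without moving ions.

## Hybrid stochastic algorithm

All gating transitions and GHK single-ion events across all membrane
triangles form one Gillespie direct-method queue (one RNG stream per
simulation keeps the method exact). A GHK event moves one ion between the
triangle's inner tetrahedron and the bath (ledgered, so total ion number
is conserved exactly) and adds `z` elementary charges — stored as an
integer — to that triangle's accumulated charge. Inner concentrations are
sampled from the single adjacent tetrahedron (ion count / tet volume); no
volumetric diffusion between tetrahedra is simulated here.

Communication with the field solver is adaptive: events execute while
they fall before the sync target (last update + `efield_dt`); the field
update then happens at the SSA clock value reached — usually slightly
earlier than the target and never later, leaving the SSA clock untouched.
If no event falls inside the window, the update happens exactly at the
target. Per triangle the communicated current is accumulated charge over
elapsed time plus Ohmic currents sampled at the current potential (they
are not integrated over the window); after the solve, triangle potentials
(mean of the three vertex potentials) and all voltage-dependent
propensities are refreshed and charges reset. GHK propensities are also
recomputed immediately for the one triangle whose concentrations an event
just changed.

The deterministic mode integrates each triangle's master equation
`dp/dt = Q(V)^T p` inside every window with an embedded Bogacki-Shampine
2(3) pair (defaults rtol 1e-5, atol 1e-8 on state fractions — far below
the O(dt) coupling error; both adjustable). Rates and explicit currents
are evaluated at the predicted mid-window potential `1.5 V_t - 0.5
V_(t-dt)` (a linear trend extrapolation) and Ohmic currents use the
window-mean open fraction; together these centre the explicit coupling
on the backward-Euler interval and cut its error several-fold (a squid
Hodgkin-Huxley patch at a 5 us step tracks a tight reference ODE
integration to ~0.24 mV through a full spike, and the Rallpack 3 cable at
5 us vs 1 us field steps self-converges to ~0.16 mV RMS at both ends).

## Fixture meshes

No external mesher is required; both validation geometries are generated
natively, as text-free procedural code.

Cylinder: a stack of prisms over a regular polygon cross-section
(fan-triangulated around a centre vertex). The polygon order is chosen so
the rim edge length roughly matches the slice thickness, `k ~ sqrt(pi d
N / 3L)`; each prism is split into tetrahedra by choosing every quad
diagonal through the quad's globally smallest vertex (which makes the
split conforming across neighbouring prisms) and coning from the prism's
smallest vertex. The polygon is scaled so the cross-section area — hence
the mesh volume — matches the ideal cylinder exactly; the residual
surface-area error is the polygon-vs-circle perimeter deficit (0.9% at
200k tets down the ladder to ~5% at 40k, the same 1-4% range unavoidable
in practice) and is reported by the generator.

Branched tree: a symmetric binary tree obeying the 3/2 power law —
daughter diameter `d * 2^(-2/3)` (so `sum d^(3/2)` is conserved to
machine precision) and daughter length `l * 2^(-1/3)`; from a 32 um x 16
um root, 8 levels span 130.7 um of cable. Each branch is a prism-stack
tube; at a junction each daughter attaches to half of the parent's
end-cap fan through a star-shaped plug: an apex vertex coned over the
half-cap triangles, the daughter's starting disc, and a lateral band
stitched between the two boundary loops by azimuth merging. The plug is
conforming by construction; mesh validity (positive volumes, two-tet face
sharing, divergence-theorem volume identity at 1e-10) is asserted after
every build. The split line of the cap rotates from junction to junction
by an irrational multiple of the polygon order so branch planes spread in
3-D; the builder tries a short fixed list of multipliers and branch-angle
scalings and keeps the first layout that passes a capsule-distance
self-intersection check (failing all raises an error naming the level).
A single global radial scale, solved by bisection, matches the total mesh
volume to the ideal union of cylinders to 1e-9 relative.

Both generators return the closed boundary membrane plus the
classification into lateral surface and end caps. The Rallpack runners
place capacitance and leak on the lateral surface only, because the 1-D
cable they are compared against has sealed, membrane-free ends; the
surface-correction factor `f = ideal_area / mesh_area` is applied to
`C_spec` and to the leak conductance per area so total membrane
capacitance and conductance match the smooth geometry exactly. The test
suite checks the contrast that motivates this: an uncompensated 1%
surface-area error costs far more accuracy than halving the mesh
resolution.

## Validation references

Rallpack parameters follow the published suite: axial resistivity 1.0
Ohm m, membrane resistance 4.0 Ohm m^2, C_spec 0.01 F/m^2, rest -65 mV,
0.1 nA step injection, field step 0.01 ms, 250 ms simulated; Rallpack 3
adds squid Hodgkin-Huxley kinetics (gNa 120, gK 36, gLeak 0.025
mS/cm^2; ENa +50 mV, EK -77 mV; 20 pS single channels).

* Rallpack 1: the separation-of-variables series for a sealed-end finite
  cable under a step current, truncated when the smallest-positive-time
  tail is below 1e-9 V. Verified against a Crank-Nicolson 1-D oracle on a
  fine grid (<1e-5 V away from the t -> 0 onset singularity at the
  injection point, where the finite-difference oracle itself is limited).
* Rallpack 2: the symmetric 3/2-law tree satisfies Rall's equivalent-
  cylinder conditions exactly (each level contributes the same
  electrotonic length), so the transient reference is the finite-cable
  series on the equivalent cylinder (root diameter, length = levels x
  root length; membrane area is conserved by the reduction). The steady
  state is independently cross-checked by recursive impedance composition
  of the tree and by a brute-force branched finite-difference oracle
  (agreement <1e-5 V; the DC recursion matches the equivalent cylinder to
  1e-12 relative).
* Rallpack 3 has no analytic solution; the runner accepts an external
  reference trace (2-column CSV) and reports RMS voltage difference and
  mean spike-peak timing offset (peaks above 0 mV, parabolic sub-sample
  refinement). Without such a file the suite uses internal checks: field
  steps of 5 us vs 1 us agree to well under 1 mV RMS, and at high channel
  counts (5000 per triangle) the mean stochastic trace stays within three
  standard errors of the deterministic mode.

Probes report the capacitance-weighted mean potential over an end's
membrane vertices — the lumped quantity a 1-D cable predicts; injection is
area-weighted over the end cap.

## Problem sizes and observed accuracy

The shipped benchmark protocol uses a ~200,000-tet cylinder (71k
vertices; half-bandwidth 25 after principal-axis ordering) and a
~60,000-tet 8-level tree (22k vertices; BFS/Cuthill-McKee ordering). At
these sizes the measured RMS against the analytic references is ~0.006
mV / ~0.003 mV for Rallpack 1 (0 and 1000 um) and ~0.003 mV at the
Rallpack 2 root. Because the generated meshes match volume exactly and
the membrane is surface-corrected, the remaining error is dominated by
the O(dt) backward-Euler term — halving the field step roughly halves the
RMS, and refining the mesh improves it only mildly (the refinement ladder
is non-increasing). Real image-derived meshes will sit closer to the
spatial-error regime; the surface-correction contrast test quantifies how
quickly uncompensated area errors dominate.

## What the generators do and do not emulate

The fixtures reproduce the geometry, surface-error magnitudes and
parameter regimes of the published benchmarks, with uniform axial slicing
(the distribution of tetrahedron sizes in externally generated meshes is
not modelled) and structured connectivity. Passing tests therefore
demonstrate the correctness of the discretisation, kinetics and coupling
— not robustness to poor-quality elements, which only appears here as the
reported negative couplings on obtuse tets. Extracellular fields, multiple
or internal membranes, volumetric reaction-diffusion between tetrahedra,
and surface diffusion of channel states are out of scope.

## Known limitations

* One membrane per simulation; the outer potential is fixed (earthed).
* The stochastic engine's event loop is pure Python/numpy; it is exact
  but suited to desk-scale channel counts (~1e5 events/s), not to
  whole-cell channel populations at physiological density.
* The 10-level Rallpack 2 geometry is not attempted (the level-10
  diameter/length contrast does not admit a usable tetrahedralisation;
  the 8-level tree is built instead).
* Deterministic-mode rates are frozen per communication window, so its
  accuracy is bounded by the field step as O(dt) even though the gating
  integrator is adaptive.
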