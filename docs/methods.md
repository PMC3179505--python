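# Methods

This note records the models, numerical choices and validation design
behind `pathmeta`, at the level of detail a user needs to judge what the
package's passing tests do and do not demonstrate.

## Units and dynamics

All public APIs use kcal mol⁻¹, Å, ps, K and amu (k_B =
1.9872041×10⁻³ kcal mol⁻¹ K⁻¹, so k_B·300 K ≈ 0.5962 kcal mol⁻¹).
Masses entering the equations of motion are pre-multiplied by
10/4184 ≈ 2.390×10⁻³ so that ½·m_eff·v² is a kcal mol⁻¹ energy for v in
Å ps⁻¹.

Dynamics are Langevin, discretised with the BAOAB splitting (kick /
drift / Ornstein–Uhlenbeck / drift / kick).  BAOAB was chosen for its
small configurational sampling bias at practical step sizes; at zero
friction it reduces to velocity Verlet, which the energy-conservation
test exercises.  Defaults follow common practice for solvated
biomolecular systems: 300 K, damping 5 ps⁻¹.  The default step is 2 fs;
the toy systems in the validation studies use 4 fs, comfortable for
their softest-to-stiffest mode range (stiffest: the 200 kcal mol⁻¹ Å⁻²
ligand bonds, ω·Δt ≈ 0.7).  All noise is drawn from one seeded stream in
a fixed per-step order, so every run — including chunked metadynamics —
is bit-reproducible from its seed.

## Steered expulsion and work

The steering module drags a harmonic guide U = ½k(ξ − ξ₀ − vt)² along
ξ = |COM(pulled) − COM(anchor)| (mass-weighted centres; a fixed anchor
point may replace the anchor group on single-particle systems).
Defaults are the slow-growth regime for ligand expulsion: k =
20 kcal mol⁻¹ Å⁻², v = 0.005 Å ps⁻¹, so a 7.5 Å extension is a 1.5 ns
pull.  Before the centre moves, the system relaxes for 5 ps under the
static restraint so the work is measured from the equilibrated guided
ensemble.  The applied force F = k(ξ₀ + vt − ξ) and the work
W = ∫F·v dt are accumulated by the trapezoid rule at every integration
step — the record stride only thins what is *stored*, never what is
integrated.  Five realisations differing only in their initial
Maxwell–Boltzmann velocities are run by default, and the lowest-work one
(ties broken by the smoother force profile, then run id) seeds the path.
No free-energy estimator is built on the work values; they serve to rank
realisations and to check the second-law bound ⟨W⟩ ≥ ΔF against
independent estimates.

## Path collective variables

The MSD metric superposes two configurations by the Kearsley quaternion
method (4×4 symmetric eigenproblem; a fixed-size Jacobi solver inside
the compiled kernels, `numpy.linalg.eigh` in the batched NumPy path —
the two routes agree to 10⁻¹⁵ and are cross-checked in the tests against
an exhaustive rotation-grid search).  Alignment uses a stable reference
cage; the distance is measured over the ligand heavy atoms only.

S is 1-indexed (a converged run spans [1, P]); Z is in Å².  Both are
evaluated in log-sum-exp form, so arbitrarily large λ·D never
underflows.  Gradients are analytic with the optimal rotation treated as
constant per evaluation; this is exact when the alignment and
displacement selections are disjoint (the default — the cage is not
displaced) and a standard small-variation approximation otherwise,
guarded by a finite-difference test.

Frameset extraction picks P frames (endpoints always kept) by dynamic
programming over a candidate grid (≤400 frames, evenly subsampled),
minimising the squared deviation of adjacent MSDs from a target spacing
that is itself iterated three times from the current selection.  On a
uniform drift this recovers exactly even spacing; on a real pull the
spacing variance is limited by the trajectory's thermal noise floor
(see "what the toys do not show" below).

λ is calibrated as λ = ln 10 / ⟨D_adjacent⟩: a configuration one
inter-frame spacing from a frame enters the sums with weight 0.1, which
keeps S smooth but localised.  No universal rule exists for λ; this one
reproduces the classic pairing of a 1.1 Å frame spacing with λ ≈ 1.9
within 2%.

## Metadynamics

Standard (non-well-tempered) metadynamics: hills of constant height
(deposition rate × stride, default 0.1 kcal mol⁻¹ ps⁻¹ × 1 ps) and
constant widths (defaults σ_S = 0.15, σ_Z = 0.20 Å²) are deposited at
the visited (S, Z) every stride.  The continuous-deposition limit is
approximated by the 1 ps stride; the engine is tested for convergence at
two strides.  Inside the integrator the bias *force* is looked up on a
grid with spacing σ/5 (bilinear interpolation) that is updated
analytically at each deposition — an O(1) cost per step independent of
the hill count.  A hill becomes active at the step it is deposited,
which makes the trajectory independent of how a long run is split into
chunks.  `bias_value`/`bias_gradient` evaluate the exact Gaussian sums
and are the reference the engine grids are tested against (the
interpolation error at σ/5 spacing is ~10⁻³ of the hill height).  The
grid must cover every (S, Z) the system can reach: hills recorded
outside it exert no force during the run, so an undersized grid lets the
walker linger in unbiased territory while the log keeps growing — a
distorted surface.  For path CVs the default grid spans S ∈ [0, P+1]
and Z from its analytic floor (−ln P/λ) upward.

The free-energy surface is F(S, Z) = −V(S, Z, t), shifted to min 0.
Because a single-time snapshot carries an O(hill height) ripple,
`reconstruct_fes` can average −V uniformly over deposition times in a
trailing window; the validation studies average over the last half of
each run.  The default stopping rule is the recrossing event (first
return to the reactant S-window after reaching the product window),
with a maximum-time cap.

## The toy systems and what they (do not) show

`double_well_1d(b, s)` confines y and z harmonically, so F(x) equals the
potential itself; it is the oracle for FES reconstruction (tolerances
0.3 kcal mol⁻¹ on ΔF, 0.75 on the 6 kcal mol⁻¹ barrier, mean over three
seeds of 8 ns each).

`build_toy_pocket` emulates — at the level of occupancy and geometry,
not chemistry — a buried binding site: a Gaussian well of depth
`pocket_depth` (default 6 kcal mol⁻¹, σ = 2 Å) acting on the centroid
of a small stiff-bonded bead "ligand", inside a spherical shell cavity
(radius = `channel_length`, default 8 Å) whose wall opens at the mouth.
The ligand's accessible region is cleft-shaped: lateral radius 3.5 Å in
the pocket, narrowing to a 2 Å neck at the mouth, then a narrow solvent
vestibule (2.2 Å radius, 9 Å long) to the cap — chosen deliberately so
the unbound state sits *on* the path (small Z) and the unbound volume
gives a binding ΔG of ~5 kcal mol⁻¹, within reach of an unbiased
oracle.  Purely repulsive WCA beads (σ = 2.8 Å, ε = 0.2 kcal mol⁻¹)
model solvent occupancy; a 4-bead tethered cage near the pocket bottom
provides the superposition reference and the pulling anchor.  The wall's
mouth aperture is wider for the ligand (0.6 rad) than for solvent
(0.38 rad): the ligand stands in for a molecule that displaces the
flexible entrance region, while water must squeeze past it — which is
what makes the optional solvent-only back-door channel at the pocket
bottom (0.35 rad) measurable in the flux tests.

Deliberate simplifications, and hence limits of what passing tests
show about real systems: no electrostatics or attractive dispersion, a
rigid rotationally-free ligand (orientation noise puts a floor of a few
Å² under the MSD between any two pull frames, so toy framesets are
spaced ~7 Å² rather than the ~1 Å² of an all-atom study), no protein
flexibility, and solvent that only pushes.  The validation demonstrates
the *estimators* (work accounting, CV evaluation, bias bookkeeping, FES
analysis) are correct, not that the physics of any real complex is
reproduced.

## The pocket validation study

`pathmeta.validation` runs the full protocol against an independent
estimate:

* **Oracle leg** — one 600 ns unbiased run at 300 K with 1 ps⁻¹
  friction.  Friction is a thermostat parameter that leaves equilibrium
  populations untouched; the light damping speeds barrier crossing ~5×,
  yielding tens of bound⇄unbound round trips, so −kT·ln p(S) is a
  converged profile.  (At the default 5 ps⁻¹ the same run shows no
  escape at all — the honest oracle would simply be unaffordable.)
* **Metadynamics leg** — three independent 20 ns depositions
  (σ_S = 0.3, σ_Z = 0.8 Å², matched to the toy's basin sizes), bias
  averaged over the last half.  The toy's re-entry barrier is only
  ~1 kcal mol⁻¹, so the recrossing event fires within 1–2 ns, long
  before the surface is filled; the study therefore uses a fixed
  deposition time instead of the recrossing stop (which remains the
  default for systems with a substantial re-entry barrier).
* Both legs reduce to the same observable: the Boltzmann marginal over
  Z of F(S, Z), minimum-to-minimum between the bound window S ∈ [1, 5]
  and the unbound window S ∈ [8, 11.8] (stopping short of S = P, where
  the progression variable saturates).

Agreement is required to 0.5 kcal mol⁻¹; the residual budget is the
oracle's counting noise (~0.2 at ~40 round trips) plus the metadynamics
seed spread (~0.2 s.e.m. over three seeds).

## Analysis layer

Basins: steepest-descent watershed on the grid (8-neighbour), then
iterative merging of basins whose prominence (lowest connecting saddle
minus basin minimum) is below `min_depth` (default 1 kcal mol⁻¹ — the
isoline spacing used for rendering, so surviving basins are the visible
ones).  ΔG between basins is minimum-to-minimum.  Barriers are minimax
path values found by a Dijkstra-style search with max-cost composition
(4-connectivity), checked exactly against threshold percolation.

Coordination numbers use the rational switching function
(1−(r/r₀)ⁿ)/(1−(r/r₀)ᵐ) with r₀ = 3.5 Å, n = 6, m = 16, evaluated in
the equivalent polynomial-ratio form Σ_{k<n}xᵏ/Σ_{k<m}xᵏ which removes
the r = r₀ singularity exactly (value n/m).  The hydration map averages
the count at 11 evenly spaced points of a pocket-axis segment over
S-bins of width 0.5, marginalising Z.  Distance/dihedral/RMSD/RMSF
monitors and single-linkage RMSD clustering (cutoff 0.7 Å, connected
components via scipy's sparse graph routines) follow their standard
constructions.  The catalytic-competence predicate requires the hydride
pair within 4.5 Å and both stabilising hydrogen bonds within 3.5 Å;
these cutoffs are conventional structural practice and are configurable.

## Degenerate inputs and tie-breaks

Superposition refuses fewer than three or collinear alignment atoms.
Frameset extraction refuses trajectories with no net displacement.
An empty hill log reconstructs to a flat zero surface.  Equal-work pull
records are ranked by force-profile total variation, then run id.
Watershed plateaus of exactly equal values each become their own
minimum (analytic surfaces make ties measure-zero).  The S = P edge
(where S saturates) is excluded from the unbound analysis window.

## Problem sizes

The shipped studies are sized for a single CPU: double well 3 × 8 ns;
pocket protocol 5 × 400 ps pulls, 3 × 20 ns metadynamics, 600 ns
oracle; the whole validation runs in roughly ten minutes.  All sizes
are parameters of the `validation` functions and scale up trivially.
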