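# Methods

## Model overview

`ossiforge` simulates endochondral ossification of a developing long bone at
single-cell resolution. Each Lagrangian material point represents one
chondrocyte plus its share of extracellular matrix; an Eulerian background
grid carries the mechanical solve and the morphogen fields. Three coupled
subsystems advance per Δt = 0.02-day increment, in a fixed order: growth
commit → mechanics → chemistry → fate → cycle/division.

### Mechanics

Finite growth uses the multiplicative split F = Fᵉ Fᵍ. The tissue is
compressible neo-Hookean,

    ψ = Jᵍ ( λ/8 ln²I₃ + μ/2 (I₁ − 3 − ln I₃) ),   Jᵍ = det Fᵍ,

with I₁ = tr Cᵉ, I₃ = det Cᵉ, Cᵉ = FᵉᵀFᵉ, and Lamé parameters from each
point's current (E, ν). ψ and its stress vanish exactly at Cᵉ = I, so
spatially uniform growth relaxes stress-free (verified by test).

Equilibrium per increment is a damped quasi-static energy minimization over
grid node displacements (L-BFGS with analytic gradient
∂E/∂u_g = Σ_p V_ref (P Fᵀ) ∇N_g), subject to zero normal displacement on the
symmetry planes x = 0, y = 0, z = 0. Developmental growth operates far below
inertial time scales, so no dynamic update is attempted. Tolerances: relative
energy change 1e-8, force residual 1e-6 × E_cell·h² (config keys
`solver.tol_energy_rel`, `solver.tol_force`).

Interpolation uses quadratic B-splines (C¹, 3-node support per axis,
partition of unity, exact linear reproduction). Instead of edge-modified
"extended" basis functions, the grid is rebuilt every increment with enough
padding (`grid.padding_cells`, default 3) that every particle sees a complete
interior stencil — same stabilizing intent, simpler bookkeeping.

Point update: x ← x + u(x), F ← (I + ∇u)F, V ← det(I + ∇u)·V. V therefore
tracks the total (elastic × growth) volume; the reference volume is recovered
as V/det F where needed.

Boundary points are massless surface markers advected with the displacement
field, for visualization and surface metrics only; their mechanical role in
ancestral versions of this model class is not reproduced here.

### Cell cycle and growth schedules

Proliferative cells cycle continuously: S/G2/M/G1 are tracked as one
continuous clock t_cycle ∈ [0, T_cycle] with division exactly at
0.5·T_cycle (sub-phase durations are not independently meaningful in this
model and are not invented). At cycle end the cell samples a G0 duration
T_G0 = −ln(1−r)/R_prolif and re-enters S afterward. A cell that
differentiates to prehypertrophic while mid-cycle finishes that cycle
(dividing once); one that differentiates in G0 never cycles again.

The growth-stretch magnitudes are not dictated by the cell-level rules, so
they are model parameters:

- proliferative, unidirectional along the division axis: θ ramps linearly
  1 → 2 over the cycle (`cycle.prolif_volume_multiple = 2`), making division
  volume-neutral per generation;
- hypertrophic, isotropic: θ ramps 1 → 2 across T_hyp
  (`cycle.hyp_volume_multiple = 8`, i.e. ×8 volume), the order of magnitude
  of hypertrophic chondrocyte enlargement seen histologically.

Division axis = normalized local ∇C_Ihh, re-sampled from the current field
at each division; children are placed at ±(V_parent/2)^{1/3}/2 along it. A
vanishing gradient (< 1e-12) falls back to the cell's previous axis, then to
a seeded random unit vector, keeping replays deterministic.

### Signaling

Ihh production follows a hat schedule over the maturation clock t_H: up to
P_max during prehypertrophy (T_prehyp = 0.5 d), back to zero by
mid-hypertrophy. Periarticular PTHrP production is
P_max·Ihh_total/Ihh_max; resting-zone production multiplies this by the SOC
maturation ramp min(t_SOC/T_mat, 1), continuous at t_SOC = T_mat.

Both species diffuse and degrade (D = 1 μm²/s, k = 0.005/s, converted to
per-day internally; 86,400 s/day) on the mechanics grid (h = 50 μm), with
zero-flux mirror conditions on the symmetry planes and C = 0 held beyond a
padding margin (≥ 2–3 cells ≫ the screening length √(D/k) ≈ 14.1 μm).
Integration is backward Euler (unconditionally stable, positivity
preserving, exact at the steady state C* = P/k), sub-stepped 4× per
mechanics increment; since 1/k ≈ 200 s ≪ 1,728 s per increment, fields are
quasi-steady and the transient path is immaterial. An explicit FTCS scheme
(`chem.scheme = "explicit"`) is kept for cross-checks and enforces its
Δt ≤ h²/(2dD) bound.

Point/grid exchange: a cell's volumetric production rate deposits
production × V_p through the B-spline weights, normalized by node volume —
i.e. the discrete source equals the tissue-volume-weighted mean production,
P where producing tissue fills a node. Ihh_total sums C over
tissue-occupied nodes × symmetry multiplicity (8 for the octant capsule, 2
for the mirrored column; `signaling.ihh_total_scope` switches to raw octant
totals).

### Differentiation

Strict thresholds exactly as configured (defaults: 1.0, 30.0, 0.5, 10.0
pM/μm³): quiescent/resting → proliferative on Ihh; proliferative →
prehypertrophic on Ihh **and** sub-threshold PTHrP; timed prehypertrophy
(0.5 d) and hypertrophy (1.0 d); then apoptosis or calcified matrix with
probability ½ each — both absorbing (no remodeling). Young's modulus ramps
log-linearly (1 → 10³ kPa spans three decades; a linear ramp would
concentrate nearly all stiffening in the final instants) and ν linearly
(0.4 → 0.3) over T_apop/T_calcif = 1 day; apoptotic points take the
calcified-matrix target because they are part of the primary spongiosa
(`properties.E_apoptotic_target_kPa` overrides). Resting-zone cells may
re-enter proliferation (they are otherwise quiescent cells); a flag on
`update_fate` disables this.

## Geometry

One-eighth of a distal metatarsal: cylinder (R = 300 μm, H = 300 μm) plus an
ellipsoidal dome (semi-axes 330, 330, 250 μm) whose apex rises 340 μm above
the cylinder top — the ellipsoid center therefore sits 90 μm above the top
plane and its equator slightly overhangs the wall (r ≈ 307.9 μm). The stated
dome height and z-semi-axis are inconsistent for a plain half-ellipsoid;
this offset-center reading is the documented interpretation, selected
because it reproduces the published discretization counts exactly.

Membership convention (frozen): cell-centered 10 μm lattice (offsets 5, 15,
25, …), closed cylinder for z ≤ H, closed unclamped ellipsoid for z > H →
42,861 material points. Boundary points: latitude rings on the analytic
outer surface (wall, dome, overhang annulus) with per-ring counts
apportioned from a frozen surface density (0.016307 points/μm²) by
largest-remainder rounding → 5,491 points. Spacing-doubling and
analytic-volume oracles confirm both scale correctly.

Initial types: lateral-wall shell (one spacing) = perichondrium; dome-cap
shell = periarticular PTHrP producers (precedence over perichondrium);
interior quiescent. POC at Day 0: a 60 μm diaphyseal slab (3 point layers in
the mirrored half) set prehypertrophic — a single 10 μm layer cannot push
grid-resolved Ihh past the 30 pM/μm³ threshold at h = 50 μm and the model
then never ignites, so the thicker default is a deliberate, configurable
choice (`events.poc_slab_thickness_um`). SOC at Day 2: the future-SOC
cluster (40 μm sphere at the epiphysis volume centroid, flagged at Day 0 and
tracked materially) set prehypertrophic; the quiescent band between the
proliferative-zone top and the seed becomes the PTHrP-producing resting
zone, limited to the plate's radial footprint.

## The 1-D column world

`run_1d_growth_plate` and the column secondary-ossification driver evolve a
single-point-wide column along z with mirror symmetry at z = 0. Mechanics is
exact there (any axial growth field is compatible, so the energy minimum is
the stress-free stack of per-point heights V/A, A = spacing²); the generic
grid solver reproduces this on fixtures. Dimension reduction of growth: only
the axial factor of each stretch acts on the column — hypertrophic cells
contribute θ = 8^{1/3} = 2 axially, exactly their axial effect in 3-D;
mapping the full ×8 onto one axis would inflate the hypertrophic zone by the
suppressed lateral expansion.

The PTHrP normalizer Ihh_max is defined as the Ihh_total peak of a sample
simulation of the same world; the published 1.5×10⁶ pM is the 3-D capsule's
calibration. `secondary_column_config` re-runs that recipe in the column
world (primary-ossification sample run; ≈ 3.8×10⁶ pM at defaults). Without
this re-calibration the column's Ihh_total/Ihh_max ≈ 10–20 overdrives
resting-zone PTHrP and suffocates the growth-plate conveyor.

The column's SOC seed sits at the material fraction of the capsule's
epiphysis centroid (≈ 0.68 of the initial 640 μm build), which places the
Day-2 plate-to-seed gap near 150 μm, comparable to the capsule geometry.

## What the reduced worlds do and do not establish

Green desk-scale tests establish: the exact geometry convention; all
closed-form signaling laws and transport analytics; the mechanics
invariants (partition of unity, linear reproduction, stress-free growth,
volume bookkeeping); cycle/division statistics; the steady 200–400 μm
combined proliferative+hypertrophic zone; and the maintenance-vs-fusion
dichotomy with its outcome ordering across T_mat. They do **not** establish
the 3-D critical maturation slope (≈ 1/6 per day at full resolution), the
~30 μm subarticular cartilage thickness, or the Day-5.8 counterfactual
fusion time — those depend on 3-D screening geometry and full resolution and
require hours-long capsule runs (`ossiforge run --preset full`). In the
column world the critical T_mat falls between 0.5 and 2 days and the
counterfactual fuses at Day ≈ 4.3–5.7 depending on column geometry.

The synthetic worlds also idealize: no external loading or contact, no
remodeling, no vascularity, isotropic linear-in-ratio PTHrP response, shared
D and k for both morphogens, and deterministic threshold switching.

## Numerical notes

- Penetration of the resting zone is evaluated against the axial interval of
  the *surviving* resting cells; a fully consumed band counts as penetrated,
  and in-place proliferation of resting-tagged cells (stem-pool turnover)
  does not. First-crossing day is logged separately from the end-state flag
  because the freshly activated SOC transiently erodes adjacent band cells
  before its PTHrP shield builds (the radial-expansion phase).
- Fusion = grid connectivity (flood fill at h = 50 μm) between calcified
  material descended from the POC slab and from the SOC seed.
- Zone extents are max−min of point z per type; the combined length is the
  sum of the proliferative and hypertrophic spans.
- Determinism: a single `numpy` Generator seeded from `config.seed` drives
  G0 sampling, the 50/50 terminal split and gradient tie-breaks; replays are
  bit-identical (tested). Sweep runs use seed + index.
- Degenerate inputs: inverted trial states during the line search are
  rejected by an energy penalty; point inversion on update raises; empty POC
  slab/SOC seed raise; an empty resting zone warns and degrades to the
  no-resting-PTHrP case.
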