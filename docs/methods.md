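# Methods

`spheroidsim` simulates the growth of an avascular tumour spheroid as a
stochastic individual-based model (IBM) in which every cell is a point
agent carrying a FUCCI cell-cycle label, coupled to a quasi-steady
diffusible-nutrient field, and quantifies the simulated spheroids with the
same kind of image pipeline used on confocal slices of real spheroids.
This note records the model, the numerical choices, and the limits of what
the synthetic experiments demonstrate.

## The model

**Agents.** Each cell is a point at position **x**ₙ(t) in a cubic domain
[−L/2, L/2]³ with one of three FUCCI phases: red (G1), yellow (early S),
green (S/G2/M). There is no cell volume, adhesion, repulsion or exclusion:
crowding acts only indirectly, through nutrient consumption. Five
per-capita rates drive the dynamics, all functions of the non-dimensional
local nutrient concentration c ∈ [0, 1]:

| rate | law | interpretation |
|---|---|---|
| red→yellow | Rr(c) = Rr_max c^η₁/(c_a^η₁ + c^η₁) | cycle entry requires nutrient; half-max at the arrest concentration c_a |
| yellow→green | Ry (constant) | committed cells progress freely |
| green→red | Rg (constant) | mitosis: parent replaced by two red daughters placed ±σ/2 along a random direction |
| migration | m(c) = (m_max−m_min) c^η₂/(c_m^η₂ + c^η₂) + m_min | step of length μ in a random direction |
| death | d(c) = (d_max−d_min)(1 − c^η₃/(c_d^η₃ + c^η₃)) + d_min | sharp rise below c_d (η₃ = 15); dead cells are removed and their location recorded |

Random directions are uniform on the sphere (φ uniform on [0, 2π),
cos θ uniform on [−1, 1]); a uniform polar angle would bias motion toward
the poles and break the spherical symmetry the model is meant to preserve.

**Nutrient.** A single diffusible nutrient (think oxygen) with
concentration C is consumed by cells at rate κ per cell and diffuses with
diffusivity D. Because diffusion is much faster than population change,
the transient equation is replaced by its quasi-steady limit for the
scaled c = C/C_b:

    0 = ∇²c − α v c   in Ω,   c = 1 on ∂Ω,

with α = κ/D (the only combination that matters, stored as one parameter)
and v the local agent density [cells/μm³]. v is estimated by counting
agents in the h-cube control volume around each node of a uniform I³ mesh
(h = L/(I−1)).

**Hybrid loop.** Time [0, T] is split into M = T/t* windows. Within a
window, all agent events are resolved with an exact Gillespie algorithm
using per-agent propensities frozen at the nutrient value each agent
cached at the last field update; migrating agents keep their cached value,
daughters born mid-window sample the frozen field at their own birth
position. At each window edge the density is re-binned, the field
re-solved, and every living agent re-samples c by trilinear
interpolation. The clock draw that overshoots the window edge is
discarded, which is exact for the frozen-rate (time-homogeneous) process.

**Initial condition.** N(0) agents volume-uniform in a ball of radius
ro(0); exactly Nr(0)/Ny(0)/Ng(0) agents get the red/yellow/green label via
a uniformly random permutation (the published counts are taken as given).

## Parameters

Defaults are the published WM793B melanoma calibration: N(0) = 30 000
(20 911 red, 995 yellow, 8 094 green), ro(0) = 245 μm, σ = μ = 12 μm (a
cell diameter), T = 240 h, t* = 1 h, Rr_max = 0.047 h⁻¹, Ry = 0.50 h⁻¹,
Rg = 0.062 h⁻¹, d ∈ [0.0005, 2] h⁻¹, m ∈ [0.06, 0.12] h⁻¹,
η = (5, 5, 15), (c_a, c_m, c_d) = (0.4, 0.5, 0.1), α = 0.15 μm/cell,
L = 4000 μm, I = 201 (h = 20 μm). All lengths are μm, times hours; c is
dimensionless. `M` is always derived as T/t* and never stored, so the two
cannot disagree.

**Reduced-domain preset.** `desk_preset()` keeps every biological
parameter but shrinks the domain to L = 1500 μm with I = 76, preserving
h = 20 μm. This is the problem size used by the long-horizon tests and by
`scripts/acceptance.py` (three 240 h realizations). The cost is a Dirichlet
boundary closer to the spheroid: matching the interior and exterior
solutions of the uniform-ball problem analytically shows the initial
central concentration rises from about 0.26 (L = 4000) to about 0.28
(L = 1500) — a small, systematic nutrient surplus that slightly delays
arrest and necrosis and slightly accelerates growth. The headline outputs
(necrotic onset near day 4, final diameter ~600 μm) are robust to it.

## Numerics

- **Event selection.** Per-agent total propensities live in a Fenwick
  (binary indexed) tree, giving O(log N) selection and update; the tree is
  rebuilt from scratch at every window start so floating-point drift
  cannot accumulate across windows. The event kernel is compiled with
  numba; a seeded global RNG makes a run bit-reproducible given
  (parameters, seed). Ensemble member k derives its seed as master + k.
- **Slot arrays.** Dead agents keep their array slot with zero propensity;
  arrays grow geometrically when mitoses exhaust the headroom, and the
  kernel pauses *before* consuming any random draw for the pending event,
  so growth is invisible to the event sequence.
- **Field solve.** Standard 7-point second-order finite-volume stencil;
  boundary nodes (c = 1) are eliminated, leaving a symmetric
  positive-definite M-matrix system solved with Jacobi-preconditioned
  conjugate gradients to a relative residual of 1e-8, warm-started from
  the previous window (typically a handful of iterations once the field
  is established). The discrete maximum principle guarantees 0 < c ≤ 1;
  excursions beyond round-off (1e-6) abort the run, smaller ones are
  clipped.
- **Boundary breaches.** L is chosen so agents never reach ∂Ω; if one
  does, the run aborts with a diagnostic rather than clamping or
  reflecting, since the premise of the far-field boundary is violated.
- **α = 0 shortcut.** With consumption off the solution is identically 1
  and the solve is skipped; this is also the well-mixed limit used to
  check the engine against the linear compartment ODE.

## Image-based quantification

Cross-sections mimic confocal slices: agents within ±6 μm (half a cell
diameter) of the cutting plane are drawn as 12-px-diameter discs on a
(L+1)×(L+1) image at 1 μm/px, one channel per FUCCI colour plus a dead
channel. The equator is z = 0; upper/lower planes default to ±ro/2.

Radii are extracted per image:

- the living-channel union is morphologically closed with a 6-μm-radius
  disc (implemented with two Euclidean distance transforms). The point
  agents cover only ~half the tissue area at physiological density, and
  the closing bridges sub-cell-scale gaps;
- 360 rays are cast from the living centroid; **ro** is the median
  outermost foreground crossing and **rn** the median innermost crossing
  (set to 0 below one cell diameter — no genuine void);
- **ra** comes from yellow+green coverage in 12-μm-wide rings (2 μm
  sliding step): scanning inward from the rim, the first ring whose
  coverage drops below 10% of the rim value marks the arrested boundary.
  If no ring qualifies — as at early times, when all colours are mixed
  everywhere — ra is reported as NaN rather than pinned to ro, so
  early-time radii plots show only what is actually detectable.
  The ordering ro > ra ≥ rn is enforced on the returned estimate.

**Noise floor and onset definition.** Because coverage is partial,
single-frame rn estimates carry a sampling noise floor: on fully mixed
balls at physiological density, ~5% of frames show a spurious central
void of up to ~20 μm, which is the same order as the true core in the
first day of its existence. The necrotic *onset* reported by the
experiment layer is therefore the first daily estimate with rn > 0 that
is confirmed by the following observation; a genuine core persists and
grows, while sampling voids are independent across days. Fixture
benchmarks show the estimator recovers known radii (50, 100, 200 μm)
within ±8 μm.

Radial profiles report relative densities against depth from the
periphery p = ro − r in 10-μm shells (the reference works with the same
periphery-referenced coordinate; the bin width is this package's choice).
All agent subpopulation profiles (cycling red, arrested red — red with
local c < c_a — yellow, green) share a single normalization, the maximum
mean density over every subpopulation, bin and requested time point; the
nutrient profile is the shell-averaged c, reported unscaled.

## Synthetic-data generators

`fixtures` builds populations with known ground truth: a three-region
annulus spheroid (mixed rim / red-only arrested shell / empty core) at
twice the physiological density by default, so the rasterized image is
dense enough for sharp edges, and radial nutrient fields from arbitrary
profiles. These emulate the *geometry* the estimators must recover; they
do not emulate microscope noise, point-spread functions, fluorescence
bleed-through, or the irregular boundaries of real spheroids, so passing
the recovery benchmarks demonstrates correctness of the estimators on
clean geometry, not performance on experimental images.

## Variability experiments

Two ensemble protocols: (A) n identically prepared realizations differing
only by seed, and (B) one realization per initial radius from the shipped
list of ten experimentally measured values (mean 245.28 μm), with initial
agent density held constant — N(0) scales with (ro(0)/245)³ and the phase
counts scale proportionally with largest-remainder rounding. Summary
tables report pointwise sample mean ± sample standard deviation (n−1).

## Problem sizes used by the test suite

The long-horizon checks run 3 realizations of the reduced-domain preset
(≈ 10⁷ events and 240 field solves each); the well-mixed ODE check uses
20 realizations at N(0) = 1000 over 48 h; waiting-time exactness uses
10⁴ independent agents per phase; radii recovery uses 20 fixture seeds.
These sizes were chosen so the whole suite completes on a single core in
well under half an hour while keeping the statistical checks sharp
(3-standard-error bands, KS level 0.01).

## Known limitations

- Point agents: no volume exclusion, so local densities can exceed
  close-packing; density feeds back only through nutrient consumption.
- One nutrient species, symmetric far-field supply; no vessels or
  asymmetric sources.
- The quasi-steady field update at t* = 1 h is a splitting approximation:
  events within a window see a field frozen at the window start.
- The arrest classification (red with c < c_a) is a threshold convention,
  not an explicit model state.
- ra is quantized by the 2-μm ring step and undefined before an arrested
  shell is detectable; rn has the single-frame noise floor described
  above.
- Parameters are taken as given; no estimation or sensitivity machinery
  is included.
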