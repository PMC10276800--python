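# Methods

## Model

The package studies a minimal activator–inhibitor description of actin
signalling on a 1-D slice of a cell membrane (a periodic domain).  An
activator `u` (Ras activity driving protrusion) and an inhibitor `v`
interact through six reaction channels with propensities

| # | reaction | propensity | Δu | Δv |
|---|----------|-----------|----|----|
| 1 | u → ∅ | a₁u | −1 | 0 |
| 2 | u → ∅ | a₂uv | −1 | 0 |
| 3 | ∅ → u | a₃u²/(a₄+u²) | +1 | 0 |
| 4 | ∅ → u | a₅ | +1 | 0 |
| 5 | v → ∅ | εc₁v | 0 | −1 |
| 6 | ∅ → v | εc₂u | 0 | +1 |

plus Fickian diffusion (Dᵤ < Dᵥ).  The reaction-rate limit is a
FitzHugh–Nagumo-type excitable reaction–diffusion system

    ∂ₜu = Dᵤ∂ₓₓu − a₁u − a₂uv + a₃u²/(a₄+u²) + a₅
    ∂ₜv = Dᵥ∂ₓₓv + ε(−c₁v + c₂u).

The same network is simulated at three levels:

1. **Macroscopic** — the deterministic equations above (`pde`).
2. **Mesoscopic** — the chemical Langevin SPDE (`cle`): the drift above
   plus reaction noise with per-species variance `diag(S diag(R) Sᵀ)`
   and a conservative diffusion-noise flux `∂ₓ(√(2DX) dW̃)`, both scaled
   by σ = 1/√Ω, Ω the number of molecules per unit concentration per
   unit length.
3. **Microscopic** — exact Gillespie simulation (`gillespie`): well-mixed
   SSA, and a spatial SSA (reaction–diffusion master equation) in which
   every molecule hops to a neighbouring cell at rate D/dx².

All quantities are nondimensional model units.  Named parameter presets
(`fig4_standing` c₁=0.1, `fig11_travelling` c₁=0.2, `fig14_oscillatory`
c₁=0.4, `fig17a` WT, `fig17b` PTEN-null) share a₁=0.167, a₂=16.67,
a₄=1.44, a₅=1.47, Dᵤ=0.1, Dᵥ=1.

## Background states and bifurcations (`equilibria`)

Eliminating v* = c₂u*/c₁ reduces the homogeneous equilibria to the
positive roots of a quartic, solved through the companion matrix; a root
counts as real when |Im| < 10⁻⁹·max(1,|Re|) and positive when
Re > 10⁻¹².  Descartes' sign rule guarantees a unique positive root when
c₁(a₃+a₅) < a₂a₄c₂ strictly; the boundary case is reported
conservatively as "one or three".

Stability comes from the 2×2 Jacobian of the kinetics.  Note the (1,1)
entry is −a₁ − a₂v* **+** 2a₃a₄u*/(a₄+(u*)²)²: the Hill term's
derivative is positive.  (The sign is occasionally misprinted in the
literature; only the positive sign reproduces the known transition
locations, real negative eigenvalues at c₁=0.18 with a complex onset
near 0.25 and a Hopf crossing near 0.29.)  `eigen_scan` locates both
transitions by a 200-point coarse scan with nearest-neighbour
continuation of u* followed by bisection to 10⁻⁶ in c₁.

## Space-time discretisation (`pde`, `cle`)

Finite volumes on a uniform periodic grid, default [−10, 10] with n=400
(dx=0.05); the 3-point Laplacian; explicit Euler with
dt = 0.2·dx²/max(Dᵤ,Dᵥ) (5·10⁻⁴ at the default grid) as the default
stepper.  An IMEX variant treats diffusion implicitly (FFT solve in the
numpy engine, cyclic Thomas/Sherman–Morrison factorisation in the
compiled engine) and is used with dt = 2·10⁻³ for ensemble work; on
smooth trajectories the two steppers agree to ~10⁻⁴ and the
diffusion-limited explicit step is only needed for fine-grid wave
validation.  Integration is first order in dt (verified by a
convergence-order test); a homogeneous run reproduces a stiff reference
integration of the kinetics to 10⁻⁶ at dt=10⁻⁵.

White noise is represented per cell and step as independent
N(0,1)/√(dx·dt) draws.  The diffusion-noise flux through interface
k+½ is √(2D·max(0,(X_k+X_{k+1})/2))·ξ_{k+½}/√(dx·dt) with one
independent normal per interface; cell increments are flux differences
times dt/dx, so the term conserves total mass on the circle exactly (to
floating-point accumulation, <10⁻¹² in tests).  The implied increment
variance at a constant state X̄ is 2·(2DX̄)·dt/dx³.

Two noise conventions exist for the inhibitor's reaction-noise variance:
the systematic construction gives ε(c₁v + c₂u) (**default**,
`sum_of_propensities`), while a commonly printed form of this
Langevin equation carries ε(−c₁v + c₂u) (`as_printed`, clamped at zero before the square
root).  The default is used everywhere because it follows from
S diag(R) Sᵀ; the printed variant is retained for fidelity experiments.

The Langevin equation does not preserve positivity; states are clamped
to zero after every step and the clamped fraction is reported in the
field metadata (≈5–8 % of cell updates at σ≈0.03–0.06, concentrated in
the small-u background where the stationary fluctuation is comparable
to u* ≈ 0.05; a warning is logged above 5 %).

Ablation modes: `reaction_only` drops the diffusion-noise flux;
`additive_u` replaces all noise by additive white noise on u.  Additive
noise per cell scales as 1/√dx, so calibrations are tied to the grid: at
dx=0.05 the level matched to ≈50 detected patches per run is
σ ≈ 0.85, and those patches are an order of magnitude narrower and
shorter than full-mode activation events (median width 0.3 vs 2.5,
duration 0.4 vs 1.6) — spatially incoherent noise cannot feed the Hill
activation the way state-dependent reaction noise does.

A numba-compiled loop implements both steppers for the built-in network
(the generic vectorised numpy engine remains the reference; they agree
to ~10⁻¹⁴ deterministically).  Each engine's σ=0 trajectory is
bit-identical to its deterministic one, because both dispatch to the
same code path.  RNG: the compiled engine uses numpy's legacy global
generator (seeded per run), the numpy engine `default_rng`; streams
differ between engines but every run is reproducible from its seed.
Ensembles use seeds base_seed + run_index.

## Wave profiles (`waves`)

A localised wave (Φᵤ, Φᵥ) moving at speed c solves the co-moving system
0 = DΦ'' + cΦ' + kinetics with background tails.  It is discretised with
the same periodic stencils and solved by damped Newton with an analytic
sparse Jacobian.  For travelling waves c is an unknown and the system is
augmented with the integral phase condition ⟨Φᵤ,init′, Φᵤ − Φᵤ,init⟩ = 0
(translation-invariance removal); for standing waves (c ≡ 0) the phase
row is dropped — the lattice itself pins the translation mode — and the
plain square system converges.  Initial guesses are clipped from PDE
simulations: a centred bump `u₀ = u* + exp(−x²)`,
`v₀ = v* + 2/cosh²(5x)` splits into two pulses; one is clipped to the
background, briefly relaxed, recentred (and symmetrised for standing
pulses).

Domain sizes matter because the slow inhibitor leaves a long trail: on
[−20, 20] the periodic trail depresses the travelling-wave speed by ≈3 %,
so the default travelling solve uses [−40, 40] with dx = 0.0125
(c = −2.19 at dx→0 by Richardson extrapolation; −2.16 at the default
dx=0.025, −2.10 measured in a direct simulation at dx=0.025 before the
pair collides).  The front's interior layer has width
√(Dᵤ/|∂ᵤf|) ≈ 0.04, so speeds are resolution-sensitive below
dx ≈ 0.025.  The co-moving validation (profile advected by the PDE
retaining its shape, L₂ < 10⁻² over T=2) needs dx = 0.00625 with the
explicit stepper at dt = 3.9·10⁻⁶; at coarser resolution the O(dt) + O(dx²)
speed mismatch dominates the drift.

`measure_speed` fits the (periodic-unwrapped) location of the
u-maximum against time by least squares, optionally restricted to an
x-window to isolate one member of a counter-propagating pair.
`measure_width` is the widest contiguous super-threshold run of cells
times dx, wrap-aware.

## Event detection and statistics (`events`)

Activation events are 8-connected components of `u > threshold` on the
(t, x) lattice, periodic in x, with components under `min_cells = 8`
cells discarded.  Durations are row-count × sampling interval, widths
are wrap-aware column extents, each event carries its peak u.  The
default threshold adapts to the parameter set:
u* + 0.25·(u_pulse_max − u*), where u_pulse_max is the peak of the
deterministic pulse grown from the centred bump on [−30, 30] (wide
enough that the pulse pair does not annihilate through the boundary
within the reference run).  Detection equals a brute-force flood fill on
random masks (exact component counts and extents).

Ensemble statistics run many independent Langevin trajectories from the
homogeneous (u*, 4v*) state plus a uniform u-perturbation of amplitude
10⁻²·u* drawn from the run's seed; counts are per-run means, while
width/duration/maximum are averaged over all events pooled across runs.
Oscillation periods are the mean spacing of prominence-filtered maxima
(prominence 0.25 of the dynamic range) of the spatial mean ⟨u⟩(t) after
discarding t < 10.

With these defaults on the [−10, 10] domain: 0.10 events/run at σ=0.03,
3.3 at σ=0.04, 7.7 at σ=0.046 (30 runs, T=100) — a sharp activation
cutoff near σ≈0.035.  Event counts scale with domain length, so
absolute counts are only comparable at fixed domain.  At very large σ
(≈0.5) the patch detector saturates with noise-driven excursions rather
than reporting zero patches; the destruction of coherent patterns shows
up as a collapse of event durations (median 0.6 vs 1.65 at σ=0.046).

## Microscopic simulators (`gillespie`)

Count rates are size·R(counts/size) (size = Ω well-mixed, Ω·dx per
cell), which reproduces the standard conversions: linear a·n,
bimolecular a₂nᵤnᵥ/size, zeroth-order a₅·size, Hill evaluated on
concentration and scaled.  Both simulators use the direct method
(exponential waiting times, linear channel selection) and are exact:
counts never go negative.  The compiled spatial loop keeps per-cell
total rates and updates only touched cells.  First moments converge to
the kinetics ODE as Ω grows (error < 10⁻² at Ω=10⁴); a single diffusing
molecule reproduces MSD = 2Dt; diffusion-only runs conserve molecule
number exactly.

The RDME's large-Ω limit is the *spatially discrete* rate equation, so
front speeds are validated against the deterministic simulation on the
same lattice (15 % tolerance at an effective noise 1/√(Ωdx) ≈ 0.035);
the continuum speed additionally requires dx refinement, and at
effective noise ≳0.05 spontaneous nucleation ahead of the front takes
over — the same noise phenomenology as the Langevin solver.

## What the generators emulate — and what they do not

All inputs are generated internally: the initial-condition fixtures
(centred bump, elevated-inhibitor homogeneous states) and the seeded
noise paths define the study conditions; there is no external data.
Real actin waves live on a closed 2-D cell cortex with dozens of
coupled species, receptor-driven external signals, and mechanical
feedback; this model is a 1-D two-species abstraction, so passing tests
demonstrate properties of the modelling chain (macroscopic ↔ mesoscopic
↔ microscopic consistency, excitability, noise-driven activation), not
quantitative cell biology.

## Problem sizes used by the test suite and acceptance script

Deterministic figure-level runs use the default grid (n=400, T≤100).
Langevin ensembles use the IMEX stepper at dt=2·10⁻³: 30 runs for the
noise-cutoff statistics, 10 seeds for the stochastic period, 20 runs per
parameter set for the WT/PTEN comparison (T=60).  Wave solves use
n=3200 on [−40,40]; the shape-preservation validation uses n=6400 on
[−20,20].  The spatial SSA test uses 77 cells on [−6,6] at Ω·dx ≈ 816.
These sizes were chosen so every quantity is resolution-converged at the
reported tolerance.

## Known limitations

- **Deterministic single-wave width.**  With the documented threshold
  rule the converged standing pulse measures 0.50 wide (0.46 at
  dx=0.0125); even thresholds barely above background give ≤ 0.7, so a
  reported reference value of 0.87 is not reproducible from the pulse
  shape under any admissible threshold here.  The activator spike is
  simply narrow: its interior layer is ~0.04 and its super-threshold
  core ~0.5.  Width values should therefore be read as
  detector-relative, not absolute.
- **WT vs PTEN-null durations.**  At matched σ=0.06 the PTEN-null
  parameter set nucleates ~1.4× more events and its waves travel ~1.6×
  faster, so on a periodic domain they annihilate sooner and the mean
  event duration comes out *shorter* than wild type (2.1 vs 2.4) — the
  opposite of the longer-lived protrusions seen microscopically.  The
  excitability ordering, by contrast, is reproduced quantitatively
  (PTEN-null activates at σ≈0.006, WT needs ≳0.015).
- The Langevin equation with the diffusion-noise flux is formally
  ill-posed in the continuum limit; all statements are about the fixed
  discretisation, and clamping introduces a small positive bias at low
  concentrations.
- Stochastic steppers are strong order ½ (Euler–Maruyama); no Milstein
  correction.
- No 2-D membrane, no Evans-function stability analysis of the wave
  profiles, no geometric singular-perturbation asymptotics.
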