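# Methods

## Model

Starved *C. elegans* L1 larvae on an agar surface are described by a
population density ρ(t, **x**) > 0 (cm⁻ᵈ, d = 1 or 2) that obeys a
Fokker–Planck / Keller–Segel equation,

    ∂ρ/∂t = ∇·(ρ∇V + σ∇ρ),      V = V_a(U_a) + V_r(U_r) + V_ρ(ρ),

i.e. worms drift down a potential V with mean velocity −∇V and disperse
with motility σ. The potential has three parts:

* **Weber-law signal response** V_i(U) = −β_i log(α_i + U) for each
  diffusible signal. β > 0 is an attractant (V decreases with
  concentration), β < 0 a repellent. The logarithmic form follows from
  integrating the just-noticeable-difference relation ΔU/(U + α) = const,
  and its convexity keeps velocities bounded where gradients are steep.
* **Crowding** V_ρ(ρ) = (σ·scale/2)(1 + tanh((ρ − ρ_max)/cushion)), a
  smoothed hard-core exclusion: the potential rises steeply as the local
  density approaches the packing density ρ_max, capping aggregate density.
* Each signal obeys a linear reaction–diffusion equation
  ∂U_i/∂t = −γ_i U_i + D_i∇²U_i + s_i ρ.

The two-signal variant pairs a short-range attractant
(√(D_a/γ_a) = 100 µm) with a long-range repellent (√(D_r/γ_r) = 1 mm).
Units are cm, s, and cm⁻ᵈ; the logarithm takes the numeric value of its
argument in cm⁻ᵈ — only ∇V matters, so the implied additive constant is
dynamically irrelevant.

### Default parameters

The bundled defaults (also in `l1agg/data/default.ini`) are the reference
parameter set for this system: σ = 5.555×10⁻⁶ cm²/s (calibrated so a
central bolus spreads over a 3 cm-radius plate in about half a day;
see `disk_mode_time_constant`), ρ_max = 28 000 cm⁻ᵈ (inverse footprint of
one larva), cushion = 2000 cm⁻ᵈ, scale = 2, β_a = 2σ = 1.111×10⁻⁵ cm²/s
(chosen so the attractant-only instability threshold is the observed
1500 cm⁻² minimum aggregation density), β_r = −2σ, α_a = α_r = 1500 cm⁻ᵈ,
γ_a = 0.01 s⁻¹, D_a = 10⁻⁶ cm²/s, γ_r = 0.001 s⁻¹, D_r = 10⁻⁵ cm²/s, and
secretion rates s_i numerically equal to γ_i so the uniform steady state
has U_i* = ρ̄ numerically. The same numbers are used in 1D and 2D. The
movement-slowdown variant multiplies σ, β_a, β_r (and with them the
σ·scale prefactor of V_ρ) by e^(−t/τ), leaving the chemical time scales
untouched, so the worm equation alone is a pure stretch of its time axis.

## Linear stability

Linearizing about (ρ̄, U_i* = s_i ρ̄/γ_i) gives, per wavenumber k, a small
eigenvalue problem (one row for ρ, one per signal). Because the chemical
rows are strictly stable, marginal stability is exactly captured by the
quasi-static condition

    g(k, ρ̄) = σ + ρ̄ V_ρ′(ρ̄) + ρ̄ Σ_i V_i′(U_i*) s_i/(γ_i + D_i k²),

with instability iff g < 0. With the defaults:

* attractant-only: g is minimized at k → 0 and the threshold is exactly
  ρ̄* = α/(β_a/σ − 1) = 1500 cm⁻ᵈ; above it every sufficiently long
  wavelength grows — there is no mechanism selecting a maximum aggregate
  size, and aggregates coarsen indefinitely.
* attractant+repellent: the two Lorentzians cancel at k → 0; the
  marginal optimum sits at k_c² = √(γ_aγ_r/(D_aD_r)) = 1000 cm⁻²
  (k_c ≈ 31.6 rad/cm) and the threshold rises to ρ̄* ≈ 2357 cm⁻ᵈ. The
  unstable band is bounded away from k = 0, so aggregates acquire a
  characteristic spacing.

The crowding term ρ̄V_ρ′(ρ̄) is ~10⁻¹⁷ cm²/s at threshold densities —
negligible against σ ≈ 5.6×10⁻⁶ — but is kept for generality (it is what
restabilizes the uniform state as ρ̄ → ρ_max). `instability_threshold`
brackets the root of min_k g by geometric scan and finishes with Brent's
method; the inner minimization over k is a bounded scalar minimization.
Wavenumbers are radians/cm in the stability module; the spectral module
reports cycles/cm (k/2π), and the conversion lives in one place to avoid
unit ambiguity.

## Discretization

Uniform tensor grids with periodic boundaries; cell centers at
(i + ½)Δx. Pointwise first and second derivatives use standard 4th-order
central stencils. The worm equation is discretized in conservative flux
form: face fluxes

    F_{i+½} = ρ̂_{i+½} (∂V/∂x)_{i+½} + σ (∂ρ/∂x)_{i+½}

are differenced, so total worm number is conserved to rounding regardless
of state. The face gradient uses the stencil
(f_{i−1} − 15f_i + 15f_{i+1} − f_{i+2})/(12Δx), chosen so that its
conservative difference reproduces the 4th-order pointwise Laplacian
exactly (a pointwise-accurate face derivative would lose two orders when
differenced). ρ is interpolated to faces with the symmetric 4-point
formula. The diffusive part of the flux is therefore formally 4th order;
the advective product term carries an O(Δx²) cross term
(∝ ρ‴V′ - type mixed derivatives) with a 4th-order-small prefactor — the
observed Laplacian convergence order on smooth fields exceeds 3.9, and
the linear growth rates of the full discrete system match the continuous
dispersion relation to < 10⁻⁴ relative at the default resolutions.

Degenerate inputs: the worm equation contains log ρ, so states must be
strictly positive; a floor of 10⁻⁶ρ̄ is applied after each accepted step,
followed by an exact multiplicative mass renormalization.

## Time integration

The right-hand side is split f = Lu + N(u, t): L holds signal diffusion
and decay plus a worm diffusion ν∇² with ν = σ_eff + max(ρV_ρ′(ρ))
(re-linearized each step — the crowding term acts as a nonlinear
diffusivity up to ~14σ inside plateaus and would otherwise force
explicit-stability step sizes); N is the remaining advection and
coupling. L is constant-coefficient on the periodic grid, hence diagonal
in Fourier space, and implicit stages are exact pointwise solves on the
rfft lattice — no linear-solver tolerance enters.

Stepping is the L-stable two-stage second-order IMEX scheme ARS(2,2,2).
The local error is estimated against an embedded IMEX-Euler solution
(a deliberately conservative first-order gap), controlled against
atol + rtol·|u| with step factors in [0.2, 4] and safety 0.9. Defaults
are rtol = 10⁻⁶, atol = 10⁻⁹; scenario presets use rtol = 10⁻⁴, which
resolution studies (128² vs 256², rtol 10⁻⁴ vs 10⁻⁵) show leaves
aggregate counts and spectra unchanged. In addition the step size is
capped by the velocity condition Δt ≤ min(Δx/|v_x|, Δy/|v_y|) with
v = −∇V, so no worm "jumps" a cell in one step. Noise injections and
snapshot times are hard breakpoints; step-size control restarts at
dt_init/10 after an injection because fresh high-frequency noise demands
small steps.

## Scenarios and noise

* `uniform_noisy_ic`: ρ = ρ̄(1 + εZ) with i.i.d. standard normal Z
  (default ε = 1%, i.e. SD 90 cm⁻ᵈ at ρ̄ = 9000), floored, renormalized
  to exact mass; signals start at the uniform steady state.
* `center_sphere_ic` (full-scale plate): background b_ρ = 100 cm⁻²
  plus a hemispherical-height bump ρ = b_ρ + a_ρ√(max(0, 1 − r²/R²)) with
  R = 1 cm and a_ρ = 3(ρ̄ − b_ρ)w²/(2πR²), i.e. 68 400 worms dropped from
  a 2 cm sphere onto the center plus 3600 spread uniformly (total 72 000,
  ρ̄ = 2000 cm⁻²); 1% multiplicative noise is applied after superposition.
  The square-root profile is used because a solid sphere's worms falling
  vertically produce a column height ∝ chord length, and the
  normalization constant matches the hemisphere-height integral 2πR²/3
  exactly.
* Injected noise (full-scale runs): at t_n = 10^(n/2) s, n = 0…10, each
  grid density is multiplied by exp(P) with P ~ N(0, 10⁻⁶Δt), Δt the time
  since the previous injection, then mass is renormalized exactly —
  a geometric Brownian perturbation mimicking continuous behavioral noise.
* Slowdown preset τ values {1800, 7200, 28800, 86400} s span "aggregation
  arrested" (30 min) to "irregular aggregates persist"; only the 30 min
  value is fixed by the source description, the others are package
  choices spanning the regimes.

Default desk-scale resolutions are 1024 points for 1D and 128² for 2D on
1×1 cm domains (the full-scale 6×6 cm at 384 points/cm — 1.6×10⁷
unknowns — is supported but not a default; the `fig6` preset can be run
at reduced resolution with `--resolution`).

## Spectral pattern quantification

Images are standardized to brightness in [0, 1]; the 2D DFT power
p_k = |b̃_k|² lives on the lattice (2π/w)Z² (numpy's unscaled-forward
convention, so Parseval reads Σp_k = N²Σb²). Radial summation maps each
lattice point at k_cyc = ‖k‖/2π to the 1-based bin coordinate
j = 1 + 1023·k_cyc/20 on a 1024-bin axis spanning 0–20 cycles/cm, and
splits its power between ⌊j⌋ and ⌈j⌉ with weights (⌈j⌉ − j, j − ⌊j⌋);
weights sum to one, so binned power is conserved exactly. The raw radial
spectrum is quasi-periodic with period ≈ 26.5 bins (a binning artifact of
the square lattice); Gaussian smoothing with radius 18.7 bins (Gaussian
σ = radius/2, the Mathematica `GaussianFilter` convention) is the
smallest that suppresses it. The dominant peak is the argmax over bins
with k_cyc ≥ 2 cycles/cm, excluding the DC/large-scale envelope.

The synthetic-pattern generator places Gaussian-profile spots on a
hexagonal or square lattice (commensurate with the periodic domain, with
optional positional jitter) and is the ground-truth fixture for the
pipeline: a hexagonal lattice with spacing a peaks at 2/(√3·a) cycles/cm.
It emulates the geometry of aggregate images, not their photometric
noise, motion blur, or the bright central mass of a real plate — tests
passing on it validate the spectral arithmetic, not robustness to
imaging artifacts.

## Particle oracle

The worm PDE is the Fokker–Planck equation of the overdamped Langevin
process dX = −∇V dt + √(2σ) dW, so an ensemble of Euler–Maruyama
particles is an independent cross-check of the continuum solver (in place
of lattice-based individual models whose parameters have no direct
correspondence). Particles deposit density with cloud-in-cell weights
(exact mass conservation); chemical fields advance on the grid with the
exact Fourier-space solution of their linear PDEs over each particle
step; forces are bilinear interpolations of −∇V. If the drift would move
a particle more than one cell per step, the step is sub-divided (with a
warning). With frozen fields the ensemble relaxes to the Gibbs density
∝ exp(−V/σ), and with full coupling it sits on the same side of the
instability threshold as the PDE.

## Numerical experiments: what the model does at desk scale

On 1×1 cm at ρ̄ = 9000 with 1% initial noise, the two-signal model first
amplifies modes at the fastest-growing wavenumber (7.7 cycles/cm,
matching the dispersion relation to <10⁻⁴), forms ~50 dense plateaus
saturating just below ρ_max, undergoes early ripening down to ~30–35
aggregates by t ≈ 2×10⁴ s, and then holds an essentially constant count
to 2×10⁵ s with a dominant radial-spectrum peak near 6 cycles/cm and a
dense-area fraction near ρ̄/ρ_max = 0.32. These numbers are stable under
refinement to 256² and tightening rtol to 10⁻⁵, so the post-linear
wavelength selection (somewhat coarser than the fastest linear mode) is a
property of the model under these conditions, not of the numerics. The
attractant-only variant never equilibrates: velocities remain O(Δx/s)
indefinitely and aggregates continue to merge, which also makes long
attractant-only runs the most expensive scenario (the step cap stays
small); the packaged coarsening checks therefore run in 1D.

## Known limitations

* The continuum density is only a measure over worm positions; at low
  expected counts it reads as a probability, not as fractional worms.
* No worm geometry, debris, oxygen, or surface-tension effects; the
  central region of full-scale plate runs is explicitly outside the
  model's remit.
* The advective flux is not positivity-preserving by construction; the
  density floor plus renormalization handles the (rare) undershoots.
* Slowdown applies a single global e^(−t/τ) to movement parameters; no
  per-worm energy state is tracked.
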