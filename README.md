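# l1agg — Keller–Segel model of starved *C. elegans* L1 aggregation

Starved first-stage (L1) *C. elegans* larvae on an agar plate collect
into dense, circular, evenly spaced aggregates. `l1agg` is a tested
simulator and analysis toolkit for the continuum model of this behavior:
worms are a density field ρ(t, **x**) that drifts down a potential built
from two self-secreted diffusible signals — a short-range attractant and
a long-range repellent — plus a crowding term, coupled to linear
reaction–diffusion equations for the signals:

    ∂ρ/∂t   = ∇·( ρ∇V + σ∇ρ ),      V = −β_a log(α_a + U_a) − β_r log(α_r + U_r) + V_ρ(ρ)
    ∂U_i/∂t = −γ_i U_i + D_i ∇²U_i + s_i ρ,        i ∈ {a, r}

with V_ρ(ρ) = (σ·scale/2)(1 + tanh((ρ − ρ_max)/cushion)) approximating
hard-core exclusion at the packing density ρ_max. β > 0 attracts,
β < 0 repels; the logarithm is a Weber-law response. The package is
aimed at modelers studying chemotaxis-driven pattern formation:
it provides

* the model and its parameters (`l1agg.model`), defaulting to the
  reference parameter set for L1 aggregation;
* a conservative 4th-order periodic finite-difference discretization
  (`l1agg.dynamics`) and an adaptive FFT-based IMEX integrator with the
  velocity step cap Δt ≤ min(Δx/|v|) (`l1agg.integrate`);
* linear stability analysis — dispersion relations, instability
  thresholds, fastest-growing modes, and the Neumann disk eigenmodes
  used to calibrate σ (`l1agg.stability`);
* scenario drivers for the standard numerical experiments, including
  noisy-uniform and central-bolus initial conditions and the geometric
  Brownian noise-injection schedule (`l1agg.scenarios`);
* radially summed Fourier power spectra with fractional-bin weighting
  for pattern quantification, plus a synthetic aggregate-pattern
  generator (`l1agg.spectral`);
* aggregate morphology and worm-centric diagnostics (`l1agg.diagnostics`);
* an individual-based Langevin particle cross-check whose empirical
  density obeys the same Fokker–Planck equation (`l1agg.particles`).

`docs/methods.md` describes the model, numerics, and design choices in
detail. Short narrative scripts live in `examples/`; a thin CLI
(`l1agg simulate|scenario|stability|threshold|spectrum|diagnose|oracle`)
wraps the library for shell use.

## Worked example

Why does the repellent matter? Ask the linear stability module:

```sh
$ python examples/threshold_and_dispersion.py
attractant-only        threshold =   1500.0 cm^-2   k_c =  0.000 rad/cm (0.00 cycles/cm)
attractant+repellent   threshold =   2357.1 cm^-2   k_c = 31.623 rad/cm (5.03 cycles/cm)

fastest-growing mode at rho_bar = 9000: k* = 48.5 rad/cm = 7.72 cycles/cm, growth rate 1.85e-03 /s (e-folding 540 s)
```

The attractant-only model goes unstable at the experimentally observed
density 1500 cm⁻², but its unstable band reaches k = 0: nothing limits
aggregate size, so aggregates coarsen forever. Adding the long-range
repellent raises the threshold to 2357 cm⁻² and bounds the unstable band
away from zero (critical wavenumber 31.6 rad/cm), selecting a finite
pattern spacing. At the working density 9000 cm⁻² the fastest-growing
mode has a 540 s e-folding time, so patterns emerge within an hour.

Running the nonlinear model in 1D from 1% noise shows the aggregates:

```sh
$ python examples/aggregation_1d.py
time (s)   plateaus   max rho   10th-pct rho   mass drift
       0          0      9283         8896.0   0.00e+00
    5000          7     25831          687.3   0.00e+00
   20000          6     26079          322.5   0.00e+00
   40000          6     26072          318.9   0.00e+00
```

Within ~5000 s the field develops dense plateaus saturating just below
ρ_max = 28 000 (the crowding cap) separated by a dilute exterior two
orders of magnitude below the mean, and the plateau count stabilizes —
the signature of repellent-limited aggregation. Total worm number is
conserved to rounding.

The spectral pipeline quantifies pattern spacing
(`examples/spectral_pipeline.py`): a synthetic hexagonal pattern with
1 mm spacing yields a dominant radial-spectrum peak at 11.7 cycles/cm
against the analytic reciprocal-ring value 2/(√3·a) = 11.5. The particle
oracle (`examples/particle_cross_check.py`) reproduces free-diffusion
MSD = 4σt to 1% and aggregates above threshold just like the PDE.

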