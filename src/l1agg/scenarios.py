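"""Initial conditions, noise injection, and scenario drivers.

Presets reproduce the standard numerical experiments at configurable
scale: small-domain aggregation runs of the attractant-only and
attractant+repellent models (1D and 2D), the movement-slowdown variant,
and the full-scale 6 cm plate run started from a central bolus of worms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .grid import FieldState, PeriodicGrid
from .integrate import (SimulationResult, StepController, simulate)
from .model import ModelParameters, SlowdownSchedule, uniform_steady_state

__all__ = ["ScenarioConfig", "uniform_noisy_ic", "center_sphere_ic",
           "noise_schedule", "inject_noise", "run_scenario",
           "scenario_preset", "PRESETS"]

VARIANTS = ("attractant-only", "attractant-repellent", "slowdown")
IC_TYPES = ("uniform-noisy", "center-sphere")


@dataclass(frozen=True)
class ScenarioConfig:
    variant: str = "attractant-repellent"
    dim: int = 2
    extent: float = 1.0              # domain width (and height), cm
    resolution: int = 128            # points per axis
    rho_bar: float = 9000.0          # mean density, cm^-d
    ic: str = "uniform-noisy"
    seed: int = 0
    noise_frac: float = 0.01         # initial noise, fraction of local density
    inject: bool = False             # geometric Brownian noise schedule on/off
    tau: float = 1800.0              # slowdown time constant, s
    t_end: float = 2e5
    snapshot_times: tuple[float, ...] = ()
    rtol: float = 1e-4
    atol: float = 1e-4
    params: ModelParameters | None = None   # overrides the variant default

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.ic not in IC_TYPES:
            raise ValueError(f"unknown IC type {self.ic!r}")
        if self.t_end < 0:
            raise ValueError("t_end must be nonnegative")

    def build_params(self) -> ModelParameters:
        if self.params is not None:
            return replace(self.params, dim=self.dim, rho_bar=self.rho_bar)
        p = ModelParameters(dim=self.dim, rho_bar=self.rho_bar)
        if self.variant == "attractant-only":
            p = p.attractant_only()
        return p

    def build_schedule(self) -> SlowdownSchedule:
        return SlowdownSchedule(tau=self.tau, enabled=self.variant == "slowdown")

    def build_grid(self) -> PeriodicGrid:
        if self.dim == 1:
            return PeriodicGrid.line(self.extent, self.resolution)
        return PeriodicGrid.square(self.extent, self.resolution)


def uniform_noisy_ic(rho_bar: float, noise_frac: float, seed: int,
                     grid: PeriodicGrid, params: ModelParameters) -> FieldState:
    """Uniform density with additive Gaussian noise of SD noise_frac*rho_bar.

    The field is clipped to the positivity floor and renormalized so total
    worm number is exactly rho_bar times the domain volume; signals start
    at their uniform steady state.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be nonnegative")
    rng = np.random.default_rng(seed)
    rho = rho_bar * (1.0 + noise_frac * rng.standard_normal(grid.shape))
    floor = 1e-6 * rho_bar
    np.maximum(rho, floor, out=rho)
    target = rho_bar * math.prod(grid.extent)
    rho *= target / grid.integrate(rho)
    Ua_star, Ur_star = uniform_steady_state(rho_bar, params)
    U_a = np.full(grid.shape, Ua_star)
    U_r = np.full(grid.shape, Ur_star) if params.repellent_enabled else None
    return FieldState(0.0, rho, U_a, U_r)


def center_sphere_ic(grid: PeriodicGrid, params: ModelParameters,
                     rho_bar: float = 2000.0, b_rho: float = 100.0,
                     R: float = 1.0, noise_frac: float = 0.01,
                     seed: int = 0) -> FieldState:
    """Central bolus: worms from a sphere of radius R dropped onto the plate.

    rho(x, y) = b_rho + a_rho * sqrt(max(0, 1 - r^2/R^2)) with r the
    distance to the domain center and a_rho = 3*(rho_bar - b_rho)*w^2 /
    (2*pi*R^2), so the hemispherical-height bump holds all worms above the
    uniform background.  Multiplicative 1% Gaussian noise is applied after
    the superposition.
    """
    if grid.dim != 2:
        raise ValueError("center-sphere IC requires a 2D grid")
    w, h = grid.extent
    if min(w, h) < 2 * R:
        raise ValueError(f"domain {w}x{h} cm too small for bump radius {R} cm")
    a_rho = 3.0 * (rho_bar - b_rho) * w * h / (2.0 * math.pi * R ** 2)
    X, Y = grid.meshgrid()
    r2 = (X - w / 2.0) ** 2 + (Y - h / 2.0) ** 2
    rho = b_rho + a_rho * np.sqrt(np.maximum(0.0, 1.0 - r2 / R ** 2))
    rng = np.random.default_rng(seed)
    if noise_frac > 0:
        rho = rho * (1.0 + noise_frac * rng.standard_normal(grid.shape))
        np.maximum(rho, 1e-6 * rho_bar, out=rho)
    Ua_star, Ur_star = uniform_steady_state(rho_bar, params)
    U_a = np.full(grid.shape, Ua_star)
    U_r = np.full(grid.shape, Ur_star) if params.repellent_enabled else None
    return FieldState(0.0, rho, U_a, U_r)


def noise_schedule() -> list[float]:
    """Injection times t_n = 10^(n/2) s for n = 0..10."""
    return [10.0 ** (n / 2.0) for n in range(11)]


def inject_noise(state: FieldState, dt_since_last: float,
                 rng: np.random.Generator) -> FieldState:
    """Geometric Brownian noise: rho <- rho*exp(P), P ~ N(0, 1e-6*dt).

    The density is then rescaled so the total worm number is exactly
    unchanged; signal fields are untouched.
    """
    if dt_since_last <= 0:
        raise ValueError("dt_since_last must be positive")
    sd = math.sqrt(1e-6 * dt_since_last)
    P = rng.normal(0.0, sd, size=state.rho.shape)
    rho = state.rho * np.exp(P)
    rho *= state.rho.sum() / rho.sum()
    return FieldState(state.t, rho, state.U_a, state.U_r)


def run_scenario(scenario: ScenarioConfig) -> SimulationResult:
    """Compose IC, noise events, and integrator for one scenario."""
    params = scenario.build_params()
    schedule = scenario.build_schedule()
    grid = scenario.build_grid()

    if scenario.ic == "uniform-noisy":
        state = uniform_noisy_ic(scenario.rho_bar, scenario.noise_frac,
                                 scenario.seed, grid, params)
    else:
        state = center_sphere_ic(grid, params, rho_bar=scenario.rho_bar,
                                 noise_frac=scenario.noise_frac,
                                 seed=scenario.seed)

    events = []
    if scenario.inject:
        rng = np.random.default_rng((scenario.seed, 1))
        times = [tt for tt in noise_schedule() if tt < scenario.t_end]
        prev = 0.0
        for tt in times:
            dt_since = tt - prev

            def make(dt_since=dt_since):
                return lambda s: inject_noise(s, dt_since, rng)

            events.append((tt, make()))
            prev = tt

    controller = StepController(rtol=scenario.rtol, atol=scenario.atol)
    return simulate(state, params, schedule, controller, grid,
                    t_end=scenario.t_end,
                    snapshot_times=list(scenario.snapshot_times),
                    events=events, seed=scenario.seed)


PRESETS: dict[str, ScenarioConfig] = {
    # small-domain aggregation from 1% noise on 1 cm domains
    "fig2-1d": ScenarioConfig(variant="attractant-only", dim=1,
                              resolution=1024),
    "fig2-2d": ScenarioConfig(variant="attractant-only", dim=2,
                              resolution=128),
    "fig3-1d": ScenarioConfig(variant="attractant-repellent", dim=1,
                              resolution=1024),
    "fig3-2d": ScenarioConfig(variant="attractant-repellent", dim=2,
                              resolution=128),
    # slowdown variant; tau of 1800 s arrests aggregation early
    "fig5": ScenarioConfig(variant="slowdown", dim=2, resolution=128,
                           tau=1800.0),
    # full-scale 6 cm plate, central bolus, noise injections; default
    # resolution scaled down from the full-scale 384 points/cm
    "fig6": ScenarioConfig(variant="attractant-repellent", dim=2,
                           extent=6.0, resolution=384, rho_bar=2000.0,
                           ic="center-sphere", inject=True),
}

SLOWDOWN_TAUS = (1800.0, 7200.0, 28800.0, 86400.0)


def scenario_preset(name: str, **overrides) -> ScenarioConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)
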