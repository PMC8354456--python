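"""Adaptive stiff time integration of the method-of-lines system.

The right-hand side is split additively, f = L u + N(u, t), where L holds
the stiff linear terms (signal diffusion and decay; worm diffusion plus a
per-step linearized crowding diffusivity) and N the remaining nonlinear
advection and coupling.  L is constant-coefficient on the periodic grid and
therefore diagonal in Fourier space, so implicit stages are exact
pointwise solves on the rfft lattice.

Time stepping uses the L-stable two-stage, second-order IMEX Runge-Kutta
scheme of Ascher, Ruth & Spiteri (ARS(2,2,2)), with an embedded IMEX-Euler
solution for local error estimation, a PI-free step controller, and the
velocity-based step cap dt <= min(dx/|v_x|, dy/|v_y|).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import (discrete_laplacian_eigenvalues, full_rhs,
                       velocity_field)
from .grid import FieldState, PeriodicGrid
from .model import (ModelParameters, SlowdownSchedule,
                    crowding_potential_derivative, effective_motility)

__all__ = ["StepController", "SimulationResult", "cfl_limit", "advance",
           "simulate", "run_simulation", "IntegrationError"]

_GAMMA = 1.0 - math.sqrt(0.5)          # ARS(2,2,2) implicit coefficient
_DELTA = 1.0 - 1.0 / (2.0 * _GAMMA)

DENSITY_FLOOR_FRACTION = 1e-6          # floor = fraction * mean density


class IntegrationError(RuntimeError):
    """Raised when the step size underflows dt_min."""

    def __init__(self, message: str, state: FieldState | None = None):
        super().__init__(message)
        self.state = state


@dataclass
class StepController:
    rtol: float = 1e-6
    atol: float = 1e-9
    dt_init: float = 1.0
    dt_min: float = 1e-8
    dt_max: float = 5000.0
    cfl_enabled: bool = True
    safety: float = 0.9

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if not (self.dt_min <= self.dt_init <= self.dt_max):
            raise ValueError("require dt_min <= dt_init <= dt_max")


@dataclass
class SimulationResult:
    """Snapshots plus step-size, mass, and RNG bookkeeping for one run."""

    snapshots: list[FieldState]
    times: list[float]
    step_sizes: list[float] = field(default_factory=list)
    n_accepted: int = 0
    n_rejected: int = 0
    mass_history: list[tuple[float, float]] = field(default_factory=list)
    seed: int | None = None

    @property
    def max_mass_drift(self) -> float:
        if not self.mass_history:
            return 0.0
        m0 = self.mass_history[0][1]
        return max(abs(m - m0) / m0 for _, m in self.mass_history)


def cfl_limit(state: FieldState, params: ModelParameters, grid: PeriodicGrid,
              motility: tuple[float, float, float] | None = None) -> float:
    """Velocity step cap min over points and axes of spacing/|v|; inf if v = 0."""
    comps, _ = velocity_field(state, params, grid, motility=motility)
    cap = math.inf
    for h, c in zip(grid.spacing, comps):
        vmax = float(np.max(np.abs(c)))
        if vmax > 0:
            cap = min(cap, h / vmax)
    return cap


def _linear_symbols(state: FieldState, params: ModelParameters,
                    sigma_eff: float, grid: PeriodicGrid) -> list[np.ndarray]:
    """Fourier symbols of L per field (rfftn lattice)."""
    lam = discrete_laplacian_eigenvalues(grid)
    # Stabilizing diffusivity: sigma plus the largest crowding diffusivity
    # rho * V_rho'(rho) present in the current state.
    factor = sigma_eff / params.sigma if params.sigma > 0 else 1.0
    crowd = float(np.max(state.rho * crowding_potential_derivative(
        state.rho, params))) * factor
    nu = sigma_eff + crowd
    syms = [nu * lam, -params.gamma_a + params.D_a * lam]
    if params.repellent_enabled:
        syms.append(-params.gamma_r + params.D_r * lam)
    return syms


def _rfft(fields: list[np.ndarray]) -> list[np.ndarray]:
    return [np.fft.rfftn(f) for f in fields]


def _irfft(hats: list[np.ndarray], shape: tuple[int, ...]) -> list[np.ndarray]:
    return [np.fft.irfftn(h, s=shape, axes=tuple(range(len(shape)))) for h in hats]


def _rhs(fields: list[np.ndarray], t: float, params: ModelParameters,
         schedule: SlowdownSchedule | None, grid: PeriodicGrid) -> list[np.ndarray]:
    state = FieldState(t, fields[0], fields[1],
                       fields[2] if len(fields) > 2 else None)
    return full_rhs(state, params, schedule, grid, t=t)


def _error_norm(diffs: list[np.ndarray], fields: list[np.ndarray],
                rtol: float, atol: float) -> float:
    total = 0.0
    n = 0
    for d, u in zip(diffs, fields):
        w = atol + rtol * np.abs(u)
        total += float(np.sum((d / w) ** 2))
        n += d.size
    return math.sqrt(total / n)


def _step(fields: list[np.ndarray], t: float, dt: float,
          syms: list[np.ndarray], params: ModelParameters,
          schedule: SlowdownSchedule | None, grid: PeriodicGrid,
          controller: StepController) -> tuple[list[np.ndarray], float]:
    """One ARS(2,2,2) step; returns (new fields, normalized error)."""
    shape = grid.shape
    hats = _rfft(fields)
    f_n = _rhs(fields, t, params, schedule, grid)
    F_n = _rfft(f_n)
    N_n = [Fh - S * h for Fh, S, h in zip(F_n, syms, hats)]

    g = _GAMMA
    u1_hat = [(h + g * dt * Nh) / (1.0 - g * dt * S)
              for h, Nh, S in zip(hats, N_n, syms)]
    u1 = _irfft(u1_hat, shape)
    u1[0] = np.maximum(u1[0], 1e-300)          # guard log/tanh in stage rhs

    f_1 = _rhs(u1, t + g * dt, params, schedule, grid)
    F_1 = _rfft(f_1)
    N_1 = [Fh - S * h for Fh, S, h in zip(F_1, syms, u1_hat)]

    new_hat = [(h + dt * (_DELTA * Nn + (1.0 - _DELTA) * N1 + (1.0 - g) * S * h1))
               / (1.0 - g * dt * S)
               for h, Nn, N1, S, h1 in zip(hats, N_n, N_1, syms, u1_hat)]

    # Embedded first-order IMEX-Euler solution for the error estimate.
    euler_hat = [(h + dt * Nn) / (1.0 - dt * S)
                 for h, Nn, S in zip(hats, N_n, syms)]

    new = _irfft(new_hat, shape)
    diffs = _irfft([a - b for a, b in zip(new_hat, euler_hat)], shape)
    err = _error_norm(diffs, new, controller.rtol, controller.atol)
    return new, err


def advance(state: FieldState, t_target: float, params: ModelParameters,
            schedule: SlowdownSchedule | None, controller: StepController,
            grid: PeriodicGrid,
            result: SimulationResult | None = None,
            dt_start: float | None = None) -> FieldState:
    """Integrate the full system from state.t to t_target.

    A density floor of 1e-6 times the mean density is applied after each
    accepted step, followed by multiplicative mass renormalization, so the
    total worm number is exactly conserved.
    """
    if t_target < state.t:
        raise ValueError("t_target must be >= state.t")
    state.validate(grid)
    fields = [f.astype(float).copy() for f in state.fields()]
    t = state.t
    mass0 = grid.integrate(fields[0])
    floor = DENSITY_FLOOR_FRACTION * mass0 / (grid.n_points * grid.cell_volume)
    dt = dt_start if dt_start is not None else controller.dt_init

    while t < t_target - 1e-12 * max(1.0, t_target):
        sigma_eff, _, _ = effective_motility(params, schedule, t)
        cur = FieldState(t, fields[0], fields[1],
                         fields[2] if len(fields) > 2 else None)
        syms = _linear_symbols(cur, params, sigma_eff, grid)
        if controller.cfl_enabled:
            cap = cfl_limit(cur, params, grid,
                            motility=effective_motility(params, schedule, t))
            dt = min(dt, cap)
        dt = min(dt, controller.dt_max, t_target - t)
        if dt < controller.dt_min:
            raise IntegrationError(
                f"step size underflow at t={t:.6g} (dt={dt:.3g})", cur)

        new, err = _step(fields, t, dt, syms, params, schedule, grid, controller)
        if err <= 1.0 and np.all(np.isfinite(new[0])):
            t += dt
            fields = new
            # positivity floor + exact mass renormalization
            np.maximum(fields[0], floor, out=fields[0])
            fields[0] *= mass0 / grid.integrate(fields[0])
            if result is not None:
                result.n_accepted += 1
                result.step_sizes.append(dt)
            factor = controller.safety * (err ** -0.5 if err > 0 else 4.0)
            dt *= min(4.0, max(0.2, factor))
        else:
            if result is not None:
                result.n_rejected += 1
            if not np.all(np.isfinite(new[0])):
                dt *= 0.1
            else:
                dt *= max(0.1, controller.safety * err ** -0.5)

    return FieldState(t_target, fields[0], fields[1],
                      fields[2] if len(fields) > 2 else None)


def simulate(state: FieldState, params: ModelParameters,
             schedule: SlowdownSchedule | None, controller: StepController,
             grid: PeriodicGrid, t_end: float,
             snapshot_times: list[float] | None = None,
             events: list[tuple[float, object]] | None = None,
             seed: int | None = None) -> SimulationResult:
    """Run advance piecewise between snapshots and hard event breakpoints.

    ``events`` is a list of (time, callable) pairs; each callable maps a
    FieldState to a new FieldState (e.g. noise injection).  Step-size
    control restarts at dt_init/10 after each event, since injected
    high-frequency noise demands small steps.
    """
    snapshot_times = sorted(snapshot_times or [])
    events = sorted(events or [], key=lambda e: e[0])
    result = SimulationResult(snapshots=[state.copy()], times=[state.t], seed=seed)
    result.mass_history.append((state.t, grid.integrate(state.rho)))

    breakpoints: list[tuple[float, str, object]] = (
        [(tt, "snap", None) for tt in snapshot_times if tt > state.t]
        + [(tt, "event", fn) for tt, fn in events if tt > state.t])
    if t_end > state.t:
        breakpoints.append((t_end, "end", None))
    breakpoints.sort(key=lambda b: b[0])

    cur = state
    dt_start = None
    for tt, kind, fn in breakpoints:
        if tt > t_end + 1e-12:
            break
        if tt > cur.t:
            cur = advance(cur, tt, params, schedule, controller, grid,
                          result=result, dt_start=dt_start)
            dt_start = result.step_sizes[-1] if result.step_sizes else None
        if kind == "event":
            cur = fn(cur)
            dt_start = controller.dt_init / 10.0
        if kind in ("snap", "end"):
            result.snapshots.append(cur.copy())
            result.times.append(cur.t)
            result.mass_history.append((cur.t, grid.integrate(cur.rho)))
    if not breakpoints:           # zero-duration run
        pass
    return result


def run_simulation(config) -> SimulationResult:
    """Run a full scenario from a ScenarioConfig (see :mod:`l1agg.scenarios`)."""
    from .scenarios import run_scenario
    return run_scenario(config)
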