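"""Model parameters and closed-form potential functions.

The model describes starved C. elegans L1 larvae as a population density
``rho`` that drifts down a scalar potential ``V`` while diffusing with
motility ``sigma``.  The potential is a sum of

* a Weber-law response to each diffusible signal,
  ``V_U(U) = -beta * log(alpha + U)`` — attractant for ``beta > 0``,
  repellent for ``beta < 0``;
* a crowding term ``V_rho(rho) = sigma*scale/2 * (1 + tanh((rho - rho_max)/cushion))``
  that approximates hard-core exclusion near the packing density ``rho_max``.

Each signal obeys a linear reaction-diffusion equation
``dU/dt = -gamma*U + D*lap(U) + s*rho``.

Units: lengths in cm, times in s, densities and concentrations in cm^-d
where ``d`` is the spatial dimension.  The logarithm in the Weber potential
is taken of the numeric value of its argument expressed in cm^-d; only
potential gradients enter the dynamics, so the additive constant implied by
this unit convention is dynamically irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "SlowdownSchedule",
    "signal_potential",
    "signal_potential_derivative",
    "crowding_potential",
    "crowding_potential_derivative",
    "total_potential",
    "uniform_steady_state",
    "signal_range",
    "slowdown_factor",
    "effective_motility",
]


@dataclass(frozen=True)
class ModelParameters:
    """All rate and shape constants of the model.

    Defaults are the reference parameter set for L1 aggregation: signal
    secretion and decay rates are numerically equal per signal, so that the
    uniform steady-state concentration of each signal equals the worm
    density numerically.
    """

    dim: int = 2
    rho_bar: float = 9000.0          # mean worm density, cm^-d
    sigma: float = 5.555e-6          # random motility, cm^2/s
    rho_max: float = 28000.0         # crowding midpoint, cm^-d
    cushion: float = 2000.0          # crowding transition width, cm^-d
    scale: float = 2.0               # crowding height multiplier
    beta_a: float = 1.111e-5         # attractant coupling (= 2*sigma), cm^2/s
    alpha_a: float = 1500.0          # attractant concentration offset, cm^-d
    gamma_a: float = 0.01            # attractant decay rate, 1/s
    D_a: float = 1.0e-6              # attractant diffusion, cm^2/s
    s_a: float = 0.01                # attractant secretion per worm, cm^-d/s
    beta_r: float = -1.111e-5        # repellent coupling (= -2*sigma), cm^2/s
    alpha_r: float = 1500.0
    gamma_r: float = 0.001
    D_r: float = 1.0e-5
    s_r: float = 0.001
    repellent_enabled: bool = True

    def __post_init__(self) -> None:
        if self.dim not in (1, 2):
            raise ValueError(f"dim must be 1 or 2, got {self.dim}")
        for name in ("sigma", "rho_max", "cushion", "alpha_a", "gamma_a",
                     "D_a", "s_a", "alpha_r", "gamma_r", "D_r", "s_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.rho_bar < 0:
            raise ValueError("rho_bar must be nonnegative")

    @property
    def signals(self) -> tuple[str, ...]:
        return ("a", "r") if self.repellent_enabled else ("a",)

    def signal_params(self, which: str) -> tuple[float, float, float, float, float]:
        """Return (beta, alpha, gamma, D, s) for signal 'a' or 'r'."""
        if which == "a":
            return self.beta_a, self.alpha_a, self.gamma_a, self.D_a, self.s_a
        if which == "r":
            return self.beta_r, self.alpha_r, self.gamma_r, self.D_r, self.s_r
        raise ValueError(f"unknown signal {which!r}")

    def attractant_only(self) -> "ModelParameters":
        return replace(self, repellent_enabled=False)


@dataclass(frozen=True)
class SlowdownSchedule:
    """Exponential decay of worm movement parameters.

    When enabled, sigma(t) = sigma0*exp(-t/tau), and likewise for beta_a
    and beta_r; the chemical-field equations keep their own time scales.
    The crowding potential's amplitude (prefactor sigma*scale) decays with
    sigma(t) too, so the worm equation in isolation is a pure stretch of
    its time axis.
    """

    tau: float = 7200.0              # decay time constant, s
    enabled: bool = False
    sigma0: float | None = None      # t=0 values; None = take from ModelParameters
    beta_a0: float | None = None
    beta_r0: float | None = None

    def __post_init__(self) -> None:
        if self.enabled and self.tau <= 0:
            raise ValueError("tau must be positive when slowdown is enabled")


NO_SLOWDOWN = SlowdownSchedule(enabled=False)


def slowdown_factor(t: float, schedule: SlowdownSchedule | None) -> float:
    """Dimensionless multiplier e^{-t/tau} applied to sigma, beta_a, beta_r."""
    if t < 0:
        raise ValueError(f"t must be nonnegative, got {t}")
    if schedule is None or not schedule.enabled:
        return 1.0
    return math.exp(-t / schedule.tau)


def effective_motility(params: ModelParameters,
                       schedule: SlowdownSchedule | None,
                       t: float) -> tuple[float, float, float]:
    """(sigma, beta_a, beta_r) at time t under the slowdown schedule."""
    f = slowdown_factor(t, schedule)
    if schedule is not None and schedule.enabled:
        sigma0 = schedule.sigma0 if schedule.sigma0 is not None else params.sigma
        ba0 = schedule.beta_a0 if schedule.beta_a0 is not None else params.beta_a
        br0 = schedule.beta_r0 if schedule.beta_r0 is not None else params.beta_r
        return sigma0 * f, ba0 * f, br0 * f
    return params.sigma, params.beta_a, params.beta_r


def _check_signal_args(U, alpha: float) -> np.ndarray:
    U = np.asarray(U, dtype=float)
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if np.any(U < 0):
        raise ValueError("signal concentration must be nonnegative")
    return U


def signal_potential(U, alpha: float, beta: float):
    """Weber-law potential -beta*log(alpha + U), in cm^2/s."""
    U = _check_signal_args(U, alpha)
    return -beta * np.log(alpha + U)


def signal_potential_derivative(U, alpha: float, beta: float):
    """dV_U/dU = -beta/(alpha + U)."""
    U = _check_signal_args(U, alpha)
    return -beta / (alpha + U)


def _check_rho(rho) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("density must be nonnegative")
    return rho


def crowding_potential(rho, params: ModelParameters, sigma: float | None = None):
    """Crowding potential sigma*scale/2*(1 + tanh((rho - rho_max)/cushion)).

    ``sigma`` overrides the amplitude prefactor (used by the slowdown model,
    where the whole potential decays with the effective motility).
    """
    rho = _check_rho(rho)
    s = params.sigma if sigma is None else sigma
    return 0.5 * s * params.scale * (1.0 + np.tanh((rho - params.rho_max) / params.cushion))


def crowding_potential_derivative(rho, params: ModelParameters, sigma: float | None = None):
    """dV_rho/drho = sigma*scale/(2*cushion) * sech^2((rho - rho_max)/cushion)."""
    rho = _check_rho(rho)
    s = params.sigma if sigma is None else sigma
    sech2 = 1.0 / np.cosh((rho - params.rho_max) / params.cushion) ** 2
    return 0.5 * s * params.scale / params.cushion * sech2


def total_potential(rho, U_a, U_r, params: ModelParameters,
                    motility: tuple[float, float, float] | None = None):
    """V = V_{U_a}(U_a) + V_{U_r}(U_r) + V_rho(rho).

    The repellent term is omitted when ``params.repellent_enabled`` is
    false.  ``motility`` optionally supplies slowdown-scaled
    (sigma, beta_a, beta_r).
    """
    sigma, beta_a, beta_r = motility if motility is not None else (
        params.sigma, params.beta_a, params.beta_r)
    V = signal_potential(U_a, params.alpha_a, beta_a)
    if params.repellent_enabled:
        if U_r is None:
            raise ValueError("repellent enabled but U_r is None")
        V = V + signal_potential(U_r, params.alpha_r, beta_r)
    V = V + crowding_potential(rho, params, sigma=sigma)
    return V


def uniform_steady_state(rho_bar: float, params: ModelParameters) -> tuple[float, float]:
    """Signal concentrations (U_a*, U_r*) in equilibrium with uniform density.

    U_i* = s_i * rho_bar / gamma_i.  With the default parameters s_i and
    gamma_i are numerically equal, so U_i* equals rho_bar numerically.
    """
    if rho_bar < 0:
        raise ValueError("rho_bar must be nonnegative")
    return params.s_a * rho_bar / params.gamma_a, params.s_r * rho_bar / params.gamma_r


def signal_range(D: float, gamma: float) -> float:
    """Mean distance a signal molecule diffuses before decaying, sqrt(D/gamma) in cm."""
    if D <= 0 or gamma <= 0:
        raise ValueError("D and gamma must be positive")
    return math.sqrt(D / gamma)
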