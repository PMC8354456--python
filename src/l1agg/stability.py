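"""Linear stability analysis of the uniform state.

Linearizing the coupled system about the uniform steady state
(rho_bar, U_i* = s_i rho_bar / gamma_i) and inserting a perturbation
proportional to exp(lambda t + i k.x) gives, per wavenumber k, a small
eigenvalue problem: one row for the worm density and one per signal.

Setting lambda = 0 in the chemical rows makes them static and yields the
exact marginal condition

    g(k, rho_bar) = sigma + rho_bar*V_rho'(rho_bar)
                    + rho_bar * sum_i V_i'(U_i*) * s_i / (gamma_i + D_i k^2)

with instability iff g < 0.  For the attractant-only model the unstable
band always reaches k -> 0, so aggregates coarsen without bound; adding a
longer-range repellent bounds the band away from zero, selecting a finite
pattern wavelength.  Wavenumbers are radians/cm throughout this module;
the spectral module reports cycles/cm (k_cyc = k / 2 pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import jn_zeros

from .model import (ModelParameters, crowding_potential_derivative,
                    signal_potential_derivative, uniform_steady_state)

__all__ = ["DispersionResult", "ThresholdResult", "marginal_condition",
           "growth_rates", "instability_threshold",
           "fastest_growing_wavenumber", "disk_mode_time_constant",
           "BelowThresholdError"]


class BelowThresholdError(ValueError):
    """No positive-growth mode exists at the requested mean density."""


@dataclass
class DispersionResult:
    rho_bar: float
    k: np.ndarray                  # radians/cm
    growth_rate: np.ndarray        # max real part of eigenvalues, 1/s
    repellent_enabled: bool

    @property
    def unstable(self) -> bool:
        return bool(np.any(self.growth_rate > 0))


@dataclass
class ThresholdResult:
    rho_bar_star: float            # threshold mean density, cm^-d
    k_c: float                     # critical wavenumber at threshold, radians/cm
    bracket: tuple[float, float]
    found: bool = True


def _signal_terms(rho_bar: float, params: ModelParameters):
    """Per-signal (Vprime at U*, gamma, D, s)."""
    U_star = uniform_steady_state(rho_bar, params)
    out = []
    for i, which in enumerate(params.signals):
        beta, alpha, gamma, D, s = params.signal_params(which)
        out.append((float(signal_potential_derivative(U_star[i], alpha, beta)),
                    gamma, D, s))
    return out


def marginal_condition(k, rho_bar: float, params: ModelParameters):
    """Quasi-static marginal stability function g(k, rho_bar), in cm^2/s.

    Negative g means the mode with wavenumber k grows.
    """
    if rho_bar <= 0:
        raise ValueError("rho_bar must be positive")
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("k must be nonnegative")
    g = params.sigma + rho_bar * float(
        crowding_potential_derivative(rho_bar, params))
    g = g + sum(rho_bar * vp * s / (gamma + D * k ** 2)
                for vp, gamma, D, s in _signal_terms(rho_bar, params))
    return g


def _linearization_matrix(k: float, rho_bar: float,
                          params: ModelParameters) -> np.ndarray:
    terms = _signal_terms(rho_bar, params)
    n = 1 + len(terms)
    A = np.zeros((n, n))
    k2 = k * k
    A[0, 0] = -k2 * (params.sigma + rho_bar * float(
        crowding_potential_derivative(rho_bar, params)))
    for j, (vp, gamma, D, s) in enumerate(terms, start=1):
        A[0, j] = -k2 * rho_bar * vp
        A[j, 0] = s
        A[j, j] = -(gamma + D * k2)
    return A


def growth_rates(k_array, rho_bar: float,
                 params: ModelParameters) -> DispersionResult:
    """Maximum real eigenvalue of the linearization at each wavenumber."""
    if rho_bar <= 0:
        raise ValueError("rho_bar must be positive")
    k_array = np.atleast_1d(np.asarray(k_array, dtype=float))
    if np.any(k_array < 0):
        raise ValueError("k must be nonnegative")
    rates = np.empty_like(k_array)
    for i, k in enumerate(k_array):
        A = _linearization_matrix(float(k), rho_bar, params)
        rates[i] = float(np.max(np.linalg.eigvals(A).real))
    return DispersionResult(rho_bar=rho_bar, k=k_array, growth_rate=rates,
                            repellent_enabled=params.repellent_enabled)


def _min_g_over_k(rho_bar: float, params: ModelParameters,
                  k_max: float = 1e4) -> tuple[float, float]:
    """(min_k g, argmin k) for k in [0, k_max]; g is monotone in each
    Lorentzian so a bounded scalar minimization suffices."""
    g0 = float(marginal_condition(0.0, rho_bar, params))
    res = minimize_scalar(
        lambda k: float(marginal_condition(k, rho_bar, params)),
        bounds=(0.0, k_max), method="bounded",
        options={"xatol": 1e-10 * k_max})
    if res.fun < g0:
        return float(res.fun), float(res.x)
    return g0, 0.0


def instability_threshold(params: ModelParameters,
                          rho_lo: float = 1.0, rho_hi: float = 1e6,
                          rtol: float = 1e-9) -> ThresholdResult:
    """Smallest mean density at which some wavenumber is marginally unstable.

    Bisection on rho_bar of F(rho) = min_k g(k, rho), with the bracket
    located by a geometric scan from rho_lo upward.
    """
    def F(rho: float) -> float:
        return _min_g_over_k(rho, params)[0]

    lo, f_lo = rho_lo, F(rho_lo)
    if f_lo <= 0:
        return ThresholdResult(rho_lo, _min_g_over_k(rho_lo, params)[1],
                               (rho_lo, rho_lo))
    hi = lo
    while hi < rho_hi:
        hi_next = hi * 1.5
        f_hi = F(hi_next)
        if f_hi <= 0:
            star = brentq(F, hi, hi_next, rtol=rtol)
            k_c = _min_g_over_k(star, params)[1]
            return ThresholdResult(float(star), float(k_c), (hi, hi_next))
        hi = hi_next
    return ThresholdResult(math.nan, math.nan, (rho_lo, rho_hi), found=False)


def fastest_growing_wavenumber(rho_bar: float, params: ModelParameters,
                               k_max: float = 1e3) -> float:
    """argmax over k of the growth rate, golden-section on the dispersion curve.

    Raises BelowThresholdError when no mode grows at this density.
    """
    def neg_rate(k: float) -> float:
        return -float(growth_rates([k], rho_bar, params).growth_rate[0])

    res = minimize_scalar(neg_rate, bounds=(1e-6, k_max), method="bounded",
                          options={"xatol": 1e-8 * k_max})
    if -res.fun <= 0:
        raise BelowThresholdError(
            f"no growing mode at rho_bar={rho_bar} (max rate {-res.fun:.3g}/s)")
    return float(res.x)


def disk_mode_time_constant(sigma: float, R: float, n: int = 1
                            ) -> tuple[float, float]:
    """Slowly decaying circularly symmetric Neumann diffusion mode on a disk.

    The radial eigenfunctions J0(k r) on a disk of radius R with a no-flux
    boundary require k = j_{1,n}/R with j_{1,n} the n-th nontrivial zero of
    J1.  Returns (k_n in radians/cm, time constant 1/(sigma k_n^2) in s).
    Used to calibrate sigma against the observed half-day spreading time of
    worms on a 3 cm radius plate.
    """
    if sigma <= 0 or R <= 0:
        raise ValueError("sigma and R must be positive")
    if n < 1:
        raise ValueError("mode index n must be >= 1")
    k_n = float(jn_zeros(1, n)[-1]) / R
    return k_n, 1.0 / (sigma * k_n ** 2)
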