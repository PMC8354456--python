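"""Fourth-order periodic finite-difference operators and PDE right-hand sides.

The worm equation drho/dt = div(rho*grad(V) + sigma*grad(rho)) is
discretized in flux form: the advective and diffusive fluxes are evaluated
at cell faces (4th-order face gradients and 4-point face interpolation of
rho) and differenced conservatively, so the discrete total worm number is
invariant to rounding.  The chemical equations use the pointwise 4th-order
Laplacian.
"""

from __future__ import annotations

import numpy as np

from .grid import FieldState, PeriodicGrid
from .model import (ModelParameters, SlowdownSchedule, effective_motility,
                    total_potential)

__all__ = [
    "gradient", "laplacian", "spatial_operators",
    "chemical_rhs", "worm_rhs", "full_rhs", "velocity_field",
    "discrete_laplacian_eigenvalues",
]


def _grad_axis(f: np.ndarray, axis: int, h: float) -> np.ndarray:
    """4th-order central first derivative along one axis, periodic."""
    fm2 = np.roll(f, 2, axis=axis)
    fm1 = np.roll(f, 1, axis=axis)
    fp1 = np.roll(f, -1, axis=axis)
    fp2 = np.roll(f, -2, axis=axis)
    # grouped as differences so constant fields give exactly zero
    return ((fm2 - fp2) - 8.0 * (fm1 - fp1)) / (12.0 * h)


def _lap_axis(f: np.ndarray, axis: int, h: float) -> np.ndarray:
    """4th-order central second derivative along one axis, periodic."""
    fm2 = np.roll(f, 2, axis=axis)
    fm1 = np.roll(f, 1, axis=axis)
    fp1 = np.roll(f, -1, axis=axis)
    fp2 = np.roll(f, -2, axis=axis)
    return (16.0 * ((fm1 - f) + (fp1 - f)) - ((fm2 - f) + (fp2 - f))) / (12.0 * h * h)


def gradient(f: np.ndarray, grid: PeriodicGrid) -> list[np.ndarray]:
    """Pointwise 4th-order gradient; one component array per axis."""
    grid.check_field(f)
    return [_grad_axis(f, ax, h) for ax, h in enumerate(grid.spacing)]


def laplacian(f: np.ndarray, grid: PeriodicGrid) -> np.ndarray:
    grid.check_field(f)
    out = _lap_axis(f, 0, grid.spacing[0])
    for ax in range(1, grid.dim):
        out += _lap_axis(f, ax, grid.spacing[ax])
    return out


def spatial_operators(f: np.ndarray, grid: PeriodicGrid):
    """(gradient components, laplacian) of a field."""
    return gradient(f, grid), laplacian(f, grid)


def _face_grad(f: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Conservative face gradient at i+1/2: (f[i-1]-15f[i]+15f[i+1]-f[i+2])/(12h).

    Chosen so that the conservative difference (G[i+1/2]-G[i-1/2])/h
    reproduces the 4th-order pointwise Laplacian stencil exactly; the face
    value itself carries a -h^2 f'''/24 deferred correction relative to
    the pointwise derivative.
    """
    fm1 = np.roll(f, 1, axis=axis)
    fp1 = np.roll(f, -1, axis=axis)
    fp2 = np.roll(f, -2, axis=axis)
    return ((fm1 - f) + 15.0 * (fp1 - f) - (fp2 - f)) / (12.0 * h)


def _face_interp(f: np.ndarray, axis: int) -> np.ndarray:
    """4-point interpolation to face i+1/2: (-f[i-1]+9f[i]+9f[i+1]-f[i+2])/16."""
    fm1 = np.roll(f, 1, axis=axis)
    fp1 = np.roll(f, -1, axis=axis)
    fp2 = np.roll(f, -2, axis=axis)
    return (-fm1 + 9.0 * f + 9.0 * fp1 - fp2) / 16.0


def _div_from_faces(flux: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Conservative difference of face values: (F[i+1/2] - F[i-1/2])/h."""
    return (flux - np.roll(flux, 1, axis=axis)) / h


def chemical_rhs(U: np.ndarray, rho: np.ndarray, gamma: float, D: float,
                 s: float, grid: PeriodicGrid) -> np.ndarray:
    """dU/dt = -gamma*U + D*lap(U) + s*rho."""
    grid.check_field(U)
    grid.check_field(rho)
    return -gamma * U + D * laplacian(U, grid) + s * rho


def worm_rhs(state: FieldState, params: ModelParameters, grid: PeriodicGrid,
             motility: tuple[float, float, float] | None = None) -> np.ndarray:
    """drho/dt = div(rho*grad(V) + sigma*grad(rho)) in conservative flux form."""
    rho = state.rho
    grid.check_field(rho)
    if np.any(rho <= 0):
        raise ValueError("worm_rhs requires strictly positive rho")
    sigma = motility[0] if motility is not None else params.sigma
    V = total_potential(rho, state.U_a, state.U_r, params, motility=motility)
    out = np.zeros_like(rho)
    for ax, h in enumerate(grid.spacing):
        flux = _face_interp(rho, ax) * _face_grad(V, ax, h) + sigma * _face_grad(rho, ax, h)
        out += _div_from_faces(flux, ax, h)
    return out


def full_rhs(state: FieldState, params: ModelParameters,
             schedule: SlowdownSchedule | None, grid: PeriodicGrid,
             t: float | None = None) -> list[np.ndarray]:
    """Time derivatives of all fields, ordered as state.fields()."""
    t = state.t if t is None else t
    motility = effective_motility(params, schedule, t)
    out = [worm_rhs(state, params, grid, motility=motility)]
    out.append(chemical_rhs(state.U_a, state.rho, params.gamma_a, params.D_a,
                            params.s_a, grid))
    if params.repellent_enabled:
        out.append(chemical_rhs(state.U_r, state.rho, params.gamma_r,
                                params.D_r, params.s_r, grid))
    return out


def velocity_field(state: FieldState, params: ModelParameters,
                   grid: PeriodicGrid,
                   motility: tuple[float, float, float] | None = None):
    """Mean worm velocity v = -grad(V) and its pointwise Euclidean norm."""
    V = total_potential(state.rho, state.U_a, state.U_r, params, motility=motility)
    comps = [-g for g in gradient(V, grid)]
    mag = np.sqrt(sum(c * c for c in comps))
    return comps, mag


def discrete_laplacian_eigenvalues(grid: PeriodicGrid) -> np.ndarray:
    """Eigenvalues of the 4th-order periodic Laplacian on the rfftn lattice.

    Returned array broadcasts over rfftn output of a real field; values are
    <= 0, equal to -k_d^2 where k_d is the discrete-operator wavenumber.
    """
    parts = []
    for ax, (n, h) in enumerate(zip(grid.shape, grid.spacing)):
        if ax == grid.dim - 1:
            m = np.arange(n // 2 + 1)
        else:
            m = np.fft.fftfreq(n, d=1.0 / n)
        theta = 2.0 * np.pi * m / n
        lam = (-2.0 * np.cos(2.0 * theta) + 32.0 * np.cos(theta) - 30.0) / (12.0 * h * h)
        shape = [1] * grid.dim
        shape[ax] = len(m)
        parts.append(lam.reshape(shape))
    out = parts[0]
    for p in parts[1:]:
        out = out + p
    return out
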