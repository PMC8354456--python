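"""Overdamped Langevin particle oracle.

The worm density PDE is the Fokker-Planck equation of the stochastic
process dX = -grad(V) dt + sqrt(2*sigma) dW, so an ensemble of
Euler-Maruyama particles coupled to the chemical grids is an independent
individual-based cross-check of the continuum solver: its empirical
density should agree in law with the PDE solution in the large-N limit,
and with frozen fields it relaxes to the Gibbs density exp(-V/sigma).

Particles deposit density onto the chemical grid with bilinear
cloud-in-cell weights (exactly mass conserving); the chemical fields are
advanced with the exact Fourier-space solution of their linear PDEs over
each particle step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import gradient
from .grid import FieldState, PeriodicGrid
from .model import (ModelParameters, SlowdownSchedule, effective_motility,
                    total_potential, uniform_steady_state)

__all__ = ["ParticleEnsemble", "simulate_particles", "deposit_density",
           "compare_density", "gibbs_density"]


@dataclass
class ParticleEnsemble:
    positions: np.ndarray            # (N, dim), unwrapped
    weight: float                    # worms represented per particle
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def wrapped(self, grid: PeriodicGrid) -> np.ndarray:
        return np.mod(self.positions, np.asarray(grid.extent))


def deposit_density(positions: np.ndarray, grid: PeriodicGrid,
                    weight: float = 1.0) -> np.ndarray:
    """Cloud-in-cell deposition of particle mass onto the grid, as density."""
    pos = np.mod(positions, np.asarray(grid.extent))
    rho = np.zeros(grid.shape)
    # fractional index of each particle relative to cell centers
    idx = [pos[:, ax] / grid.spacing[ax] - 0.5 for ax in range(grid.dim)]
    lo = [np.floor(i).astype(int) for i in idx]
    frac = [i - l for i, l in zip(idx, lo)]
    if grid.dim == 1:
        n0 = grid.shape[0]
        np.add.at(rho, lo[0] % n0, 1.0 - frac[0])
        np.add.at(rho, (lo[0] + 1) % n0, frac[0])
    else:
        n0, n1 = grid.shape
        for d0, w0 in ((0, 1.0 - frac[0]), (1, frac[0])):
            for d1, w1 in ((0, 1.0 - frac[1]), (1, frac[1])):
                np.add.at(rho, ((lo[0] + d0) % n0, (lo[1] + d1) % n1), w0 * w1)
    return rho * (weight / grid.cell_volume)


def _interpolate(field_comps: list[np.ndarray], positions: np.ndarray,
                 grid: PeriodicGrid) -> np.ndarray:
    """Bilinear interpolation of per-axis grid fields to particle positions."""
    pos = np.mod(positions, np.asarray(grid.extent))
    idx = [pos[:, ax] / grid.spacing[ax] - 0.5 for ax in range(grid.dim)]
    lo = [np.floor(i).astype(int) for i in idx]
    frac = [i - l for i, l in zip(idx, lo)]
    out = np.zeros_like(pos)
    if grid.dim == 1:
        n0 = grid.shape[0]
        for c, comp in enumerate(field_comps):
            out[:, c] = (comp[lo[0] % n0] * (1.0 - frac[0])
                         + comp[(lo[0] + 1) % n0] * frac[0])
    else:
        n0, n1 = grid.shape
        for c, comp in enumerate(field_comps):
            acc = np.zeros(pos.shape[0])
            for d0, w0 in ((0, 1.0 - frac[0]), (1, frac[0])):
                for d1, w1 in ((0, 1.0 - frac[1]), (1, frac[1])):
                    acc += comp[(lo[0] + d0) % n0, (lo[1] + d1) % n1] * w0 * w1
            out[:, c] = acc
    return out


def _chemical_update_exact(U_hat: np.ndarray, rho_hat: np.ndarray,
                           gamma: float, D: float, s: float,
                           lam: np.ndarray, dt: float) -> np.ndarray:
    """Exact Fourier solution of dU/dt = -gamma U + D lap U + s rho over dt
    with rho frozen (lam = spectral Laplacian eigenvalues <= 0)."""
    a = -gamma + D * lam
    decay = np.exp(a * dt)
    forced = np.where(a != 0, (decay - 1.0) / np.where(a == 0, 1.0, a), dt)
    return U_hat * decay + s * rho_hat * forced


def simulate_particles(N: int, params: ModelParameters, grid: PeriodicGrid,
                       t_end: float, dt: float, seed: int = 0,
                       rho_bar: float | None = None,
                       schedule: SlowdownSchedule | None = None,
                       frozen_potential: np.ndarray | None = None,
                       initial_positions: np.ndarray | None = None,
                       snapshot_times: list[float] | None = None,
                       ) -> tuple[ParticleEnsemble, np.ndarray, dict]:
    """Euler-Maruyama integration of N chemotactic particles.

    Each particle represents rho_bar*volume/N worms.  With
    ``frozen_potential`` set, the chemical fields are not evolved and the
    drift is computed from that fixed potential (Gibbs-relaxation mode).
    Returns (ensemble, final density histogram, info dict with
    trajectory snapshots and substepping diagnostics).
    """
    if N < 100:
        raise ValueError("need at least 100 particles")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    rho_bar = params.rho_bar if rho_bar is None else rho_bar
    volume = math.prod(grid.extent)
    weight = rho_bar * volume / N

    if initial_positions is not None:
        pos = np.array(initial_positions, dtype=float)
    else:
        pos = rng.uniform(0.0, 1.0, size=(N, grid.dim)) * np.asarray(grid.extent)

    from .dynamics import discrete_laplacian_eigenvalues
    lam = discrete_laplacian_eigenvalues(grid)

    if frozen_potential is None:
        Ua_star, Ur_star = uniform_steady_state(rho_bar, params)
        U_a = np.full(grid.shape, Ua_star)
        U_r = np.full(grid.shape, Ur_star) if params.repellent_enabled else None
        Ua_hat = np.fft.rfftn(U_a)
        Ur_hat = np.fft.rfftn(U_r) if U_r is not None else None

    snapshot_times = sorted(snapshot_times or [])
    snaps: list[tuple[float, np.ndarray]] = []
    n_substeps_total = 0
    min_dx = min(grid.spacing)

    t = 0.0
    n_steps = int(round(t_end / dt))
    for step in range(n_steps):
        sigma_eff, beta_a, beta_r = effective_motility(params, schedule, t)
        if frozen_potential is None:
            rho_grid = deposit_density(pos, grid, weight)
            rho_hat = np.fft.rfftn(rho_grid)
            Ua_hat = _chemical_update_exact(Ua_hat, rho_hat, params.gamma_a,
                                            params.D_a, params.s_a, lam, dt)
            U_a = np.fft.irfftn(Ua_hat, s=grid.shape, axes=tuple(range(grid.dim)))
            if Ur_hat is not None:
                Ur_hat = _chemical_update_exact(Ur_hat, rho_hat, params.gamma_r,
                                                params.D_r, params.s_r, lam, dt)
                U_r = np.fft.irfftn(Ur_hat, s=grid.shape, axes=tuple(range(grid.dim)))
            V = total_potential(np.maximum(rho_grid, 1e-12), U_a, U_r, params,
                                motility=(sigma_eff, beta_a, beta_r))
        else:
            V = frozen_potential
        force_comps = [-g for g in gradient(V, grid)]

        # velocity step cap: sub-step if drift would cross more than a cell
        F = _interpolate(force_comps, pos, grid)
        vmax = float(np.max(np.abs(F))) if F.size else 0.0
        n_sub = 1
        if vmax * dt > min_dx:
            n_sub = int(math.ceil(vmax * dt / min_dx))
            warnings.warn(f"dt exceeds velocity cap at t={t:.3g}; "
                          f"sub-stepping x{n_sub}", stacklevel=2)
        h = dt / n_sub
        for sub in range(n_sub):
            if sub > 0:
                F = _interpolate(force_comps, pos, grid)
            noise = rng.standard_normal(pos.shape)
            pos = pos + F * h + math.sqrt(2.0 * sigma_eff * h) * noise
        n_substeps_total += n_sub
        t += dt
        while snapshot_times and t >= snapshot_times[0] - 1e-9:
            snaps.append((snapshot_times.pop(0), pos.copy()))

    ensemble = ParticleEnsemble(positions=pos, weight=weight, seed=seed)
    hist = deposit_density(pos, grid, weight)
    info = {"snapshots": snaps, "n_substeps": n_substeps_total, "t": t}
    return ensemble, hist, info


def gibbs_density(V: np.ndarray, sigma: float, grid: PeriodicGrid,
                  total_mass: float = 1.0) -> np.ndarray:
    """Stationary density exp(-V/sigma), normalized to the given total mass."""
    w = np.exp(-(V - V.min()) / sigma)
    return w * (total_mass / grid.integrate(w))


def compare_density(histogram: np.ndarray, pde_rho: np.ndarray,
                    grid: PeriodicGrid, threshold: float | None = None) -> dict:
    """Side-by-side metrics for a particle histogram and a PDE density.

    Returns the normalized L1 distance integral(|a-b|)/integral((a+b)/2)
    and, when ``threshold`` is given, each field's dense-area fraction and
    aggregate count.
    """
    histogram = np.asarray(histogram, dtype=float)
    pde_rho = np.asarray(pde_rho, dtype=float)
    if histogram.shape != pde_rho.shape:
        raise ValueError("fields must share a grid coarsening")
    grid.check_field(histogram)
    mean_mass = 0.5 * (grid.integrate(histogram) + grid.integrate(pde_rho))
    l1 = grid.integrate(np.abs(histogram - pde_rho)) / mean_mass
    out = {"l1": float(l1)}
    if threshold is not None:
        from .diagnostics import aggregate_summary
        for name, f in (("particle", histogram), ("pde", pde_rho)):
            summ = aggregate_summary(f, grid, threshold)
            out[f"{name}_count"] = summ.count
            out[f"{name}_dense_fraction"] = summ.dense_area_fraction
    return out
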