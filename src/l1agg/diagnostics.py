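"""Scalar and field diagnostics: worm counts, worm-weighted means,
potential elasticity, sphere of influence, and aggregate morphology."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import PeriodicGrid

__all__ = ["AggregateSummary", "expected_count", "worm_weighted_mean",
           "sphere_of_influence", "potential_elasticity",
           "aggregate_summary"]


@dataclass
class AggregateSummary:
    count: int
    masses: np.ndarray                 # worms per aggregate
    areas: np.ndarray                  # cm^2 (or cm in 1D)
    centroids: np.ndarray              # periodic centroids, (count, dim)
    dense_area_fraction: float
    nn_spacing: np.ndarray             # nearest-neighbor centroid distances
    threshold: float


def expected_count(rho: np.ndarray, region_mask: np.ndarray,
                   grid: PeriodicGrid) -> float:
    """Expected number of worms in the masked region, integral of rho.

    Where the result is much less than one it reads as the probability of
    finding a single worm in the region.
    """
    grid.check_field(np.asarray(rho))
    grid.check_field(np.asarray(region_mask))
    return float(np.sum(np.asarray(rho) * np.asarray(region_mask, dtype=bool))
                 * grid.cell_volume)


def worm_weighted_mean(fieldvals: np.ndarray, rho: np.ndarray,
                       grid: PeriodicGrid) -> float:
    """Mass-weighted average of a field: integral(rho*f)/integral(rho).

    With f = rho this is the worm-weighted density, the density an average
    worm experiences — far above the plain mean once aggregates form.
    """
    grid.check_field(np.asarray(fieldvals))
    grid.check_field(np.asarray(rho))
    total = float(np.sum(rho))
    if total <= 0:
        raise ValueError("total mass must be positive")
    return float(np.sum(np.asarray(rho) * np.asarray(fieldvals)) / total)


def sphere_of_influence(rho_value: float, attractant_range_cm: float) -> float:
    """Worms within one attractant range of a point: rho * pi * r_a^2."""
    if rho_value < 0 or attractant_range_cm < 0:
        raise ValueError("inputs must be nonnegative")
    return rho_value * math.pi * attractant_range_cm ** 2


def potential_elasticity(U: float, alpha: float) -> float:
    """Relative sensitivity of the Weber-law potential at concentration U.

    E = U * V'(U) / (V(U) - V(0)) = U / ((alpha + U) * log(1 + U/alpha));
    the coupling strength beta cancels.  E lies in (0, 1) and tends to 1
    as U -> 0 (linear regime).
    """
    if U <= 0:
        raise ValueError("U must be positive")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return U / ((alpha + U) * math.log1p(U / alpha))


def _periodic_label(mask: np.ndarray, connectivity: int = 1) -> tuple[np.ndarray, int]:
    """Connected-component labeling with periodic wraparound.

    Labels with scipy.ndimage.label, then merges components that touch
    across opposite domain edges via union-find.
    """
    structure = ndimage.generate_binary_structure(mask.ndim, connectivity)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return labels, 0
    parent = list(range(n + 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for ax in range(mask.ndim):
        first = np.atleast_1d(np.take(labels, 0, axis=ax))
        last = np.atleast_1d(np.take(labels, -1, axis=ax))
        shifts = (0,) if connectivity == 1 or mask.ndim == 1 else (-1, 0, 1)
        for sh in shifts:
            rolled = np.roll(last, sh)
            both = (first > 0) & (rolled > 0)
            for a, b in zip(first[both], rolled[both]):
                union(int(a), int(b))

    remap = np.zeros(n + 1, dtype=int)
    next_id = 0
    for i in range(1, n + 1):
        r = find(i)
        if remap[r] == 0:
            next_id += 1
            remap[r] = next_id
        remap[i] = remap[r]
    return remap[labels], next_id


def _periodic_centroid(coords: np.ndarray, weights: np.ndarray,
                       extent: float) -> float:
    """Mass centroid of one coordinate on a circle (circular mean)."""
    theta = 2.0 * math.pi * coords / extent
    c = np.average(np.cos(theta), weights=weights)
    s = np.average(np.sin(theta), weights=weights)
    ang = math.atan2(s, c) % (2.0 * math.pi)
    return ang * extent / (2.0 * math.pi)


def _periodic_distance(a: np.ndarray, b: np.ndarray,
                       extent: tuple[float, ...]) -> float:
    d2 = 0.0
    for ai, bi, w in zip(a, b, extent):
        d = abs(ai - bi)
        d = min(d, w - d)
        d2 += d * d
    return math.sqrt(d2)


def aggregate_summary(rho: np.ndarray, grid: PeriodicGrid,
                      threshold: float, connectivity: int = 1
                      ) -> AggregateSummary:
    """Label dense aggregates (rho > threshold) on the periodic domain.

    The natural threshold is half the packing density rho_max/2, the
    midpoint of the crowding potential's rise.  An aggregate wrapping the
    periodic seam is counted once.
    """
    rho = np.asarray(rho, dtype=float)
    grid.check_field(rho)
    mask = rho > threshold
    labels, n = _periodic_label(mask, connectivity)
    masses = np.zeros(n)
    areas = np.zeros(n)
    centroids = np.zeros((n, grid.dim))
    mesh = grid.meshgrid()
    for i in range(1, n + 1):
        sel = labels == i
        masses[i - 1] = float(np.sum(rho[sel])) * grid.cell_volume
        areas[i - 1] = float(np.sum(sel)) * grid.cell_volume
        for ax in range(grid.dim):
            centroids[i - 1, ax] = _periodic_centroid(
                mesh[ax][sel], rho[sel], grid.extent[ax])
    dense_fraction = float(np.sum(mask)) / mask.size
    if n >= 2:
        nn = np.array([min(_periodic_distance(centroids[i], centroids[j],
                                              grid.extent)
                           for j in range(n) if j != i)
                       for i in range(n)])
    else:
        nn = np.zeros(0)
    return AggregateSummary(count=n, masses=masses, areas=areas,
                            centroids=centroids,
                            dense_area_fraction=dense_fraction,
                            nn_spacing=nn, threshold=threshold)
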