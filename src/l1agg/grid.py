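"""Uniform periodic grids and field states for the method of lines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PeriodicGrid", "FieldState"]


@dataclass(frozen=True)
class PeriodicGrid:
    """Uniform tensor grid on [0, w] (1D) or [0, w] x [0, h] (2D).

    Cell centers sit at (i + 1/2) * spacing; index n wraps to 0.  Array
    axis 0 is x and axis 1 is y.
    """

    extent: tuple[float, ...]        # domain size per axis, cm
    shape: tuple[int, ...]           # points per axis

    def __post_init__(self) -> None:
        if len(self.extent) != len(self.shape):
            raise ValueError("extent and shape must have the same length")
        if len(self.shape) not in (1, 2):
            raise ValueError("only 1D and 2D grids are supported")
        if any(n < 8 for n in self.shape):
            raise ValueError("at least 8 points per axis are required")
        if any(w <= 0 for w in self.extent):
            raise ValueError("extents must be positive")

    @classmethod
    def line(cls, w: float = 1.0, n: int = 1024) -> "PeriodicGrid":
        return cls(extent=(w,), shape=(n,))

    @classmethod
    def square(cls, w: float = 1.0, n: int = 128) -> "PeriodicGrid":
        return cls(extent=(w, w), shape=(n, n))

    @property
    def dim(self) -> int:
        return len(self.shape)

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(w / n for w, n in zip(self.extent, self.shape))

    @property
    def cell_volume(self) -> float:
        v = 1.0
        for h in self.spacing:
            v *= h
        return v

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def axes(self) -> tuple[np.ndarray, ...]:
        """Cell-center coordinate arrays per axis."""
        return tuple((np.arange(n) + 0.5) * h
                     for n, h in zip(self.shape, self.spacing))

    def meshgrid(self) -> tuple[np.ndarray, ...]:
        return tuple(np.meshgrid(*self.axes(), indexing="ij"))

    def check_field(self, f: np.ndarray) -> None:
        if np.shape(f) != self.shape:
            raise ValueError(f"field shape {np.shape(f)} does not match grid {self.shape}")

    def integrate(self, f: np.ndarray) -> float:
        """Cell-volume weighted sum (discrete integral over the domain)."""
        self.check_field(np.asarray(f))
        return float(np.sum(f) * self.cell_volume)


@dataclass
class FieldState:
    """Worm density and signal concentrations on a grid at time t."""

    t: float
    rho: np.ndarray
    U_a: np.ndarray
    U_r: np.ndarray | None = None

    def fields(self) -> list[np.ndarray]:
        out = [self.rho, self.U_a]
        if self.U_r is not None:
            out.append(self.U_r)
        return out

    def copy(self) -> "FieldState":
        return FieldState(self.t, self.rho.copy(), self.U_a.copy(),
                          None if self.U_r is None else self.U_r.copy())

    def validate(self, grid: PeriodicGrid) -> None:
        for f in self.fields():
            grid.check_field(f)
        if not np.all(self.rho > 0):
            raise ValueError("rho must be positive everywhere")
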