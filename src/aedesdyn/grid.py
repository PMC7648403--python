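"""Cell-centered uniform grid and the three state fields."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "FieldSet"]


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centered rectangular grid.

    The origin is the lower-left corner of the domain; x increases with the
    column index and y with the row index.  Cells are square (dx == dy),
    matching the uniform finite-volume discretization.  Arrays defined on
    the grid have shape ``(ny, nx)``.
    """

    nx: int
    ny: int
    dx: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError(f"grid needs nx, ny >= 3, got {self.nx} x {self.ny}")
        if self.dx <= 0:
            raise ValueError(f"cell size must be positive, got {self.dx}")

    @property
    def dy(self) -> float:
        return self.dx

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area(self) -> float:
        return self.dx * self.dx

    @property
    def extent(self) -> tuple[float, float]:
        """Domain size (Lx, Ly) in meters."""
        return (self.nx * self.dx, self.ny * self.dx)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinate arrays (X, Y), each of shape (ny, nx)."""
        x0, y0 = self.origin
        x = x0 + (np.arange(self.nx) + 0.5) * self.dx
        y = y0 + (np.arange(self.ny) + 0.5) * self.dx
        return np.meshgrid(x, y)

    def center(self) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + self.nx * self.dx / 2.0, y0 + self.ny * self.dx / 2.0)

    def nearest_cell(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell whose center is nearest to (x, y)."""
        x0, y0 = self.origin
        col = int(np.clip(np.floor((x - x0) / self.dx), 0, self.nx - 1))
        row = int(np.clip(np.floor((y - y0) / self.dx), 0, self.ny - 1))
        return (row, col)

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape)

    def full(self, value: float) -> np.ndarray:
        return np.full(self.shape, float(value))


@dataclass
class FieldSet:
    """Per-cell densities of the mobile (M), egg (E) and aquatic (A) phases."""

    grid: Grid
    M: np.ndarray
    E: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        for name in ("M", "E", "A"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"field {name} has shape {arr.shape}, expected {self.grid.shape}"
                )
            setattr(self, name, arr)

    @classmethod
    def uniform(cls, grid: Grid, M: float = 0.0, E: float = 0.0, A: float = 0.0) -> "FieldSet":
        return cls(grid, grid.full(M), grid.full(E), grid.full(A))

    def copy(self) -> "FieldSet":
        return FieldSet(self.grid, self.M.copy(), self.E.copy(), self.A.copy())

    def totals(self) -> tuple[float, float, float]:
        """Domain-integrated populations (counts) of each phase."""
        a = self.grid.cell_area
        return (float(self.M.sum() * a), float(self.E.sum() * a), float(self.A.sum() * a))

    def check_box_constraints(self, k, tol: float = 0.0) -> None:
        """Raise if M < 0, E < 0, A < 0 or A > k beyond tolerance ``tol``.

        ``k`` may be a scalar or a per-cell array.
        """
        k = np.asarray(k, dtype=float)
        if self.M.min() < -tol:
            raise ValueError(f"M has negative values (min {self.M.min():.3e})")
        if self.E.min() < -tol:
            raise ValueError(f"E has negative values (min {self.E.min():.3e})")
        if self.A.min() < -tol:
            raise ValueError(f"A has negative values (min {self.A.min():.3e})")
        excess = float((self.A - k).max())
        if excess > tol:
            raise ValueError(f"A exceeds carrying capacity by {excess:.3e}")
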