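"""Synthetic urban scenario generation.

Builds raster masks of a regular city layout (square house blocks separated
by streets, optionally with larger merged blocks in the center), the spray
mask (streets dilated by a ring of cells, since sprayed insecticide drifts
slightly into the block edges), and the street/house coefficient fields.

Streets are the favourable corridor for adult movement, so the default
heterogeneous scenario halves both the diffusion coefficient and the
mortality rates inside house blocks relative to the street values.  The
matched homogeneous scenario replaces every two-valued coefficient by its
area-weighted mean, which preserves the domain-average diffusion and
mortality and lets the well-mixed equilibrium theory apply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .fvm import CoefficientFields
from .grid import Grid
from .kernel import ReleaseSpec, annulus_expected_counts
from .params import AnnulusData, ParameterSet, SpraySchedule

__all__ = [
    "BlockLayout",
    "MaskSet",
    "make_block_grid",
    "make_spray_mask",
    "assemble_heterogeneous",
    "homogenize",
    "implied_street_fraction",
    "schedule_from_frequency",
    "synth_trap_counts",
    "SPRAY_FREQUENCIES",
]


@dataclass(frozen=True)
class BlockLayout:
    """Periodic lattice of square house blocks separated by streets.

    Each period cell is ``block_size + street_width`` on a side: a square
    block with a street strip along its east and north edges.  Optional
    ``big_block_positions`` (block indices ``(bx, by)``) merge a block with
    its east/north neighbours into a 2x2 super-block by filling in the
    streets between them.
    """

    block_size: float = 50.0
    street_width: float = 10.0
    n_blocks_x: int = 5
    n_blocks_y: int = 5
    big_block_positions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.block_size <= 0:
            raise ValueError("block_size must be positive")
        if self.street_width < 0:
            raise ValueError("street_width must be nonnegative")
        if self.n_blocks_x < 1 or self.n_blocks_y < 1:
            raise ValueError("need at least one block in each direction")

    @property
    def pitch(self) -> float:
        return self.block_size + self.street_width

    @property
    def street_fraction(self) -> float:
        """Street-area fraction of the uniform lattice (no big blocks)."""
        return 1.0 - (self.block_size / self.pitch) ** 2


@dataclass
class MaskSet:
    """Boolean rasters partitioning the domain into streets and house blocks."""

    grid: Grid
    street_mask: np.ndarray
    house_mask: np.ndarray
    spray_mask: np.ndarray

    def __post_init__(self) -> None:
        for name in ("street_mask", "house_mask", "spray_mask"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
            setattr(self, name, arr)
        if np.any(self.street_mask & self.house_mask):
            raise ValueError("street and house masks overlap")
        if not np.all(self.street_mask | self.house_mask):
            raise ValueError("street and house masks do not cover the domain")
        if np.any(self.street_mask & ~self.spray_mask):
            raise ValueError("spray mask must contain all street cells")

    @property
    def street_fraction(self) -> float:
        return float(self.street_mask.mean())


def make_block_grid(
    layout: BlockLayout, dx: float, spray_dilation_cells: int = 1
) -> tuple[Grid, MaskSet]:
    """Rasterize a block layout; returns the grid and street/house/spray masks.

    ``dx`` must divide both the block size and the street width so cell
    centers classify unambiguously.
    """
    for name, value in (("block_size", layout.block_size), ("street_width", layout.street_width)):
        ratio = value / dx
        if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
            raise ValueError(f"dx = {dx} does not divide {name} = {value}")
    pitch = layout.pitch
    nx = int(round(layout.n_blocks_x * pitch / dx))
    ny = int(round(layout.n_blocks_y * pitch / dx))
    grid = Grid(nx=nx, ny=ny, dx=dx)

    X, Y = grid.cell_centers()
    u = np.mod(X, pitch)
    v = np.mod(Y, pitch)
    street = (u > layout.block_size) | (v > layout.block_size)

    # merge 2x2 neighbourhoods into big blocks by filling the interior streets
    for bx, by in layout.big_block_positions:
        if not (0 <= bx < layout.n_blocks_x - 1 and 0 <= by < layout.n_blocks_y - 1):
            raise ValueError(
                f"big block at {(bx, by)} has no east/north neighbour to merge with"
            )
        x_lo, x_hi = bx * pitch, (bx + 1) * pitch + layout.block_size
        y_lo, y_hi = by * pitch, (by + 1) * pitch + layout.block_size
        inside = (X > x_lo) & (X < x_hi) & (Y > y_lo) & (Y < y_hi)
        street &= ~inside

    house = ~street
    spray = make_spray_mask(street, spray_dilation_cells)
    return grid, MaskSet(grid, street, house, spray)


def make_spray_mask(street_mask: np.ndarray, dilation_cells: int) -> np.ndarray:
    """Dilate the street mask by ``dilation_cells`` rings of cells (8-connected).

    Models the drift of the sprayed aerosol slightly into the house blocks.
    """
    street_mask = np.asarray(street_mask, dtype=bool)
    if dilation_cells < 0:
        raise ValueError("dilation_cells must be nonnegative")
    if dilation_cells == 0:
        return street_mask.copy()
    structure = np.ones((3, 3), dtype=bool)
    return ndimage.binary_dilation(
        street_mask, structure=structure, iterations=dilation_cells
    )


def assemble_heterogeneous(
    masks: MaskSet,
    street_params: ParameterSet,
    house_factor: float = 0.5,
    schedule: SpraySchedule | None = None,
) -> CoefficientFields:
    """Build per-cell coefficient fields from street values and a house factor.

    Street cells carry the street values of D, mu1 and mu2; house cells get
    ``house_factor`` times those values (default one half).  gamma, r, e and
    k are uniform.  The insecticide increment (from ``schedule.rate`` if
    given, else ``street_params.mu1_insecticide``) applies on the spray mask
    only — pulverized insecticide cannot reach the block interiors.
    """
    if not 0 < house_factor <= 1:
        raise ValueError(f"house_factor must lie in (0, 1], got {house_factor}")
    grid = masks.grid
    scale = np.where(masks.street_mask, 1.0, house_factor)
    rate = schedule.rate if schedule is not None else street_params.mu1_insecticide
    return CoefficientFields(
        grid=grid,
        D=street_params.D * scale,
        mu1_base=street_params.mu1_base * scale,
        mu2=street_params.mu2 * scale,
        gamma=street_params.gamma,
        r=street_params.r,
        e=street_params.e,
        k=street_params.k,
        mu1_insecticide=rate * masks.spray_mask.astype(float),
    )


def homogenize(masks: MaskSet, coeffs: CoefficientFields) -> ParameterSet:
    """Area-weighted average of the coefficient fields -> homogeneous ParameterSet.

    Preserves the domain-average diffusion and mortality of the heterogeneous
    scenario, enabling a like-for-like comparison with the well-mixed theory.
    """

    def avg(v) -> float:
        arr = np.asarray(v, dtype=float)
        return float(arr) if arr.ndim == 0 else float(arr.mean())

    return ParameterSet(
        D=avg(coeffs.D),
        gamma=avg(coeffs.gamma),
        mu1_base=avg(coeffs.mu1_base),
        mu2=avg(coeffs.mu2),
        r=avg(coeffs.r),
        e=avg(coeffs.e),
        k=avg(coeffs.k),
        mu1_insecticide=avg(coeffs.mu1_insecticide),
    )


def implied_street_fraction(house_value: float, street_value: float, mixed_value: float) -> float:
    """Street-area weight w solving w*street + (1-w)*house = mixed.

    Recovers the areal weighting used in a published street/house/average
    coefficient triple, e.g. from a diffusion-coefficient row.
    """
    if street_value == house_value:
        raise ValueError("street and house values are equal; weight is undetermined")
    w = (mixed_value - house_value) / (street_value - house_value)
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"implied weight {w:.4f} falls outside [0, 1]")
    return w


#: Pulse mortality rates (1/day) during a 30-minute window, per application
#: frequency.  The rates scale with the period so the total insecticide dose
#: over any 14-day horizon is the same for every strategy; the daily value is
#: conventionally quoted as 6.86 (exact equal dose would be 48/7 = 6.857...).
SPRAY_FREQUENCIES: dict[str, tuple[float, float]] = {
    "daily": (1.0, 6.86),
    "twice_weekly": (3.5, 24.0),
    "weekly": (7.0, 48.0),
    "biweekly": (14.0, 96.0),
}


def schedule_from_frequency(
    frequency: str,
    start_time: float = 0.0,
    exact_dose: bool = False,
) -> SpraySchedule:
    """Standard pulsed-application schedule for a named frequency.

    All frequencies use a 30-minute window.  ``exact_dose=True`` replaces the
    conventional daily rate 6.86 by the exactly dose-matched 48/7.
    """
    if frequency not in SPRAY_FREQUENCIES:
        raise ValueError(
            f"unknown frequency {frequency!r}; expected one of {sorted(SPRAY_FREQUENCIES)}"
        )
    period, rate = SPRAY_FREQUENCIES[frequency]
    if exact_dose and frequency == "daily":
        rate = 48.0 / 7.0
    return SpraySchedule(period=period, rate=rate, window=0.5 / 24.0, start_time=start_time)


def synth_trap_counts(
    true_params: tuple[float, float, float],
    release: ReleaseSpec,
    annuli: AnnulusData | None = None,
    poisson: bool = False,
    seed: int | None = None,
) -> AnnulusData:
    """Synthetic ring counts from known (D, mu, alpha).

    Noise-free mode returns the expected counts exactly; Poisson mode draws
    integer counts with those means (ovitrap egg-batch detections are
    counting data), deterministically for a given seed.
    """
    D, mu, alpha = true_params
    if annuli is None:
        annuli = AnnulusData()
    expected = annulus_expected_counts(release, D, mu, alpha, annuli)
    if poisson:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return AnnulusData(edges=annuli.edges, counts=counts, weights=annuli.weights)
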