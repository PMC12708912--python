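"""Regular analysis grid: cell geometry, point location, presence matrix.

Coordinates are planar (km). Cells are half-open rectangles, closed on
their lower/left edges, so a point on a shared edge belongs to exactly
one cell. Cell ids are row-major from the lower-left corner:
``cell_id = row * n_cols + col`` with row 0 the southernmost row.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel cell id for points outside the grid.
OUTSIDE = -1


@dataclass(frozen=True)
class GridSpec:
    """A regular grid of square cells over a planar extent.

    Attributes
    ----------
    x0, y0
        Lower-left corner of the grid (km).
    cell_size
        Cell edge length (km).
    n_cols, n_rows
        Grid dimensions.
    """

    x0: float
    y0: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of one cell; the rectangle is half-open."""
        row, col = divmod(cell_id, self.n_cols)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"cell id {cell_id} out of range")
        s = self.cell_size
        return (
            self.x0 + col * s,
            self.y0 + row * s,
            self.x0 + (col + 1) * s,
            self.y0 + (row + 1) * s,
        )

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center coordinates, in cell-id order."""
        cols = np.arange(self.n_cells) % self.n_cols
        rows = np.arange(self.n_cells) // self.n_cols
        s = self.cell_size
        return np.column_stack(
            [self.x0 + (cols + 0.5) * s, self.y0 + (rows + 0.5) * s]
        )


def build_grid(
    extent: tuple[float, float, float, float], cell_size: float
) -> GridSpec:
    """Build the grid covering an extent (xmin, ymin, xmax, ymax).

    The number of columns/rows is the ceiling of extent width/height over
    ``cell_size``, so the grid may overhang the extent on the top/right.
    """
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent is empty")
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    n_cols = math.ceil((xmax - xmin) / cell_size)
    n_rows = math.ceil((ymax - ymin) / cell_size)
    return GridSpec(xmin, ymin, cell_size, n_cols, n_rows)


def locate(x: float, y: float, grid: GridSpec) -> int:
    """Cell id containing a point, or :data:`OUTSIDE`.

    Uses ``floor((coord - origin) / cell_size)``; points on a shared edge
    fall in the cell whose lower/left edge they lie on.
    """
    col = _axis_index(x, grid.x0, grid.cell_size)
    row = _axis_index(y, grid.y0, grid.cell_size)
    if 0 <= col < grid.n_cols and 0 <= row < grid.n_rows:
        return row * grid.n_cols + col
    return OUTSIDE


def _axis_index(coord: float, origin: float, size: float) -> int:
    idx = math.floor((coord - origin) / size)
    # the division can land one cell off at representation edges (e.g.
    # a denormal negative offset underflows to -0.0); re-check against
    # the half-open bounds so locate always agrees with cell_bounds
    if coord < origin + idx * size:
        idx -= 1
    elif coord >= origin + (idx + 1) * size:
        idx += 1
    return idx


def locate_many(xs, ys, grid: GridSpec) -> np.ndarray:
    """Vectorised :func:`locate` for coordinate arrays."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    cols = np.floor((xs - grid.x0) / grid.cell_size).astype(np.int64)
    rows = np.floor((ys - grid.y0) / grid.cell_size).astype(np.int64)
    s = grid.cell_size
    cols -= (xs < grid.x0 + cols * s).astype(np.int64)
    cols += (xs >= grid.x0 + (cols + 1) * s).astype(np.int64)
    rows -= (ys < grid.y0 + rows * s).astype(np.int64)
    rows += (ys >= grid.y0 + (rows + 1) * s).astype(np.int64)
    inside = (
        (cols >= 0) & (cols < grid.n_cols) & (rows >= 0) & (rows < grid.n_rows)
    )
    return np.where(inside, rows * grid.n_cols + cols, OUTSIDE)


@dataclass
class PresenceMatrix:
    """Boolean cells x species occupancy on a grid.

    ``occupancy[c, s]`` is True iff at least one record of species
    ``species[s]`` falls in cell ``c``. Cell order is the grid's row-major
    id order; species order is the (stable) order of first appearance in
    the checklist or occurrence input.
    """

    grid: GridSpec
    species: list[str]
    occupancy: np.ndarray  # (n_cells, n_species) bool

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != (self.grid.n_cells, len(self.species)):
            raise ValueError("occupancy shape does not match grid/species")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, species_ids=None) -> np.ndarray:
        """Column indices of the given species ids (all if None)."""
        if species_ids is None:
            return np.arange(self.n_species)
        pos = {s: i for i, s in enumerate(self.species)}
        try:
            return np.array([pos[s] for s in species_ids], dtype=np.int64)
        except KeyError as err:
            raise KeyError(f"species {err.args[0]!r} not in matrix") from err


def build_presence(
    occurrences: pd.DataFrame, grid: GridSpec, species_order=None
) -> PresenceMatrix:
    """Rasterise occurrence records (species_id, x, y) to a presence matrix.

    Records outside the grid are dropped and their count logged. Extra
    columns in the input are ignored. ``species_order`` fixes the column
    order (e.g. the checklist order) and forces a column for species with
    no in-grid record; by default columns follow first appearance.
    """
    if species_order is not None:
        species = list(species_order)
    else:
        species = list(dict.fromkeys(occurrences["species_id"]))
    n_cells = grid.n_cells
    occ = np.zeros((n_cells, len(species)), dtype=bool)
    if len(occurrences) == 0:
        logger.warning("empty occurrence set: presence matrix is all-false")
        return PresenceMatrix(grid, species, occ)
    cells = locate_many(
        occurrences["x"].to_numpy(), occurrences["y"].to_numpy(), grid
    )
    dropped = int((cells == OUTSIDE).sum())
    if dropped:
        logger.info("dropped %d occurrence records outside the grid", dropped)
    pos = {s: i for i, s in enumerate(species)}
    col = occurrences["species_id"].map(pos).to_numpy()
    keep = cells != OUTSIDE
    occ[cells[keep], col[keep]] = True
    return PresenceMatrix(grid, species, occ)


def range_sizes(pm: PresenceMatrix) -> pd.Series:
    """Occupied-cell count per species (the weighted-endemism denominator)."""
    return pd.Series(
        pm.occupancy.sum(axis=0), index=pd.Index(pm.species, name="species_id"),
        name="range_size",
    )


def occupied_cells(pm: PresenceMatrix) -> np.ndarray:
    """Sorted ids of cells holding at least one species."""
    return np.flatnonzero(pm.occupancy.any(axis=1))
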