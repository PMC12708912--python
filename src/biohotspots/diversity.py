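"""Per-cell diversity surfaces: richness, complementarity, weighted endemism.

Each surface assigns one non-negative scalar per grid cell for one species
subset. Richness counts species; weighted endemism (range-size rarity)
sums 1/range_size over the species present in a cell, so every species
contributes total weight 1 across its range; complementarity records, for
each cell picked by the greedy set-cover heuristic, how many species that
pick newly covered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .checklist import subset_species
from .grid import GridSpec, PresenceMatrix

METRICS = ("richness", "complementarity", "weighted_endemism")

#: Pearson |r| bands: label -> half-open interval [lo, hi). The top band
#: is closed at 1 and r == 0 gets the label "none"; the published scale
#: starts strictly above 0 and stops strictly below 1, so both edges need
#: a documented assignment.
CORRELATION_BANDS = (
    ("negligible", 0.0, 0.1),
    ("weak", 0.1, 0.4),
    ("moderate", 0.4, 0.7),
    ("strong", 0.7, 0.9),
    ("very_strong", 0.9, 1.0),
)


@dataclass
class DiversitySurface:
    """One metric evaluated for one species subset on one grid."""

    metric: str
    subset: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("surface values must be finite and >= 0")


@dataclass
class ComplementaritySelection:
    """Greedy set-cover trace: (cell_id, newly covered species count)."""

    subset: str
    steps: list[tuple[int, int]]

    @property
    def cells(self) -> list[int]:
        return [c for c, _ in self.steps]

    @property
    def total_covered(self) -> int:
        return sum(g for _, g in self.steps)


def _subset_columns(pm: PresenceMatrix, checklist, subset: str) -> np.ndarray:
    ids = subset_species(checklist, subset)
    ids = [s for s in ids if s in set(pm.species)]
    return pm.species_index(ids)


def richness_surface(
    pm: PresenceMatrix, checklist, subset: str = "all"
) -> DiversitySurface:
    """Number of subset species present in each cell."""
    cols = _subset_columns(pm, checklist, subset)
    values = pm.occupancy[:, cols].sum(axis=1).astype(float)
    return DiversitySurface("richness", subset, values)


def complementarity_selection(
    pm: PresenceMatrix, checklist, subset: str = "all"
) -> ComplementaritySelection:
    """Greedy set cover over cells for one species subset.

    Iteratively selects the cell covering the most not-yet-covered subset
    species until every subset species with at least one occupied cell is
    covered. Ties are broken by the lowest cell id, which makes the trace
    deterministic.
    """
    cols = _subset_columns(pm, checklist, subset)
    occ = pm.occupancy[:, cols]
    uncovered = occ.any(axis=0)  # species with >=1 occupied cell
    steps: list[tuple[int, int]] = []
    while uncovered.any():
        gains = occ[:, uncovered].sum(axis=1)
        cell = int(np.argmax(gains))  # argmax returns the lowest index on ties
        gain = int(gains[cell])
        steps.append((cell, gain))
        uncovered &= ~occ[cell]
    return ComplementaritySelection(subset, steps)


def complementarity_surface(
    sel: ComplementaritySelection, grid: GridSpec
) -> DiversitySurface:
    """Per-cell gain-at-selection surface (0 for unselected cells)."""
    values = np.zeros(grid.n_cells)
    for cell, gain in sel.steps:
        values[cell] = gain
    return DiversitySurface("complementarity", sel.subset, values)


def weighted_endemism_surface(
    pm: PresenceMatrix, checklist, subset: str = "all"
) -> DiversitySurface:
    """Range-size rarity: per cell, sum of 1/range_size over present species."""
    cols = _subset_columns(pm, checklist, subset)
    occ = pm.occupancy[:, cols]
    ranges = occ.sum(axis=0).astype(float)
    weights = np.zeros_like(ranges)
    present = ranges > 0  # zero-range species carry no weight anywhere
    weights[present] = 1.0 / ranges[present]
    values = occ @ weights
    return DiversitySurface("weighted_endemism", subset, values)


def correlate_surfaces(a, b) -> tuple[float, float]:
    """Pearson r and two-sided p between two surfaces (t-dist, n-2 df)."""
    va = a.values if isinstance(a, DiversitySurface) else np.asarray(a, float)
    vb = b.values if isinstance(b, DiversitySurface) else np.asarray(b, float)
    if va.shape != vb.shape:
        raise ValueError("surfaces have different lengths")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("correlation undefined for a constant surface")
    r, p = stats.pearsonr(va, vb)
    return float(r), float(p)


def classify_correlation(r: float) -> str:
    """Verbal strength band for a Pearson correlation coefficient."""
    a = abs(r)
    if a > 1:
        raise ValueError(f"|r| = {a} > 1")
    if a == 0:
        return "none"
    if a == 1:
        return "very_strong"
    for label, lo, hi in CORRELATION_BANDS:
        if lo <= a < hi:
            return label
    raise AssertionError("unreachable")  # pragma: no cover
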