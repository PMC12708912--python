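"""Hotspot selection: composite scores, top-k% cells, consensus classes.

For each of the three diversity algorithms, the surfaces for the all /
endemic / threatened species subsets are min-max standardized to [0, 1]
and summed into a composite score in [0, 3]. Cells in the top k% of the
composite (among occupied cells) form that algorithm's hotspot set; a
score tie at the k% boundary pulls every tying cell in, so the returned
set can slightly exceed the nominal count. The union of the three sets is
the hotspot set at that threshold; cells picked by 3 / 2 / 1 algorithms
are Class I / II / III, and cells are priority-ordered by the sum of
their dense composite ranks across the three algorithms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import (
    DiversitySurface,
    complementarity_selection,
    complementarity_surface,
    richness_surface,
    weighted_endemism_surface,
)
from .grid import PresenceMatrix, occupied_cells

logger = logging.getLogger(__name__)

#: Thresholds used in the headline analysis: 5%, 10%, 17% (Aichi),
#: 30% (post-2020 framework). Any fraction in (0, 1] is accepted.
DEFAULT_FRACTIONS = (0.05, 0.10, 0.17, 0.30)

ALGORITHMS = ("richness", "complementarity", "weighted_endemism")


@dataclass
class CompositeScore:
    """Sum of three standardized subset surfaces for one algorithm."""

    algorithm: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-9) or np.any(self.values > 3 + 1e-9):
            raise ValueError("composite score must lie in [0, 3]")


@dataclass
class HotspotSet:
    """Hotspot cells at one threshold with consensus classes and priority."""

    threshold: float
    cells: set[int]
    classes: dict[int, str]  # cell -> "I" | "II" | "III"
    priority: list[int]  # cells ordered by ascending rank sum
    per_algorithm: dict[str, set[int]] = field(default_factory=dict)

    def class_cells(self, cls: str) -> set[int]:
        return {c for c, k in self.classes.items() if k == cls}


def minmax_standardize(values: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] by (v - min) / (max - min); constant input -> zeros."""
    v = np.asarray(values, dtype=float)
    span = np.ptp(v)
    if span == 0:
        return np.zeros_like(v)
    return (v - v.min()) / span


def zscore_standardize(values: np.ndarray) -> np.ndarray:
    """Alternative standardization; constant input -> zeros."""
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def composite_score(
    all_s: DiversitySurface,
    endemic_s: DiversitySurface,
    threatened_s: DiversitySurface,
    standardize=minmax_standardize,
) -> CompositeScore:
    """Cellwise sum of the three standardized subset surfaces."""
    surfaces = (all_s, endemic_s, threatened_s)
    algorithms = {s.metric for s in surfaces}
    if len(algorithms) != 1:
        raise ValueError("surfaces mix algorithms")
    lengths = {len(s.values) for s in surfaces}
    if len(lengths) != 1:
        raise ValueError("surfaces on mismatched grids")
    total = sum(standardize(s.values) for s in surfaces)
    if standardize is not minmax_standardize:
        # z-scored composites are unbounded; bypass the [0, 3] check
        cs = CompositeScore.__new__(CompositeScore)
        cs.algorithm = algorithms.pop()
        cs.values = np.asarray(total, dtype=float)
        return cs
    return CompositeScore(algorithms.pop(), total)


def top_fraction(
    score: CompositeScore | np.ndarray, fraction: float, base_cells
) -> set[int]:
    """Cells in the top ``fraction`` of the score over ``base_cells``.

    The nominal count is ``round(fraction * |base_cells|)`` (half up);
    every cell tying the boundary score is also included, which is how a
    nominal 280 can return 281 cells.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    values = score.values if isinstance(score, CompositeScore) else np.asarray(score, float)
    base = np.asarray(sorted(base_cells), dtype=np.int64)
    if base.size == 0:
        return set()
    m = int(np.floor(fraction * base.size + 0.5))
    if m == 0:
        return set()
    sub = values[base]
    order = np.lexsort((base, -sub))  # score desc, cell id asc
    boundary = sub[order[m - 1]]
    if m < base.size and np.count_nonzero(sub == boundary) > 1:
        selected = base[order[:m]].tolist()
        ties = base[(sub == boundary)].tolist()
        return set(selected) | set(ties)
    return set(base[order[:m]].tolist())


def consensus_classes(
    set_r: set[int], set_c: set[int], set_w: set[int]
) -> dict[int, str]:
    """Map each cell in the union to I/II/III by algorithm agreement count."""
    label = {3: "I", 2: "II", 1: "III"}
    classes: dict[int, str] = {}
    for cell in set_r | set_c | set_w:
        n = (cell in set_r) + (cell in set_c) + (cell in set_w)
        classes[cell] = label[n]
    return classes


def dense_ranks(score: CompositeScore | np.ndarray, base_cells) -> dict[int, int]:
    """Dense rank (1 = highest score) of each base cell under one score."""
    values = score.values if isinstance(score, CompositeScore) else np.asarray(score, float)
    base = np.asarray(sorted(base_cells), dtype=np.int64)
    ranks = pd.Series(values[base]).rank(method="dense", ascending=False)
    return {int(c): int(r) for c, r in zip(base, ranks)}


def rank_sum_priority(
    ranks_by_algorithm: dict[str, dict[int, int]], cells
) -> list[int]:
    """Order hotspot cells by ascending sum of per-algorithm ranks.

    Ties in the rank sum are broken by the lower cell id. Raises if a cell
    lacks a rank under any algorithm.
    """
    order = []
    for cell in cells:
        try:
            total = sum(ranks[cell] for ranks in ranks_by_algorithm.values())
        except KeyError:
            raise KeyError(f"cell {cell} missing a rank") from None
        order.append((total, cell))
    return [cell for _, cell in sorted(order)]


def composite_scores(
    pm: PresenceMatrix, checklist, standardize=minmax_standardize
) -> dict[str, CompositeScore]:
    """Composite score per algorithm from a presence matrix and checklist."""
    subsets = ("all", "endemic", "threatened")
    out: dict[str, CompositeScore] = {}
    rich = {s: richness_surface(pm, checklist, s) for s in subsets}
    out["richness"] = composite_score(*(rich[s] for s in subsets), standardize)
    comp = {
        s: complementarity_surface(
            complementarity_selection(pm, checklist, s), pm.grid
        )
        for s in subsets
    }
    out["complementarity"] = composite_score(
        *(comp[s] for s in subsets), standardize
    )
    we = {s: weighted_endemism_surface(pm, checklist, s) for s in subsets}
    out["weighted_endemism"] = composite_score(
        *(we[s] for s in subsets), standardize
    )
    return out


def identify_hotspots(
    pm: PresenceMatrix,
    checklist,
    fraction: float,
    base_cells=None,
    combine: str = "union",
    standardize=minmax_standardize,
) -> HotspotSet:
    """Full hotspot pipeline at one threshold.

    ``base_cells`` defaults to the occupied cells (cells holding at least
    one species), which is the percentile base the published cell counts
    imply; pass ``range(grid.n_cells)`` to rank over the whole grid.
    ``combine`` is ``"union"`` (default: any algorithm suffices, classes
    I/II/III record agreement) or ``"intersection"`` (all three must
    agree; every kept cell is Class I).
    """
    if base_cells is None:
        base_cells = occupied_cells(pm)
    scores = composite_scores(pm, checklist, standardize)
    tops = {
        alg: top_fraction(scores[alg], fraction, base_cells)
        for alg in ALGORITHMS
    }
    classes = consensus_classes(
        tops["richness"], tops["complementarity"], tops["weighted_endemism"]
    )
    if combine == "union":
        cells = set(classes)
    elif combine == "intersection":
        cells = {c for c, k in classes.items() if k == "I"}
        classes = {c: "I" for c in cells}
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    if not cells:
        logger.warning("no hotspot cells at fraction %.3f", fraction)
    ranks = {alg: dense_ranks(scores[alg], base_cells) for alg in ALGORITHMS}
    priority = rank_sum_priority(ranks, sorted(cells))
    return HotspotSet(fraction, cells, classes, priority, tops)


def hotspot_table(hs: HotspotSet, scores: dict[str, CompositeScore]) -> pd.DataFrame:
    """Per-cell summary of one hotspot set (one row per hotspot cell)."""
    rank_pos = {c: i for i, c in enumerate(hs.priority)}
    rows = []
    for cell in hs.priority:
        rows.append(
            {
                "cell_id": cell,
                "composite_richness": scores["richness"].values[cell],
                "composite_complementarity": scores["complementarity"].values[cell],
                "composite_weighted_endemism": scores["weighted_endemism"].values[cell],
                "n_algorithms": {"I": 3, "II": 2, "III": 1}[hs.classes[cell]],
                "class": hs.classes[cell],
                "priority_rank": rank_pos[cell] + 1,
            }
        )
    return pd.DataFrame(rows)
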