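"""Reserve overlay: protection status, effectiveness tables, gap cells.

Reserves come in two tiers, NNR (national) and PNR (provincial). A grid
cell counts as protected by a tier when at least one reserve polygon of
that tier overlaps the cell rectangle with positive area — a cell is a
conservation gap only when no reserve touches it at all, so any-overlap
is the complementary protection rule. At the record level a species'
protected fraction is the share of its occurrence records falling inside
(or on the boundary of) any reserve polygon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, box
from shapely.strtree import STRtree
from shapely.validation import make_valid

from .checklist import subset_species
from .grid import GridSpec, PresenceMatrix

logger = logging.getLogger(__name__)

TIERS = ("NNR", "PNR")

#: Distance tolerance (km) for counting a boundary record as inside.
BOUNDARY_TOL = 1e-9


@dataclass
class ReserveLayer:
    """Reserve polygons with a tier label each.

    Invalid polygons are repaired with ``make_valid`` where possible;
    unrepairable ones are rejected. Both events are logged with the
    polygon's position in the input.
    """

    geometries: list
    tiers: list[str]

    def __post_init__(self) -> None:
        if len(self.geometries) != len(self.tiers):
            raise ValueError("one tier per polygon required")
        bad = set(self.tiers) - set(TIERS)
        if bad:
            raise ValueError(f"unknown reserve tiers: {sorted(bad)}")
        geoms, tiers = [], []
        for i, (g, t) in enumerate(zip(self.geometries, self.tiers)):
            if not g.is_valid:
                repaired = make_valid(g)
                if repaired.is_valid and not repaired.is_empty:
                    logger.warning("repaired invalid reserve polygon %d", i)
                    g = repaired
                else:
                    logger.warning("rejected invalid reserve polygon %d", i)
                    continue
            geoms.append(g)
            tiers.append(t)
        self.geometries, self.tiers = geoms, tiers

    def tier_geometries(self, tier: str) -> list:
        if tier not in TIERS:
            raise ValueError(f"unknown tier {tier!r}")
        return [g for g, t in zip(self.geometries, self.tiers) if t == tier]

    def __len__(self) -> int:
        return len(self.geometries)


@dataclass
class ProtectionStatus:
    """Per-cell protection booleans by reserve tier."""

    by_nnr: np.ndarray
    by_pnr: np.ndarray

    @property
    def by_either(self) -> np.ndarray:
        return self.by_nnr | self.by_pnr

    def by_tier(self, tier: str) -> np.ndarray:
        if tier == "NNR":
            return self.by_nnr
        if tier == "PNR":
            return self.by_pnr
        if tier == "either":
            return self.by_either
        raise ValueError(f"unknown tier {tier!r}")


def _covered_cells(grid: GridSpec, geoms: list) -> np.ndarray:
    """Boolean per cell: does any polygon overlap the cell with area > 0?"""
    out = np.zeros(grid.n_cells, dtype=bool)
    if not geoms:
        return out
    tree = STRtree(geoms)
    for cell in range(grid.n_cells):
        rect = box(*grid.cell_bounds(cell))
        for idx in tree.query(rect):
            if geoms[idx].intersection(rect).area > 0:
                out[cell] = True
                break
    return out


def protection_status(grid: GridSpec, reserves: ReserveLayer) -> ProtectionStatus:
    """Overlay reserves on the grid; positive-area intersection protects."""
    return ProtectionStatus(
        by_nnr=_covered_cells(grid, reserves.tier_geometries("NNR")),
        by_pnr=_covered_cells(grid, reserves.tier_geometries("PNR")),
    )


def percentage(count: float, base: float, decimals: int = 2) -> float:
    """count / base as a percentage, rounded half-up to ``decimals``."""
    if base == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    ratio = Decimal(str(count)) * 100 / Decimal(str(base))
    return float(ratio.quantize(q, rounding=ROUND_HALF_UP))


def gap_cells(hotspot_cells, status: ProtectionStatus, tier: str) -> set[int]:
    """Hotspot cells not protected by the given tier ('NNR'/'PNR'/'either')."""
    protected = status.by_tier(tier)
    return {c for c in hotspot_cells if not protected[c]}


def _species_in_cells(pm: PresenceMatrix, cells, species_ids) -> int:
    """Number of the given species with >= 1 presence in the cell set."""
    cells = np.asarray(sorted(cells), dtype=np.int64)
    if cells.size == 0:
        return 0
    cols = pm.species_index([s for s in species_ids if s in set(pm.species)])
    if cols.size == 0:
        return 0
    return int(pm.occupancy[np.ix_(cells, cols)].any(axis=0).sum())


def effectiveness_summary(
    hotspot_cells,
    status: ProtectionStatus,
    pm: PresenceMatrix,
    checklist: pd.DataFrame,
) -> pd.DataFrame:
    """Conservation effectiveness and gap table for one hotspot set.

    One row per (tier in NNR/PNR/either) x (protected/unprotected):
    cell count and percent of hotspot cells, and the number / percent of
    all, endemic and threatened species with at least one presence in
    those cells. Species percentages use the full checklist group totals
    as denominators (not just species present in hotspots); percentages
    are rounded half-up to two decimals.
    """
    hotspot_cells = sorted(set(hotspot_cells))
    n_hot = len(hotspot_cells)
    if n_hot == 0:
        logger.warning("empty hotspot set: effectiveness table is all zeros")
    groups = {s: subset_species(checklist, s) for s in ("all", "endemic", "threatened")}
    rows = []
    for tier in ("NNR", "PNR", "either"):
        protected = status.by_tier(tier)
        for label, cells in (
            ("protected", [c for c in hotspot_cells if protected[c]]),
            ("unprotected", [c for c in hotspot_cells if not protected[c]]),
        ):
            row = {
                "tier": tier,
                "status": label,
                "cells": len(cells),
                "cells_pct": percentage(len(cells), n_hot),
            }
            for gname, ids in groups.items():
                n = _species_in_cells(pm, cells, ids)
                row[f"{gname}_species"] = n
                row[f"{gname}_species_pct"] = percentage(n, len(ids))
            rows.append(row)
    return pd.DataFrame(rows)


def species_record_protection(
    occurrences: pd.DataFrame, reserves: ReserveLayer
) -> pd.DataFrame:
    """Per-species fraction of occurrence records inside any reserve.

    A record on a polygon boundary counts as inside (tolerance 1e-9 km).
    Returns species_id, n_records, n_protected, fraction, and the strict
    flags ``under_30`` (fraction < 0.30) and ``over_90`` (fraction > 0.90).
    Species with zero records are absent from the result by construction.
    """
    geoms = reserves.geometries
    pts = [Point(x, y) for x, y in zip(occurrences["x"], occurrences["y"])]
    inside = np.zeros(len(pts), dtype=bool)
    if geoms:
        tree = STRtree(geoms)
        for i, pt in enumerate(pts):
            for idx in tree.query(pt.buffer(BOUNDARY_TOL)):
                if shapely.dwithin(geoms[idx], pt, BOUNDARY_TOL):
                    inside[i] = True
                    break
    df = occurrences.assign(_inside=inside)
    agg = df.groupby("species_id", sort=True).agg(
        n_records=("_inside", "size"), n_protected=("_inside", "sum")
    )
    agg["fraction"] = agg["n_protected"] / agg["n_records"]
    agg["under_30"] = agg["fraction"] < 0.30
    agg["over_90"] = agg["fraction"] > 0.90
    return agg.reset_index()
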