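"""Climate-impact post-processing of habitat-suitability surfaces.

This module consumes per-species suitability surfaces (values in [0, 1]
per grid cell) for a current and a future climate scenario, as produced
by a species-distribution model such as MaxEnt, together with per-species
AUC metadata. Model fitting itself is out of scope: the inputs here are
the model's outputs. The pipeline is:

1. prune collinear environmental layers (|r| > 0.85) — bookkeeping for
   which variables a model run should use;
2. restrict to species with >= 5 occurrence records and AUC >= 0.7;
3. threshold suitability at > 0.6 into binary ranges;
4. derive richness-change surfaces and per-species habitat change:
   contraction / no change / expansion, loss of suitable area (LSA) and
   range-shift fraction;
5. map LSA onto projected threat categories
   (EX = 100%, CR [80, 100), EN [50, 80), VU [30, 50), CC < 30%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCENARIOS = ("current", "RCP2.6", "RCP8.5")

#: LSA -> projected category bands, checked in order. EX requires total
#: loss; the remaining bands are half-open, left-closed.
LSA_BANDS = (("CR", 0.8), ("EN", 0.5), ("VU", 0.3))

CHANGE_CLASSES = ("contraction", "no_change", "expansion")


@dataclass
class SuitabilityStack:
    """Species x cells suitability values in [0, 1] for one scenario."""

    scenario: str
    species: list[str]
    values: np.ndarray  # (n_species, n_cells) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.species):
            raise ValueError("one row per species required")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("suitability values must lie in [0, 1]")

    def select(self, species_ids) -> "SuitabilityStack":
        """Sub-stack restricted to the given species, in the given order."""
        pos = {s: i for i, s in enumerate(self.species)}
        idx = [pos[s] for s in species_ids]
        return SuitabilityStack(self.scenario, list(species_ids), self.values[idx])


@dataclass
class EnvStack:
    """Named environmental layers, one value per cell."""

    names: list[str]
    values: np.ndarray  # (n_layers, n_cells) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.names):
            raise ValueError("one row per layer required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("environmental layers must be finite")


def prune_variables(env: EnvStack, r_max: float = 0.85) -> list[str]:
    """Drop one layer from each highly correlated pair (|r| > r_max).

    Pairs are visited in input order and the later-listed layer of an
    offending pair is dropped, so the input order encodes priority.
    Constant layers have no defined correlation; they are retained and
    logged. The retained list preserves input order.
    """
    if len(env.names) < 2:
        raise ValueError("pruning needs at least two layers")
    constant = [np.ptp(row) == 0 for row in env.values]
    for name, c in zip(env.names, constant):
        if c:
            logger.warning("layer %s is constant; excluded from correlation", name)
    dropped = [False] * len(env.names)
    for i in range(len(env.names)):
        if dropped[i] or constant[i]:
            continue
        for j in range(i + 1, len(env.names)):
            if dropped[j] or constant[j]:
                continue
            r = np.corrcoef(env.values[i], env.values[j])[0, 1]
            if abs(r) > r_max:
                dropped[j] = True
    return [n for n, d in zip(env.names, dropped) if not d]


def eligible_species(record_counts: pd.Series, min_records: int = 5) -> list[str]:
    """Species with at least ``min_records`` occurrence records.

    Mirrors the modelling constraint that distribution models are
    unreliable below five occurrence points; the boundary count itself
    is retained (strictly fewer is excluded).
    """
    counts = record_counts
    keep = counts[counts >= min_records]
    n_excluded = len(counts) - len(keep)
    if n_excluded:
        logger.info("excluded %d species with < %d records", n_excluded, min_records)
    return list(keep.index)


def auc_filter(auc_table: pd.DataFrame, auc_min: float = 0.7) -> list[str]:
    """Species whose model AUC is at least ``auc_min``.

    ``auc_table`` has columns species_id and auc. Species with missing
    AUC are excluded with a warning; AUC exactly at the threshold is
    retained (only strictly lower is excluded).
    """
    missing = auc_table["auc"].isna()
    if missing.any():
        logger.warning(
            "excluding %d species with missing AUC", int(missing.sum())
        )
    keep = auc_table.loc[~missing & (auc_table["auc"] >= auc_min), "species_id"]
    return keep.tolist()


def binary_range(stack: SuitabilityStack, s_min: float = 0.6) -> np.ndarray:
    """Boolean presence per species x cell: suitability strictly > s_min."""
    return stack.values > s_min


def richness_and_change(cur: np.ndarray, fut: np.ndarray) -> dict[str, np.ndarray]:
    """Per-cell richness / gain / loss / net surfaces from binary ranges.

    ``gain[c]`` counts species absent in the current scenario but present
    in the future one; ``loss[c]`` the reverse; ``net = gain - loss``
    equals the richness difference exactly.
    """
    cur = np.asarray(cur, dtype=bool)
    fut = np.asarray(fut, dtype=bool)
    if cur.shape != fut.shape:
        raise ValueError("scenario ranges differ in species set or grid")
    return {
        "richness_cur": cur.sum(axis=0).astype(float),
        "richness_fut": fut.sum(axis=0).astype(float),
        "gain": (fut & ~cur).sum(axis=0).astype(float),
        "loss": (cur & ~fut).sum(axis=0).astype(float),
        "net": fut.sum(axis=0).astype(float) - cur.sum(axis=0).astype(float),
    }


def habitat_change(
    cur: np.ndarray, fut: np.ndarray, species: list[str]
) -> pd.DataFrame:
    """Per-species habitat change between two binary range stacks.

    Returns a frame with current/future cell counts, the change class
    (strict comparison of the counts), LSA = lost cells / current cells,
    and shift fraction = (gained + lost cells) / current cells. Species
    with an empty current range are flagged ``assessable = False`` and
    carry NaN for LSA/shift.
    """
    cur = np.asarray(cur, dtype=bool)
    fut = np.asarray(fut, dtype=bool)
    if cur.shape != fut.shape or cur.shape[0] != len(species):
        raise ValueError("scenario ranges differ in species set or grid")
    a_cur = cur.sum(axis=1)
    a_fut = fut.sum(axis=1)
    lost = (cur & ~fut).sum(axis=1)
    gained = (fut & ~cur).sum(axis=1)
    assessable = a_cur > 0
    if not assessable.all():
        logger.warning(
            "%d species have no current range and are not assessable",
            int((~assessable).sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        lsa = np.where(assessable, lost / np.maximum(a_cur, 1), np.nan)
        shift = np.where(assessable, (lost + gained) / np.maximum(a_cur, 1), np.nan)
    change = np.where(
        a_fut < a_cur, "contraction", np.where(a_fut > a_cur, "expansion", "no_change")
    )
    return pd.DataFrame(
        {
            "species_id": species,
            "a_cur": a_cur,
            "a_fut": a_fut,
            "cells_lost": lost,
            "cells_gained": gained,
            "change_class": change,
            "lsa": lsa,
            "shift_fraction": shift,
            "assessable": assessable,
        }
    )


def reclassify_threat(current_category: str, lsa: float) -> str:
    """Projected threat category from the loss of suitable area.

    EX at LSA exactly 1 (total habitat loss), then left-closed half-open
    bands: CR [0.8, 1), EN [0.5, 0.8), VU [0.3, 0.5), CC below 0.3.
    The band lookup ignores the current category; callers report a
    category "upgrade" only for currently unthreatened (NT/CC) species.
    """
    if not 0 <= lsa <= 1:
        raise ValueError(f"LSA must lie in [0, 1], got {lsa}")
    if lsa == 1:
        return "EX"
    for category, lo in LSA_BANDS:
        if lsa >= lo:
            return category
    return "CC"


def reassess(
    change: pd.DataFrame, checklist: pd.DataFrame, scenario: str
) -> pd.DataFrame:
    """Join habitat change with the checklist and project categories.

    Adds ``projected_category`` (LSA band) and ``upgraded`` — True when a
    currently unthreatened (NT/CC) species lands in a threatened or
    extinct band. Unassessable species keep NaN projections.
    """
    df = change.merge(
        checklist[["species_id", "category"]], on="species_id", how="left"
    )
    df = df.rename(columns={"category": "current_category"})
    df["projected_category"] = [
        reclassify_threat(cat, float(lsa)) if ok else None
        for cat, lsa, ok in zip(df["current_category"], df["lsa"], df["assessable"])
    ]
    df["upgraded"] = (
        df["current_category"].isin(["NT", "CC"])
        & df["projected_category"].isin(["EX", "CR", "EN", "VU"])
    )
    df["scenario"] = scenario
    return df


def impact_summary(reassessments: pd.DataFrame, n_total: int) -> dict:
    """Scenario-level summary of threat reclassification.

    Returns the NT/CC -> projected-category cross table (counts and
    percentages of ``n_total``, the full checklist size), the
    contraction / no-change / expansion proportions over assessed
    species, and counts of species whose LSA exceeds 10% / 30% / 60%
    or whose shift fraction exceeds 60%.
    """
    df = reassessments[reassessments["assessable"]]
    unthreatened = df[df["current_category"].isin(["NT", "CC"])]
    cross = pd.crosstab(
        unthreatened["current_category"], unthreatened["projected_category"]
    )
    cross = cross.reindex(
        index=["NT", "CC"], columns=["EX", "CR", "EN", "VU", "CC"], fill_value=0
    )
    from .conservation import percentage

    cross_pct = cross.map(lambda c: percentage(c, n_total))
    n_assessed = len(df)
    change_counts = df["change_class"].value_counts()
    change_prop = {
        cls: float(change_counts.get(cls, 0)) / n_assessed if n_assessed else 0.0
        for cls in CHANGE_CLASSES
    }
    return {
        "n_assessed": n_assessed,
        "upgrade_counts": cross,
        "upgrade_pct": cross_pct,
        "n_upgraded": int(df["upgraded"].sum()),
        "change_proportions": change_prop,
        "lsa_over_10": int((df["lsa"] > 0.10).sum()),
        "lsa_over_30": int((df["lsa"] > 0.30).sum()),
        "lsa_over_60": int((df["lsa"] > 0.60).sum()),
        "shift_over_60": int((df["shift_fraction"] > 0.60).sum()),
    }
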