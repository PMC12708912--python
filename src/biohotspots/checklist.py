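"""Species checklist: threat categories, endemism flags, subset filters.

The checklist is the master species list for an analysis: one row per
species with an endemism flag and a red-list-style threat category.
Categories follow the five-level scheme CR (critically endangered),
EN (endangered), VU (vulnerable), NT (near threatened) and CC
(conservation concern); CR/EN/VU together form the "threatened" group.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Threat categories, ordered from most to least severe.
CATEGORIES = ("CR", "EN", "VU", "NT", "CC")

#: Categories counted as "threatened" in subset analyses.
THREATENED = frozenset({"CR", "EN", "VU"})

#: Valid species-subset labels for diversity surfaces.
SUBSETS = ("all", "endemic", "threatened")


@dataclass(frozen=True)
class ChecklistEntry:
    """One checklist species."""

    species_id: str
    name: str
    endemic: bool
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown threat category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )


def checklist_frame(entries) -> pd.DataFrame:
    """Convert an iterable of :class:`ChecklistEntry` to a DataFrame."""
    df = pd.DataFrame(
        [(e.species_id, e.name, e.endemic, e.category) for e in entries],
        columns=["species_id", "name", "endemic", "category"],
    )
    return df


def validate_checklist(checklist: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and category values; return the frame."""
    required = {"species_id", "endemic", "category"}
    missing = required - set(checklist.columns)
    if missing:
        raise ValueError(f"checklist missing columns: {sorted(missing)}")
    bad = set(checklist["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown threat categories: {sorted(bad)}")
    if checklist["species_id"].duplicated().any():
        raise ValueError("duplicate species_id in checklist")
    return checklist


def subset_species(checklist: pd.DataFrame, subset: str) -> list[str]:
    """Species ids belonging to a named subset.

    Parameters
    ----------
    checklist
        Frame with columns ``species_id``, ``endemic``, ``category``.
    subset
        One of ``"all"``, ``"endemic"`` (endemic flag set) or
        ``"threatened"`` (category in CR/EN/VU).
    """
    validate_checklist(checklist)
    if subset == "all":
        mask = pd.Series(True, index=checklist.index)
    elif subset == "endemic":
        mask = checklist["endemic"].astype(bool)
    elif subset == "threatened":
        mask = checklist["category"].isin(THREATENED)
    else:
        raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSETS}")
    return checklist.loc[mask, "species_id"].tolist()
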