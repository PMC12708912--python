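import numpy as np
import pandas as pd
import pytest

import biohotspots as bh


@pytest.fixture
def tiny_checklist():
    """Five species: A endemic+CR, B VU, C NT, D endemic+CC, E EN."""
    return pd.DataFrame(
        {
            "species_id": list("ABCDE"),
            "name": [f"species {s}" for s in "ABCDE"],
            "endemic": [True, False, False, True, False],
            "category": ["CR", "VU", "NT", "CC", "EN"],
        }
    )


@pytest.fixture
def tiny_grid():
    """3 x 1 grid of 10-km cells (cells 0, 1, 2)."""
    return bh.build_grid((0, 0, 30, 10), 10)


def presence_from_sets(grid, checklist, cell_species):
    """Build a PresenceMatrix from {cell_id: iterable of species ids}."""
    species = checklist["species_id"].tolist()
    occ = np.zeros((grid.n_cells, len(species)), dtype=bool)
    pos = {s: i for i, s in enumerate(species)}
    for cell, ids in cell_species.items():
        for s in ids:
            occ[cell, pos[s]] = True
    return bh.PresenceMatrix(grid, species, occ)


@pytest.fixture
def cover_presence(tiny_grid, tiny_checklist):
    """The worked greedy-cover instance: c0={A,B,C}, c1={C,D}, c2={D,E}."""
    return presence_from_sets(
        tiny_grid, tiny_checklist, {0: "ABC", 1: "CD", 2: "DE"}
    )


def random_instance(rng, max_cells=12, max_species=12):
    """Random small presence matrix + checklist for set-cover oracles."""
    n_cells = int(rng.integers(2, max_cells + 1))
    n_species = int(rng.integers(2, max_species + 1))
    occ = rng.random((n_cells, n_species)) < 0.3
    # every species gets at least one cell so the cover is feasible
    for s in range(n_species):
        if not occ[:, s].any():
            occ[rng.integers(n_cells), s] = True
    grid = bh.build_grid((0, 0, 10 * n_cells, 10), 10)
    species = [f"s{i}" for i in range(n_species)]
    checklist = pd.DataFrame(
        {
            "species_id": species,
            "name": species,
            "endemic": [False] * n_species,
            "category": ["CC"] * n_species,
        }
    )
    return bh.PresenceMatrix(grid, species, occ), checklist


def exhaustive_min_cover(pm):
    """Exact minimum set-cover size by exhaustive subset search."""
    from itertools import combinations

    occ = pm.occupancy
    cells = np.flatnonzero(occ.any(axis=1))
    target = occ.any(axis=0)
    for size in range(1, len(cells) + 1):
        for combo in combinations(cells, size):
            if np.array_equal(occ[list(combo)].any(axis=0) & target, target):
                return size
    raise AssertionError("no cover found")


@pytest.fixture
def small_world():
    """A small but full synthetic world shared by integration tests."""
    cfg = bh.SyntheticConfig(
        seed=7,
        n_species=80,
        extent=(0, 0, 1000, 1000),
        cell_size=50,
        n_hotspot_clusters=1,
        cluster_radius=125,
        n_nnr=15,
        n_pnr=25,
        n_env_layers=6,
    )
    checklist = bh.generate_checklist(cfg)
    occurrences = bh.generate_occurrences(cfg, checklist)
    grid = cfg.grid()
    pm = bh.build_presence(occurrences, grid, species_order=checklist["species_id"])
    return cfg, checklist, occurrences, grid, pm
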