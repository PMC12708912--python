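"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: occurrence / checklist / AUC tables as
CSV, reserves as a GeoJSON FeatureCollection with a ``tier`` property,
gridded surfaces as ESRI ASCII grids, the presence matrix as a sparse
triplet CSV, and suitability stacks as either one ASCII grid per species
per scenario or a single long CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .climate import SuitabilityStack
from .conservation import ReserveLayer
from .grid import GridSpec, PresenceMatrix

NODATA = -9999.0


# ---------------------------------------------------------------- tables

def read_occurrences(path) -> pd.DataFrame:
    """Read an occurrence CSV; extra columns are tolerated and kept."""
    df = pd.read_csv(path)
    missing = {"species_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence file missing columns: {sorted(missing)}")
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValueError("occurrence coordinates must be finite")
    return df


def write_occurrences(df: pd.DataFrame, path) -> None:
    df[["species_id", "x", "y"]].to_csv(path, index=False)


def read_checklist(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["endemic"] = df["endemic"].astype(bool)
    return df


def write_checklist(df: pd.DataFrame, path) -> None:
    df[["species_id", "name", "endemic", "category"]].to_csv(path, index=False)


def read_auc(path) -> pd.DataFrame:
    return pd.read_csv(path)[["species_id", "auc"]]


def write_auc(df: pd.DataFrame, path) -> None:
    df[["species_id", "auc"]].to_csv(path, index=False)


# --------------------------------------------------------------- GeoJSON

def write_reserves(layer: ReserveLayer, path) -> None:
    """Write reserves as a GeoJSON FeatureCollection with a tier property."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"tier": tier},
        }
        for geom, tier in zip(layer.geometries, layer.tiers)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_reserves(path) -> ReserveLayer:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValueError("reserve file is not a GeoJSON FeatureCollection")
    geoms, tiers = [], []
    for feat in data["features"]:
        geoms.append(shape(feat["geometry"]))
        tiers.append(feat["properties"]["tier"])
    return ReserveLayer(geoms, tiers)


# ------------------------------------------------------ ESRI ASCII grids

def write_ascii_grid(values: np.ndarray, grid: GridSpec, path) -> None:
    """Write one per-cell surface as an ESRI ASCII grid.

    Cell-id order is row-major from the lower-left; the ASCII format
    stores rows north-to-south, so rows are flipped on write.
    """
    values = np.asarray(values, dtype=float)
    if values.size != grid.n_cells:
        raise ValueError("surface length does not match the grid")
    arr = values.reshape(grid.n_rows, grid.n_cols)[::-1]
    arr = np.where(np.isfinite(arr), arr, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x0}\n"
        f"yllcorner {grid.y0}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid back to (per-cell values, GridSpec)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, value = line.split()
        header[key.lower()] = float(value)
    grid = GridSpec(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell_size=header["cellsize"],
        n_cols=int(header["ncols"]),
        n_rows=int(header["nrows"]),
    )
    arr = np.loadtxt(lines[6:], ndmin=2)
    if arr.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("ASCII grid body does not match its header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    return arr[::-1].reshape(-1), grid


# ------------------------------------------------------ presence / stacks

def write_presence_triplets(pm: PresenceMatrix, path) -> None:
    """Sparse (cell_id, species_id) pairs, one row per presence."""
    cells, cols = np.nonzero(pm.occupancy)
    df = pd.DataFrame(
        {"cell_id": cells, "species_id": [pm.species[c] for c in cols]}
    )
    df.to_csv(path, index=False)


def read_presence_triplets(path, grid: GridSpec, species_order=None) -> PresenceMatrix:
    df = pd.read_csv(path)
    species = (
        list(species_order)
        if species_order is not None
        else list(dict.fromkeys(df["species_id"]))
    )
    pos = {s: i for i, s in enumerate(species)}
    occ = np.zeros((grid.n_cells, len(species)), dtype=bool)
    occ[df["cell_id"].to_numpy(), df["species_id"].map(pos).to_numpy()] = True
    return PresenceMatrix(grid, species, occ)


def write_suitability_csv(stack: SuitabilityStack, path) -> None:
    """Long-form CSV: species_id, cell_id, scenario, suitability."""
    n_cells = stack.values.shape[1]
    frames = []
    for i, sid in enumerate(stack.species):
        frames.append(
            pd.DataFrame(
                {
                    "species_id": sid,
                    "cell_id": np.arange(n_cells),
                    "scenario": stack.scenario,
                    "suitability": stack.values[i],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_suitability_csv(path, scenario: str) -> SuitabilityStack:
    df = pd.read_csv(path)
    df = df[df["scenario"] == scenario]
    species = list(dict.fromkeys(df["species_id"]))
    n_cells = int(df["cell_id"].max()) + 1
    values = np.zeros((len(species), n_cells))
    pos = {s: i for i, s in enumerate(species)}
    values[df["species_id"].map(pos), df["cell_id"]] = df["suitability"]
    return SuitabilityStack(scenario, species, values)


def write_suitability_grids(
    stack: SuitabilityStack, grid: GridSpec, directory
) -> list[Path]:
    """One ASCII grid per species, named {species_id}_{scenario}.asc."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sid in enumerate(stack.species):
        path = directory / f"{sid}_{stack.scenario}.asc"
        write_ascii_grid(stack.values[i], grid, path)
        paths.append(path)
    return paths


def read_suitability_grids(directory, scenario: str) -> SuitabilityStack:
    """Read every {species_id}_{scenario}.asc in a directory into a stack."""
    directory = Path(directory)
    paths = sorted(directory.glob(f"*_{scenario}.asc"))
    if not paths:
        raise FileNotFoundError(f"no *_{scenario}.asc grids in {directory}")
    species, rows = [], []
    for path in paths:
        values, _ = read_ascii_grid(path)
        species.append(path.name[: -len(f"_{scenario}.asc")])
        rows.append(values)
    return SuitabilityStack(scenario, species, np.vstack(rows))
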