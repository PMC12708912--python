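"""Synthetic occurrence / reserve / suitability data with known structure.

Every downstream stage of the pipeline is testable against data whose
generating parameters are known exactly: a checklist with fixed category
fractions, occurrence records with a heavy-tailed range-size distribution
and planted clusters of narrow-range species, two-tier rectangular
reserves with controllable coverage, equicorrelated environmental layers,
and current/future suitability stacks whose per-species habitat loss and
gain fractions are planted so the climate module must recover them.

All generators are pure functions of (config, seed): each derives its own
random stream from the seed and a fixed per-generator salt, so the output
of one generator never depends on whether another ran first.

Defaults emulate the headline analysis they stand in for: 458 species
(264 threatened split evenly over CR/EN/VU, 56 NT, 138 CC; 232 endemic)
on a 64 x 64 grid of 50-km cells (4096 cells, close to the 4069 land
cells of a national 50-km grid), with 464 national and 806 provincial
reserves covering ~18% of the extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box

from .checklist import CATEGORIES, ChecklistEntry, checklist_frame
from .climate import EnvStack, SuitabilityStack
from .conservation import ReserveLayer
from .grid import GridSpec, PresenceMatrix, build_grid

logger = logging.getLogger(__name__)

# Per-generator salts keep the random streams independent.
_SALT = {
    "checklist": 101,
    "occurrences": 202,
    "reserves": 303,
    "suitability": 404,
    "env": 505,
}


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration is internally inconsistent."""


def _paper_like_fractions() -> dict[str, float]:
    # 264 threatened split evenly over CR/EN/VU; 56 NT; 138 CC (of 458)
    return {
        "CR": 88 / 458,
        "EN": 88 / 458,
        "VU": 88 / 458,
        "NT": 56 / 458,
        "CC": 138 / 458,
    }


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic world.

    Attributes
    ----------
    seed
        Master seed; every generator is deterministic given it.
    n_species
        Checklist size.
    extent
        (xmin, ymin, xmax, ymax) in planar km.
    cell_size
        Grid cell edge (km).
    frac_endemic
        Bernoulli probability of the endemic flag.
    category_fractions
        Proportions over CR/EN/VU/NT/CC; converted to counts by
        largest-remainder rounding so the composition is reproducible.
    range_size_shape
        Sigma of the truncated discrete lognormal from which each
        species' target occupied-cell count is drawn (median
        ``range_size_median`` cells, floor 1, cap n_cells).
    narrow_cutoff
        Species with target range <= this many cells are "narrow" and
        are planted inside one of the hotspot cluster disks.
    n_hotspot_clusters, cluster_radius
        Number and radius (km) of the planted narrow-species clusters.
    n_nnr, n_pnr, reserve_coverage
        Reserve counts per tier and the target total polygon area as a
        proportion of the extent area (matched within 20%).
    n_env_layers, env_corr
        Environmental layer count and target pairwise correlation.
    loss_fractions, gain_fractions
        Planted per-species habitat loss / gain for the future scenario:
        a scalar applied to every species, a mapping species_id ->
        value, or None to draw per species (loss ~ U(0, 0.9),
        gain ~ U(0, 0.6), giving a mix of contraction and expansion).
    n_low_auc
        Number of species planted with AUC below 0.7 (they must be
        excluded by the AUC filter downstream).
    """

    seed: int = 0
    n_species: int = 458
    extent: tuple[float, float, float, float] = (0.0, 0.0, 3200.0, 3200.0)
    cell_size: float = 50.0
    frac_endemic: float = 232 / 458
    category_fractions: dict[str, float] = field(
        default_factory=_paper_like_fractions
    )
    range_size_shape: float = 1.2
    range_size_median: float = 4.0
    narrow_cutoff: int = 3
    n_hotspot_clusters: int = 3
    cluster_radius: float = 150.0
    n_nnr: int = 464
    n_pnr: int = 806
    reserve_coverage: float = 0.18
    n_env_layers: int = 20
    env_corr: float = 0.5
    loss_fractions: float | dict[str, float] | None = None
    gain_fractions: float | dict[str, float] | None = None
    n_low_auc: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ConfigurationError("extent is empty")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be > 0")
        if not 0 <= self.frac_endemic <= 1:
            raise ConfigurationError("frac_endemic must lie in [0, 1]")
        if set(self.category_fractions) != set(CATEGORIES):
            raise ConfigurationError(
                f"category_fractions must cover {CATEGORIES}"
            )
        total = sum(self.category_fractions.values())
        if abs(total - 1) > 1e-9:
            raise ConfigurationError(
                f"category_fractions sum to {total}, not 1"
            )
        if self.reserve_coverage > 1 or self.reserve_coverage < 0:
            raise ConfigurationError("reserve_coverage must lie in [0, 1]")
        if abs(self.env_corr) > 1:
            raise ConfigurationError("|env_corr| must be <= 1")

    def grid(self) -> GridSpec:
        return build_grid(self.extent, self.cell_size)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["extent"] = list(self.extent)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "extent" in data:
            data["extent"] = tuple(data["extent"])
        return cls(**data)


def _rng(cfg: SyntheticConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([_SALT[stage], cfg.seed])


def largest_remainder_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Integer counts summing to n, by largest-remainder apportionment.

    Remainder ties are broken by the fixed CR > EN > VU > NT > CC order.
    """
    keys = [k for k in CATEGORIES if k in fractions]
    quotas = np.array([n * fractions[k] for k in keys])
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    remainders = quotas - np.floor(quotas)
    order = sorted(range(len(keys)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(keys, counts))


def generate_checklist(cfg: SyntheticConfig) -> pd.DataFrame:
    """Checklist of n_species with planted category counts and endemism."""
    rng = _rng(cfg, "checklist")
    counts = largest_remainder_counts(cfg.n_species, cfg.category_fractions)
    categories = [c for cat in CATEGORIES for c in [cat] * counts[cat]]
    endemic = rng.random(cfg.n_species) < cfg.frac_endemic
    entries = [
        ChecklistEntry(
            species_id=f"sp{i:04d}",
            name=f"species {i:04d}",
            endemic=bool(endemic[i]),
            category=categories[i],
        )
        for i in range(cfg.n_species)
    ]
    return checklist_frame(entries)


def _cluster_centers(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    xmin, ymin, xmax, ymax = cfg.extent
    r = cfg.cluster_radius
    if xmax - xmin <= 2 * r or ymax - ymin <= 2 * r:
        raise ConfigurationError("extent too small for the cluster radius")
    xs = rng.uniform(xmin + r, xmax - r, cfg.n_hotspot_clusters)
    ys = rng.uniform(ymin + r, ymax - r, cfg.n_hotspot_clusters)
    return np.column_stack([xs, ys])


def generate_occurrences(
    cfg: SyntheticConfig, checklist: pd.DataFrame
) -> pd.DataFrame:
    """Occurrence records (species_id, x, y) with planted structure.

    Each species draws a target occupied-cell count from a truncated
    discrete lognormal (floor 1). Narrow species (target <=
    ``narrow_cutoff``) are confined to one of the planted cluster disks;
    the rest scatter over the whole grid. Every occupied cell receives
    1-3 records jittered inside the cell, so presence (not abundance)
    carries the signal.
    """
    rng = _rng(cfg, "occurrences")
    grid = cfg.grid()
    centers = grid.cell_centers()
    n_cells = grid.n_cells
    targets = np.exp(
        rng.normal(np.log(cfg.range_size_median), cfg.range_size_shape, cfg.n_species)
    )
    targets = np.clip(np.floor(targets + 0.5), 1, n_cells).astype(int)

    cluster_xy = (
        _cluster_centers(cfg, rng) if cfg.n_hotspot_clusters > 0 else np.empty((0, 2))
    )
    cluster_cells = []
    for cx, cy in cluster_xy:
        d2 = (centers[:, 0] - cx) ** 2 + (centers[:, 1] - cy) ** 2
        cells = np.flatnonzero(d2 <= cfg.cluster_radius**2)
        if cells.size == 0:
            raise ConfigurationError(
                "cluster disk contains no cell center; increase cluster_radius"
            )
        cluster_cells.append(cells)

    rows = []
    species_ids = checklist["species_id"].tolist()
    for i, sid in enumerate(species_ids):
        target = targets[i]
        narrow = target <= cfg.narrow_cutoff and cluster_cells
        if narrow:
            pool = cluster_cells[int(rng.integers(len(cluster_cells)))]
        else:
            pool = np.arange(n_cells)
        k = min(target, pool.size)
        chosen = rng.choice(pool, size=k, replace=False)
        for cell in np.sort(chosen):
            n_rec = int(rng.integers(1, 4))
            xmin_c, ymin_c, _, _ = grid.cell_bounds(int(cell))
            xs = xmin_c + rng.random(n_rec) * grid.cell_size
            ys = ymin_c + rng.random(n_rec) * grid.cell_size
            rows.extend((sid, float(x), float(y)) for x, y in zip(xs, ys))
    return pd.DataFrame(rows, columns=["species_id", "x", "y"])


def narrow_species(cfg: SyntheticConfig, checklist: pd.DataFrame) -> list[str]:
    """Ids of the species planted inside cluster disks (target <= cutoff).

    Recomputed from the same random stream as :func:`generate_occurrences`,
    so tests can ask which species were planted without re-deriving ranges.
    """
    rng = _rng(cfg, "occurrences")
    targets = np.exp(
        rng.normal(np.log(cfg.range_size_median), cfg.range_size_shape, cfg.n_species)
    )
    targets = np.clip(np.floor(targets + 0.5), 1, cfg.grid().n_cells).astype(int)
    ids = checklist["species_id"].tolist()
    return [s for s, t in zip(ids, targets) if t <= cfg.narrow_cutoff]


def generate_reserves(cfg: SyntheticConfig) -> ReserveLayer:
    """Axis-aligned rectangular reserves in two tiers.

    The target total polygon area is ``reserve_coverage`` x extent area,
    split over the n_nnr + n_pnr rectangles with random weights; every
    rectangle lies fully inside the extent, so the summed polygon area
    matches the target exactly (well within the 20% contract).
    """
    rng = _rng(cfg, "reserves")
    n = cfg.n_nnr + cfg.n_pnr
    if n == 0 or cfg.reserve_coverage == 0:
        return ReserveLayer([], [])
    xmin, ymin, xmax, ymax = cfg.extent
    extent_area = (xmax - xmin) * (ymax - ymin)
    weights = rng.dirichlet(np.full(n, 2.0))
    areas = weights * cfg.reserve_coverage * extent_area
    geoms, tiers = [], []
    for i, area in enumerate(areas):
        aspect = rng.uniform(0.5, 2.0)
        w = min(np.sqrt(area * aspect), xmax - xmin)
        h = min(area / w, ymax - ymin)
        x = rng.uniform(xmin, xmax - w)
        y = rng.uniform(ymin, ymax - h)
        geoms.append(box(x, y, x + w, y + h))
        tiers.append("NNR" if i < cfg.n_nnr else "PNR")
    return ReserveLayer(geoms, tiers)


def _per_species_fractions(
    spec, species: list[str], rng: np.random.Generator, low: float, high: float
) -> np.ndarray:
    if spec is None:
        return rng.uniform(low, high, len(species))
    if isinstance(spec, dict):
        return np.array([float(spec[s]) for s in species])
    return np.full(len(species), float(spec))


def generate_suitability(
    cfg: SyntheticConfig, pm: PresenceMatrix
) -> tuple[SuitabilityStack, SuitabilityStack, pd.DataFrame]:
    """Current and future suitability stacks plus an AUC table.

    Current suitability is ~0.8 (jitter within [0.65, 0.95]) on each
    species' occupied cells and ~0.2 ([0.05, 0.35]) elsewhere, so the
    > 0.6 presence rule recovers the occupied set exactly. The future
    stack moves round(loss_fraction x range) in-range cells below the
    threshold and lifts round(gain_fraction x range) new cells above it.
    AUC values are U(0.75, 0.99) except the first ``n_low_auc`` species,
    planted at U(0.55, 0.69).
    """
    rng = _rng(cfg, "suitability")
    species = pm.species
    n_sp, n_cells = len(species), pm.grid.n_cells
    loss = _per_species_fractions(cfg.loss_fractions, species, rng, 0.0, 0.9)
    gain = _per_species_fractions(cfg.gain_fractions, species, rng, 0.0, 0.6)
    if np.any(loss < 0) or np.any(loss > 1):
        raise ConfigurationError("loss fractions must lie in [0, 1]")
    if np.any(gain < 0):
        raise ConfigurationError("gain fractions must be >= 0")

    jitter = rng.uniform(-0.15, 0.15, (n_sp, n_cells))
    occ = pm.occupancy.T  # (n_species, n_cells)
    cur = np.where(occ, 0.8, 0.2) + jitter
    fut = cur.copy()
    for i in range(n_sp):
        in_range = np.flatnonzero(occ[i])
        out_range = np.flatnonzero(~occ[i])
        a_cur = in_range.size
        n_lost = int(np.floor(loss[i] * a_cur + 0.5))
        n_gain = min(int(np.floor(gain[i] * a_cur + 0.5)), out_range.size)
        if n_lost:
            drop = rng.choice(in_range, n_lost, replace=False)
            fut[i, drop] = 0.2 + rng.uniform(-0.15, 0.15, n_lost)
        if n_gain:
            add = rng.choice(out_range, n_gain, replace=False)
            fut[i, add] = 0.8 + rng.uniform(-0.15, 0.15, n_gain)
    auc = rng.uniform(0.75, 0.99, n_sp)
    if cfg.n_low_auc:
        auc[: cfg.n_low_auc] = rng.uniform(0.55, 0.69, cfg.n_low_auc)
    auc_table = pd.DataFrame({"species_id": species, "auc": auc})
    return (
        SuitabilityStack("current", list(species), np.clip(cur, 0, 1)),
        SuitabilityStack("RCP2.6", list(species), np.clip(fut, 0, 1)),
        auc_table,
    )


def planted_fractions(
    cfg: SyntheticConfig, pm: PresenceMatrix
) -> pd.DataFrame:
    """The loss/gain fractions the suitability generator planted.

    Drawn from the same stream as :func:`generate_suitability`, so tests
    can compare recovered LSA against the planted truth.
    """
    rng = _rng(cfg, "suitability")
    species = pm.species
    loss = _per_species_fractions(cfg.loss_fractions, species, rng, 0.0, 0.9)
    gain = _per_species_fractions(cfg.gain_fractions, species, rng, 0.0, 0.6)
    return pd.DataFrame(
        {"species_id": species, "loss_fraction": loss, "gain_fraction": gain}
    )


def generate_env_layers(cfg: SyntheticConfig, grid: GridSpec) -> EnvStack:
    """Equicorrelated Gaussian environmental layers, one value per cell."""
    if cfg.n_env_layers < 2:
        raise ConfigurationError("need at least two environmental layers")
    rng = _rng(cfg, "env")
    k = cfg.n_env_layers
    rho = cfg.env_corr
    if rho < -1.0 / (k - 1) - 1e-12:
        raise ConfigurationError(
            f"equicorrelation {rho} is not positive semidefinite for {k} layers"
        )
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    sample = rng.multivariate_normal(
        np.zeros(k), cov, size=grid.n_cells, method="svd"
    )
    names = [f"env{i + 1:02d}" for i in range(k)]
    return EnvStack(names, sample.T.copy())
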