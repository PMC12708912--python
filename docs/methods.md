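# Methods

## Scope and model

The package post-processes species occurrence data into conservation
prioritization outputs on a regular planar grid. It deliberately does
*not* fit species-distribution models: habitat-suitability surfaces and
their AUC values are inputs (synthetic or user-supplied), because model
fitting is a published-tool run, not part of this analysis. Likewise no
geodesic math is done — coordinates are planar km, and users of real
data must project beforehand.

## Grid and presence

Cells are half-open rectangles `[x0+i·s, x0+(i+1)·s) × [y0+j·s,
y0+(j+1)·s)`, closed on the lower/left edge, so a record on a shared
edge belongs to exactly one cell. Cell ids are row-major from the
lower-left. `locate` uses `floor((coord − origin)/size)` with a
one-step bounds correction, because raw floating-point division can
land one cell off at representation edges (a denormal negative offset
underflows to −0.0); the correction makes `locate` exactly consistent
with `cell_bounds`, which a property test enforces. Records outside the
grid are dropped (not clamped) with a logged count, mirroring the
exclusion of invalid records in real compilations. Presence is boolean:
ten records in one cell count once.

## Diversity surfaces

- Richness and weighted endemism are sums over the presence matrix;
  both satisfy exact mass-conservation identities (Σ richness =
  Σ range sizes; Σ WE = number of species present) which the tests
  assert to 1e-9.
- Complementarity is the classic greedy set-cover heuristic. The
  per-cell scalar needed for correlation and compositing is the *gain
  at selection* (0 for unselected cells): the source analyses correlate
  "the results of the three algorithms" without defining the
  complementarity cell value, and gain-at-selection is the natural
  scalarization that reproduces its characteristically dispersed
  pattern. One cell is selected per iteration; ties go to the lowest
  cell id for determinism.
- Pearson correlations use the t-distribution two-sided p (n − 2 df)
  with no spatial-autocorrelation correction, as in the source scale.
  The verbal bands are half-open on |r|; r = 0 is labelled "none" and
  |r| = 1 closes the top band — both edges fall outside the published
  scale and needed a documented assignment.

## Hotspots

"Standardize" is implemented as min-max to [0, 1] (z-score available),
keeping the three subset contributions commensurable and non-negative;
a constant surface standardizes to zeros. The percentile base is the
set of *occupied* cells, not the whole grid: the published cell counts
(140 at 5%, 476 at 17%) imply a common base of 2800 occupied cells
rather than the 4069-cell grid. The nominal count is
`round(fraction × base)` (half-up) and every cell tying the boundary
score is included — this reproduces the "281 cells at the top 10%, the
280th and 281st tied" overshoot pattern. The hotspot set at a threshold
is the union over the three algorithms (intersection available); Class
I/II/III record three/two/one-algorithm agreement, and priority order
is the ascending sum of dense per-algorithm ranks, ties to the lower
cell id.

A degenerate all-constant composite makes every base cell tie the
boundary, so the selection returns the whole base; this is the
tie-inclusion rule applied consistently rather than a special case.

## Reserve overlay

A cell is protected by a tier iff some polygon of that tier intersects
the cell rectangle with positive area — the contrapositive of "a cell
with no reserve is a gap". Records on a polygon boundary count as
inside with tolerance 1e-9 km. Species-coverage percentages use the
full checklist group totals (all/endemic/threatened) as denominators,
which is what makes printed values like 446/97.38% reproducible;
percentages round half-up, two decimals in tables (one decimal where a
source prints one). Cell-level ("any occupied hotspot cell protected")
and record-level ("fraction of records inside reserves") species
protection are distinct operations, as in the source analyses.

## Climate impact

Binary ranges use strict suitability > 0.6 (0.6 exactly is absent).
Eligibility is ≥ 5 records and AUC ≥ 0.7, both boundaries retained
(only strictly-below excluded). Area is measured in cell counts —
equivalent to km² up to a constant on a uniform grid. Change class
compares current and future cell counts with strict equality for "no
change". LSA bands are exhaustive and mutually exclusive on [0, 1];
EX requires LSA exactly 1. The shift fraction is
(gained + lost)/current — the source never defines the denominator of
"shift covering over 60% of habitat", so this choice is recorded here;
|ΔA|/current can be derived from the returned columns if preferred.
Collinearity pruning visits layer pairs in input order and drops the
later-listed layer, so input order encodes user priority; constant
layers are retained with a warning since their correlation is
undefined. Pruning is idempotent (tested).

## Synthetic world

The generator's defaults state the world the pipeline is tested in:
458 species (264 threatened split evenly 88/88/88 over CR/EN/VU since
the source gives no split, 56 NT, 138 CC; endemism probability
232/458), a 64 × 64 grid of 50-km cells (4096 cells ≈ the 4069 land
cells of a national 50-km grid), 464 NNR + 806 PNR rectangles covering
18% of the extent (a realistic national protected-area share), and 20
equicorrelated environmental layers.

Range sizes come from a truncated discrete lognormal (median 3 cells by
default via `range_size_median`, shape σ = `range_size_shape`, floor 1)
— many narrow, few wide, the rarity structure weighted endemism
assumes; the source states no distribution, so this is a package
choice. Species with target range ≤ `narrow_cutoff` (3) are confined to
one of the planted cluster disks; everything else scatters uniformly.
Each occupied cell gets 1–3 records jittered inside the cell, so
presence, not abundance, carries the signal. Category counts use
largest-remainder rounding (remainder ties broken CR→CC) so the
composition is exactly reproducible.

Suitability is ~0.8 on occupied cells and ~0.2 elsewhere with jitter
bounded away from the 0.6 threshold, so thresholding recovers the
occupied set exactly; the future stack drops `round(loss_fraction ×
range)` in-range cells and lifts `round(gain_fraction × range)` new
cells, which makes the generator's loss fraction recoverable as LSA to
within 1/range — a planted-parameter identity the acceptance tests
assert for every species. Unset loss/gain fractions draw per species
from U(0, 0.9) and U(0, 0.6), giving a mix of contraction and expansion
comparable to published scenario outcomes. AUC values are U(0.75, 0.99)
with `n_low_auc` species planted below 0.7 to exercise the filter.

Every generator derives its random stream from (seed, per-generator
salt), so outputs are pure functions of the config and independent of
call order.

### What a green test does not establish

The synthetic world has rectangular reserves, uncorrelated placement of
wide-ranging species, no coastline clipping, no spatial autocorrelation
in occurrence effort, and planted (not emergent) cluster structure.
Green recovery tests establish that the *operations* implement their
contracts, not that real-data headline numbers would be reproduced —
those depend on a proprietary occurrence database and real reserve
shapefiles.

### Planted-cluster recovery

The cluster-recovery tests instantiate the stated structure (≥ 20
narrow species in one disk, diffuse wide-rangers elsewhere) with
geometry fixed a priori: a Jaccard ≥ 0.8 match against a top-5% set is
only possible when the cluster holds ≈ 5% of occupied cells, hence a
20 × 20 grid with a radius-125-km disk (~20 cells). The top-5%
weighted-endemism set recovers the planted cells at Jaccard ≥ 0.8.
Full Class-I membership of every cluster cell is structurally
unreachable under gain-at-selection complementarity — the greedy cover
skips redundant cluster cells, which then score 0 — so the
whole-pipeline test requires ≥ 90% of planted cells in the consensus
union and a Class-I majority instead.

## Numerical conventions

- Percentages: decimal half-up rounding (never banker's).
- Nominal top-k counts and planted loss/gain cell counts:
  `floor(x + 0.5)`.
- Ties: lowest cell id, everywhere a tie needs breaking.
- Weighted-endemism and richness identities asserted to 1e-9 (they are
  exact in floating point up to summation order).

## Known limitations

- Performance is adequate for national-scale grids (thousands of
  cells); the reserve overlay is O(cells × candidate polygons) with an
  STRtree, not a rasterized overlay.
- `SuitabilityStack` holds dense species × cells arrays; hundreds of
  species on tens of thousands of cells fit easily in memory, global
  rasters would not.
- The complementarity correlation value is a scalarization choice;
  alternative definitions (e.g. selection order) would change the
  correlation bands reported for that surface.
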