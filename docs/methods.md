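# Methods

This note documents the model implemented by `ecozone`, every default
parameter with its rationale, the numerical choices, and the limitations
of the synthetic study-area generator. It is the reference for anyone
auditing a run report or adapting the pipeline to a real study area.

## 1. Raster model

All layers live on a common `GridSpec`: row/column counts, square cell
size in metres, top-left origin, and a projected CRS identifier (default
`EPSG:32650`, UTM zone 50N). Geographic (degree-based) CRS identifiers
are rejected because buffer distances and cell areas are metric.
Layers are `GridLayer` objects with a float or integer array and a
nodata sentinel (default −9999). Every multi-layer operation checks
alignment and raises `AlignmentError` on mismatch; nodata propagates
through all combining operations (a cell missing in any input is missing
in the output).

I/O is plain text: ESRI ASCII grids (`.asc`) with a `.prj` sidecar
holding the CRS id, and GeoJSON for point/line/polygon feature sets.
Integers are written exactly; floats via `repr` so round trips are
lossless to within 1e-6.

### Terrain derivatives

Slope and aspect use Horn's 3×3 finite-difference stencil on an
edge-replicated DEM. Aspect is degrees clockwise from north; cells with
zero gradient get the flat sentinel −1. Slope/aspect are nodata wherever
*any* cell of the 3×3 stencil (including the centre) is nodata. Relief
is the max−min of a square focal window, default **5×5** — at 30 m cells
that is a 150 m neighbourhood, a common scale for local relief; the
window is truncated at grid edges rather than padded, so edge relief is
computed over the cells that exist.

### Distance surfaces

Distances from cell centres to feature sets are exact Euclidean
distances to the nearest geometry (vectorised shapely), not a raster
propagation approximation. Cells inside polygons get distance 0.

## 2. Single-factor classification

Eighteen factors in three groups, each classified to integer levels
1 (non-sensitive) … 5 (extremely sensitive):

| group | factors |
|---|---|
| topographic (6) | elevation, slope, aspect, relief, distance to water areas, distance to water-source protection zones |
| ecological (8) | NDVI, precipitation, soil erosion intensity, soil pH, integrated heavy-metal risk, distance to nature reserves, distance to scenic spots, land-use type |
| human (4) | nighttime light, distance to roads, distance to settlements, distance to industrial sites |

Classifier types:

- **`continuous_jenks`** — five-class Fisher–Jenks natural breaks on the
  factor's own distribution (section 3). `ascending=True` means higher
  raw values are more sensitive (elevation, slope, relief, NDVI,
  precipitation, erosion, heavy-metal risk). **Nighttime light is
  descending**: in a largely undeveloped district the dark cells are the
  undisturbed, sensitive ones, so low radiance maps to high sensitivity.
- **`distance`** — four strictly increasing buffer distances define five
  rings. For protective features (*near is sensitive*) the innermost
  ring is level 5. For roads the coding is mirrored (*far is
  sensitive*): far from disturbance corridors is level 5. Ring
  membership uses half-open intervals closed on the right, i.e. a cell
  exactly at a threshold belongs to the inner ring. Default buffers (m):

  | factor | buffers |
  |---|---|
  | water areas | 30, 60, 90, 120 |
  | water-source protection | 50, 100, 300, 600 |
  | nature reserves / scenic spots | 100, 500, 1000, 1500 |
  | roads / settlements / industrial | 50, 100, 150, 200 |

  These are riparian/protection-corridor widths typical of county-scale
  sensitivity studies; they are configuration, not constants, and can be
  overridden per factor.
- **`categorical`** — lookup table; land use maps forest→5, grassland→4,
  water→3, cropland→2, built-up→1. Unmapped codes become nodata with a
  warning rather than silently inheriting a level.
- **`range`** — closed intervals with an explicit overlap check; soil pH
  uses a V-shaped table (extremes are sensitive): (0,5]→5, (5,6.5]→3,
  (6.5,7.5]→1, (7.5,8.5]→3, (8.5,14]→5. Values exactly on a shared
  endpoint belong to the lower interval.
- **`aspect`** — eight 45° sectors centred on the compass directions,
  north/east-facing slopes more sensitive (levels per sector starting at
  north: 2, 3, 4, 5, 5, 3, 1, 1); flat cells (sentinel −1) are level 1.

A constant layer cannot be split into classes; it classifies to all-1
with a warning instead of failing, so a degenerate input does not abort
a batch run.

### Heavy-metal integrated risk

The heavy-metal factor is the potential ecological risk index over Cd,
Cr, Pb, Cu, Zn, As. Per metal, the contamination factor is measured
concentration over regional background, the single-metal risk is the
toxicity coefficient times the contamination factor, and RI is the sum.
Defaults:

| metal | background (mg/kg) | toxicity |
|---|---|---|
| Cd | 0.119 | 30 |
| Cr | 18 | 2 |
| Pb | 24.6 | 5 |
| Cu | 18.7 | 5 |
| Zn | 57.5 | 1 |
| As | 7.09 | 10 |

A sample exactly at background has RI = 30+2+5+5+1+10 = 53; this is used
as a self-check throughout the test suite. Backgrounds are regional
soil-baseline values and must be replaced when moving to another region.

## 3. Natural-breaks classification

`ecozone.jenks` implements exact Fisher–Jenks optimal 1-D classification
by dynamic programming over **distinct values with multiplicities**
(weighted prefix sums of counts, sums and squared sums), minimising total
within-class sum of squared deviations. Operating on distinct values
guarantees strictly increasing break values even when duplicates
straddle a would-be boundary. The O(k·n²) kernel is numba-compiled.

- Classification convention: class membership is `value ≤ break`, i.e.
  intervals are (lo, hi]; `ascending=False` reverses the level order,
  not the breaks.
- Above **10,000** distinct-bearing cells, a seeded random subsample of
  10,000 values (always retaining the true min and max) is used; the
  achieved goodness-of-variance fit is logged. The threshold keeps the
  worst-case kernel under ~10⁸ DP cell updates (a few seconds) while a
  10,000-point sample estimates quantile structure of a smooth field to
  well under the width of a class.
- Fewer distinct values than classes collapses to the feasible number of
  classes with a warning (a constant input yields one class).

Correctness is tested against an exhaustive search over all
break placements for hundreds of random small instances.

## 4. AHP weighting

`ecozone.ahp` computes weights as the principal eigenvector of the
pairwise-comparison matrix (power iteration, tolerance 1e-12, λ_max via
the Rayleigh quotient), with the geometric-mean method available as a
cross-check. Consistency: CI = (λ_max − n)/(n − 1), CR = CI/RI(n) with
Saaty's random-index table for n ≤ 10. CR > 0.1 raises a **warning**,
not an error — the analyst must see and judge it, but an exploratory run
should not die; the value is recorded in the run report. Matrices larger
than 10×10 are rejected with advice to split the hierarchy, since the
random-index table (and human judgement) does not extend further.
Reciprocal-symmetry violations are reported per entry by
`validate_matrix`.

## 5. Overlay, scores and scenarios

Within each group the five-level rasters are combined by a weighted
overlay Σ wᵢ·levelᵢ (weights positive, summing to 1 within 1e-9), then
cut by **three-class Jenks** into the group comprehensive map coded
1/2/3. Each group is cut independently on its own overlay distribution —
groups are deliberately not forced onto a common scale, so a group's
internal contrast determines its classes. The three group maps sum to a
score grid on 3…9.

A `ScenarioSpec` maps every score 3…9 to one of three zones and is
validated to be **total and monotone** (the zone's protection level
never drops as the score rises), so no custom scenario can interleave
zones. Built-ins:

| scenario | FMCA | SMCA | NMCA | intent |
|---|---|---|---|---|
| `priority_ecological` | 7–9 | 5–6 | 3–4 | strictest control |
| `balanced` | 8–9 | 5–7 | 3–4 | default |
| `development` | 8–9 | 6–7 | 3–5 | most permissive |

By construction the scenarios are nested: FMCA(development) =
FMCA(balanced) ⊆ FMCA(priority_ecological) and NMCA(balanced) =
NMCA(priority_ecological) ⊆ NMCA(development). Zone rasters are coded
3 = FMCA, 2 = SMCA, 1 = NMCA.

`enumerate_combinations` tabulates all 27 ordered group-level triples:
per-sum counts are 1, 3, 6, 7, 6, 3, 1 for scores 3…9, so only 4 of 27
combinations can reach the NMCA scores of the stricter scenarios — the
small non-management share is structural, not empirical.

Area statistics report cells, km² (cells × cell_size² / 10⁶) and
proportions of *valid* area per zone.

## 6. Traditional-method comparison experiment

`ecozone.experiment` implements the comparison against the conventional
single-overlay workflow: each expert supplies within-group factor
weights (validated positive and summing to 1 per group); a panel's
weights are arithmetic panel means; the global weight of a factor is its
within-group weight times the group's share (**equal group shares of 1/3
by default** — the traditional workflow being emulated typically has no
principled between-group weighting, which is precisely its weakness);
one weighted overlay over all 18 level maps is cut by three-class Jenks,
highest class → FMCA. `run_panel_experiment` tabulates zone proportions
per panel next to the group-overlay reference, exposing how much the
traditional result moves when the expert panel changes.

## 7. Synthetic study-area generator

`generate_study_area(SyntheticConfig(...))` produces all 18 input layers,
feature sets, pairwise-comparison matrices and a runnable YAML config
from a single seed (default grid 120×120 at 30 m). One `default_rng`
with a fixed call order makes the bundle byte-identical across runs.

What it emulates: spatially smooth fields (Gaussian random fields,
smoothing σ = 6 cells) with plausible ranges — elevation 100–1500 m
(slope/aspect/relief are *derived* from the DEM, not sampled), NDVI
−0.2–0.9, precipitation 450–700 mm, erosion modulus 0–8, nighttime light
0–63 (8-bit DN scale), pH 4–9.5; log-normal metal concentrations with
median at background (σ_log = 0.4); land use drawn by quantile cut of a
smooth field with a forest-dominated mixture (84 % forest, 7 %
grassland, 0.3 % water, 1.7 % cropland, 7 % built-up); random point/line
feature sets for the distance factors.

What it does **not** emulate: hydrologically consistent drainage, road
networks that follow valleys, spatial correlation *between* factors
(e.g. built-up land near roads), or any real region's statistics. It is
a fixture generator for testing and demonstration, not a landscape
simulator. The bundled pairwise matrices are illustrative Saaty-scale
matrices, not elicited judgements.

## 8. Determinism and reproducibility

Every stochastic step (generator, Jenks subsampling) takes an explicit
seed; `run_pipeline` threads one seed through all stages and records it,
together with resolved weights and AHP consistency, in
`run_report.yaml`. Identical seed + config produce byte-identical output
rasters (verified by hash in the test suite).

## 9. Limitations

- Jenks class boundaries depend on the study area's own distribution, so
  levels are *relative* sensitivity within the area, not absolute; two
  areas classified separately are not comparable level-for-level.
- Buffer distances, pH intervals, land-use levels, aspect-sector levels
  and metal backgrounds are regional judgements supplied as defaults;
  applying them unchanged elsewhere is a modelling decision the user
  must own.
- The subsampled Jenks path is near-optimal, not provably optimal, above
  10,000 values; the logged goodness-of-variance fit quantifies it.
- Zone statistics from synthetic areas illustrate the machinery; they do
  not reproduce any real district's zoning areas, which require the
  original input rasters.
- Horn slope/aspect on the edge-replicated border rows/columns is biased
  toward flat; masked-stencil handling means a single nodata cell
  removes slope/aspect in its 3×3 neighbourhood.
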