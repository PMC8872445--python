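# Methods

This note documents the models implemented in `luces`, the choices made
where the methods literature leaves room, and what the synthetic test bed
does and does not establish about behaviour on real data.

## Raster data model

Land-cover maps are 2-D integer arrays on a fixed nine-class legend
(CL=1, OC=2, FL=3, SL=4, GL=5, BL=6, WB=7, WL=8, BUL=9), with a reserved
nodata code (default −9999), a cell size in metres (default 30 m), row 0 at
the north, and 0-based row-major indexing.  Rasters are treated as abstract
aligned grids: no projection or geotransform is carried, and reprojection /
resampling is out of scope.  Nodata cells are excluded from every area,
matrix, metric and service total, and are never touched by the allocators.
Supported formats are single-band TIFF (cell size and nodata in a JSON
ImageDescription tag) and the ESRI ASCII grid.

## Transfer matrices

`cross_tabulate` counts cells over the joint valid mask only, which makes
the conservation identities exact: row sums equal date-1 class areas and
column sums date-2 class areas on that mask.  Row normalization takes the
identity convention for empty rows (a class absent at date 1 persists), so
probability matrices are always row-stochastic.  Multi-date series are kept
as ordered lists of period matrices; no annualized generator is inferred,
because period matrices are what the projection stage consumes.

## Landscape metrics

Patches are maximal connected components under 8-neighbour connectivity
(the FRAGSTATS convention; 4-neighbour available).  Perimeters count cell
edges against a different class, nodata or the grid boundary, regardless of
the patch-connectivity rule.  PD is reported in patches/km² and MPS in km²
(ha via a flag).  COHESION uses the standard cell-based form

    COHESION = [1 − Σp*ij / Σ(p*ij √a*ij)] / [1 − 1/√A*] × 100

with perimeters in cell edges, areas in cells, and A* the count of valid
cells; it is therefore dimensionless and invariant to cell size, 0 for a
class of isolated single cells and exactly 100 for one patch filling the
landscape.  The landscape area for PD and COHESION is valid cells only.

## AHP suitability

Weights are the principal right eigenvector of a positive reciprocal
pairwise matrix, normalized to sum 1; λmax gives CI = (λmax − n)/(n − 1)
and CR = CI/RI(n) with Saaty's random-index table (orders 1–15).  CR ≥ 0.1
flags the matrix but is not fatal — the caller decides.  A geometric-mean
helper aggregates several experts' matrices (preserving reciprocity), but
individual matrices are user input.

Criterion rasters are graded 4/3/2/1 by half-open interval lookup (a value
exactly at a breakpoint goes to the upper interval — a determinism choice).
Grades normalize as (g−1)/3 and combine as a weighted mean; the class grade
is 4 at score ≥ 0.75, 3 at ≥ 0.5, otherwise 2 — deepened to 1 where some
criterion sits at its worst grade, and forced to 1 under an absolute
exclusion.  The only built-in exclusion is the steep-slope farming ban:
slope ≥ 25° forces cropland to grade 1 regardless of score.  The 0.75/0.5
thresholds and the shipped criterion hierarchy (slope, elevation, pH, and
optionally soil-loss / soil-conservation / water-yield strata) are
documented defaults, overridable in config; grades 2 and 1 both count as
"inappropriate" in area tables.  This aggregation is monotone: improving
any single criterion never lowers a class grade.

The five class grades pack into a five-digit composite code per cell,
digits left to right CL, OC, FL, GL, SL (e.g. 43444).

## CA-Markov

Demand is `start_areas · Pⁿ` (row-vector convention), which conserves the
total exactly for all n.  Spatial allocation integerizes the demanded
areas into cell quotas by largest-remainder rounding (so final counts
match demand within ±1 cell per class, every run), then iterates: at
iteration t of n the interim quota interpolates linearly between the
current composition and the demand (IDRISI-style annual slicing; defaults
10 iterations for hindcast-style runs, 16 for horizon runs).

Within an iteration, only net changes move.  Classes above quota must
release the difference; classes below quota claim it, in descending claim
score

    score_c(cell) = suitability_c(cell) × (f_c(cell) + ε),   ε = 0.01

where f_c is the class-c fraction of the 5×5 Moore window around the cell
(centre excluded; edge windows truncated and normalized by their actual
valid size).  ε keeps zero-neighbourhood cells allocatable, so a class can
seed a new patch, but only after adjacent candidates are exhausted.  Ties
break by a seeded random permutation, then row-major index — deterministic
without systematic spatial bias.  Net-change reassignment was chosen over
re-ranking every cell because it makes three desired properties structural:
a demand equal to the current composition reproduces the input map exactly;
cells keeping their class are never displaced gratuitously; and every
conversion is placed by the target class's own claim score, so conversions
follow suitability dominance.  Classes without a suitability surface (the
atlas covers CL, OC, FL, GL, SL) use a uniform surface unless the user
supplies one.

Validation: kappa = (P₀ − P𝒸)/(P𝓅 − P𝒸) with P₀ the observed cellwise
agreement, P𝒸 = Σ_c (reference share × simulated share), P𝓅 = 1.
Per-class kappa is computed on binary presence maps and reported as
undefined (not 0) for degenerate marginals; overall kappa uses the 9-class
maps.  `validate_hindcast` calibrates on the first interval of a ≥3-date
series and scores the held-out last date; 0.7 is used as the conventional
acceptance bar.

## Ecosystem services

**Water yield.**  Vegetated classes (CL, OC, FL, SL, GL, WL) follow the
Budyko curve: TPE = K𝒸·ET₀, R = TPE/P, w = Z·AWC/P + 1.25,
TAE/P = (1+wR)/(1+wR+1/R), Y = P − TAE.  Open water, built-up and bare
classes (WB, BUL, BL) use the direct clamp TAE = min(K𝒸·ET₀, P) — the
split follows the InVEST convention these equations come from.  AWC enters
w in mm, making w dimensionless.  The K𝒸 table (FL 1.0, SL 0.8, GL 0.65,
CL 0.65, OC 0.75, WL 0.5, BL 0.2, WB 1.1, BUL 0.3) and the seasonal
constant Z = 9.0 are documented defaults, overridable per run; Z raises w
and hence evapotranspiration, so total yield is monotone non-increasing
in Z.  The Budyko ratio lies strictly in (0, 1) for positive inputs, so
0 ≤ TAE ≤ P holds cellwise by construction.

**Soil budget.**  USLE = R·K·LS and RUSLE = R·K·LS·C·P per cell.  LS uses
the Moore–Burch form (A·cell/22.13)^0.4 · (sinθ/0.0896)^1.3 with θ the
Horn slope and A the D8 flow accumulation in cells (each cell counts
itself).  D8 picks the steepest positive drop among the 8 neighbours;
ties take the first neighbour in row-major scan order, border cells never
drain off-grid, and pits/flats do not drain — so routing terminates by
construction and flat terrain gives LS = 0.  Sediment routing processes
cells from high to low elevation: each cell exports its own RUSLE plus any
pass-through; the receiving cell intercepts a per-class retention
efficiency of the arriving load (that interception is SED) and passes the
rest on.  SEDRET = USLE − RUSLE + SED.  Totals: SLO = Σ RUSLE × area(ha),
SC = Σ SEDRET × area(ha).  C, P and retention-efficiency tables are
documented per-class defaults; R and K rasters are inputs, not derived.

**Carbon.**  Stock is per-class density (tC/ha) × class area — composition
only, invariant to spatial arrangement — with the default densities
CL/OC 30.96, FL 150.40, SL 118.42, GL/WL 96.68, BL 10.0, WB/BUL 0.  The
schema accepts a four-pool split (above-ground, below-ground, soil, dead)
summing to the total; the default table carries the aggregate in a single
pool because that is what is published for the worked district.  Because
carbon is composition-only, printed area tables are sufficient inputs, and
the package recomputes the district's stocks as 1713.53 / 1707.39 /
1707.53 × 10⁴ t for 2014 and the two 2030 scenarios.  The published 2014
figure is 1713.54 × 10⁴ t; the 0.013 × 10⁴ t gap is within the rounding
propagation of area inputs printed at 0.01 km² (worst case ≈ 0.027 × 10⁴ t
given the densities), i.e. the original total was evidently computed from
unrounded areas.

## Grey-linear optimization

GM(1,1) fits dx¹/dt + a·x¹ = b on the cumulative series by least squares
with background values z(k) = ½(x¹(k)+x¹(k−1)) and forecasts
x̂⁰(k) = (1−eᵃ)(x⁰(1) − b/a)e^(−a(k−1)); |a| < 1e−12 falls back to the
constant-b limit, so constant series forecast themselves exactly.  The fit
requires ≥ 4 positive observations and reports in-sample relative errors.

The quantity LP maximizes Σ (w_eco·eco_c + w_econ·econ_c)·x_c subject to an
exact total-area equality and per-class bounds (grey forecasts ± tolerance,
policy locks as equalities, optional suitability capacity caps), solved
with HiGHS.  Infeasibility raises with the full bound set listed — no
silent relaxation.  The eco/econ weights default to ½/½ (equal emphasis);
the benefit coefficients shipped in the analysis scripts are documented
placeholders, because no published coefficient table exists for the worked
district — the LP is a faithful skeleton around user-supplied economics,
not a reconstruction of a specific program.

Spatial allocation for the optimized scenario is priority-based: classes
with demanding environmental requirements (default order CL, OC, FL, GL,
SL — ascending suitable area, scarcest first) claim their demanded cell
counts from the highest-suitability unclaimed cells, persistence winning
exact ties via an infinitesimal bonus; remaining classes fill the residual
in descending residual-demand order.  This is the "demanding classes get
the good land first" rule made explicit; it guarantees the priority class
ends with mean suitability at least that of any later class on a shared
candidate pool.

## Synthetic district generator

The generator emulates a mountainous district at 30 m: a Gaussian-smoothed
random field (default kernel width 5 cells) is rank-warped so the three
elevation strata hit fixed shares — plain ≤ 200 m (6 %), hills 200–500 m
(23 %), mountains above (71 %) — between a 80–1500 m range; slope and
aspect come from Horn's 3×3 differences (aspect −1 for flat cells);
precipitation (orographic gradient, ~420–680 mm/yr), reference ET
(~740–1060 mm/yr), AWC, erosivity, erodibility and pH are smooth fields in
realistic ranges.  Initial land cover samples each cell's class with
probability proportional to a per-stratum affinity table (cropland /
orchard / built-up on the plain, shrub/grass on hills, forest/shrub/bare
rock in the mountains).  The series then evolves each cell as an
independent Markov chain under a diagonal-dominant matrix (default
persistence 0.92, off-diagonal mass uniform) — deliberately non-spatial,
so the series is an exact sampling null for transition-estimation recovery
tests, while CA spatial behaviour is tested separately against stated
properties.  One master seed drives everything; per-layer sub-streams are
derived by fixed offsets so adding a layer never perturbs existing ones.

What passing tests on this bed do *not* show: classification error and
mixed pixels (maps are clean), spatially correlated transitions (real
conversion fronts), real hydrology behind R and K, or the economics behind
the LP coefficients.  They do establish the accounting identities, the
closed-form service arithmetic, parameter recovery at scale, conservation
and determinism of both allocators, and hindcast skill when the generating
process matches the model class.

## Problem sizes and determinism

The shipped analyses use a 100×100 district (10⁴ cells) for the
end-to-end pipeline, 350×300 (~10⁵ cells) for transition-recovery studies,
and 20 seeds of 60×60 for the hindcast study — sizes chosen so the full
analysis reruns in seconds while keeping sampling errors well inside the
tested tolerances (binomial 3σ at 10⁴ cells per class is ~0.01 on a
probability entry).  Every stochastic step takes an explicit seed;
identical configs and seeds are bit-reproducible, and the pipeline writes
a manifest (config, seeds, package version) beside its outputs.

## Known limitations

- No georeferencing; inputs must be pre-aligned externally.
- Sediment routing is single-direction (D8) with per-class interception —
  not a connectivity-index SDR; monthly water balance is out of scope.
- The published expert matrices, criterion weights and LP coefficients for
  the worked district are not available; shipped values are labelled
  defaults or placeholders, and the corresponding printed tables are used
  as fixtures rather than re-derived.
- Per-class kappa for classes that are absent (or fill the map) is
  undefined and reported as such.
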