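# Methods

This note records the models, conventions and numerical choices behind
`rangecoder`, and what its synthetic-data tests do and do not demonstrate.

## Geometry

Polygons are planar figures in longitude/latitude degrees; edges are
straight lines in that plane, not great circles. This matches the behaviour
users expect from polygons digitised in a GIS and keeps verdicts independent
of any projection library. Containment uses the even–odd (ray-casting)
rule, so ring orientation (clockwise or counter-clockwise) is irrelevant and
self-consistent verdicts are produced even for hand-digitised rings.

Conventions that the file formats cannot express and therefore live here:

* **Boundary points are inside**, with a tolerance of 1e-9 degrees
  (~0.1 mm at the equator) measured as planar distance to the nearest edge
  or vertex. This makes grid-aligned data deterministic: a point on an edge
  shared by two units is coded into both.
* **Longitude normalization** maps any finite value into [−180, 180] modulo
  360; values congruent to ±180 map to +180. Polygon vertices already inside
  [−180, 180] are kept verbatim, so rings touching the anti-meridian at
  −180° remain valid.
* **Anti-meridian crossing polygons are rejected** (any edge spanning >180°
  of longitude) with a message asking the user to split them: planar
  semantics across the date line are ambiguous and silently "wrapping" would
  invert the intended region.
* Holes (multi-ring polygons) are not supported; a single outer ring only.

A bounding-box prefilter guarantees only that `False` means "outside"; an
instrumented edge-test counter exposes that total work grows linearly in
points × polygons × vertices, which is the property that makes very large
occurrence sets tractable.

## Input formats and row accounting

Occurrence tables are tab-separated with header `species`, `latitude`,
`longitude` (case-insensitive), or the GBIF archive dialect
(`decimalLatitude`/`decimalLongitude`, extra columns ignored). Because
downstream conclusions depend on what was *excluded*, readers never coerce
silently: each rejected row is counted under a reason (`missing species`,
`missing coordinate`, `unparseable coordinate`, `latitude out of range`) and
accepted + rejected always equals the number of input rows. Species names
are matched exactly after whitespace trimming and internal-whitespace
collapse; no fuzzy synonym resolution is attempted.

The unit-definition dialect is this package's own (one unit per line:
`name TAB lon,lat pairs TAB min:max`), since no standard text dialect exists
for named polygons with elevation bands; GeoJSON FeatureCollections with a
`name` property are accepted as an interoperable alternative. Shapefiles
are deliberately unsupported (binary sidecar files); GeoJSON fills that
role for both polygon input and point export.

Elevation rasters use the ESRI ASCII grid; sampling is nearest-cell, and a
coordinate exactly on a cell boundary belongs to the cell to its north-east
(the deterministic result of floor indexing with row 0 northernmost).
Points outside the raster, or on nodata cells, have *missing* elevation:
they are excluded from banded units only (never from purely spatial ones)
and counted in the run log.

## Coding semantics

* **Elevation bands are half-open, [min_m, max_m).** Two units that split a
  polygon at 1000 m then partition it exactly: a record at 1000 m falls in
  the 1000:6000 highland unit, not the 0:1000 lowland one. The closed-band
  alternative would double-code every record sitting exactly on the split.
* Units may overlap; an occurrence contributes one count to every unit that
  contains it. Reduction to a single state per species happens only where a
  single-character model requires it (see mapping).
* Species order everywhere is first appearance in the input — reproducible
  without imposing any taxonomy.
* The presence threshold *t* (default 1) doubles as an outlier screen:
  counts in [1, t) are reported as candidate misplacements (e.g. a
  latitude/longitude swap).
* The coexistence matrix refuses data sets of ≥ 40 species: it is a
  small-set inspection tool, and the quadratic output stops being readable.

## Sensitivity test

Model: each occurrence is independently misidentified with probability
*r*; misidentified records are **removed**, never reassigned to another
species (cross-contamination is out of scope). Replicates re-draw every
occurrence each time; the RNG is a named, seeded generator
(`numpy.random.default_rng`) recorded in all outputs. Defaults —
r ∈ {0.05, 0.10, 0.25, 0.50} and 10,000 replicates — are the standard
configuration of this test. "Changed" means any cell of the species' 0/1
row differs from the full-data coding; since removal cannot create
presences, this equals "lost at least one coded unit". Replicates drop
records from the precomputed membership rather than re-running
point-in-polygon (mathematically identical, much faster). The reported
spread of affected-species counts is the sample standard deviation
(ddof = 1) over replicates.

For disjoint units the change probability is exactly
`1 − Π_{u: k_u ≥ t} P(Binom(k_u, 1 − r) ≥ t)`; this closed form is the
oracle the Monte-Carlo path is calibrated against in the tests, and it
refuses overlapping-unit data (where unit losses are not independent).

## Mk model and stochastic mapping

The character is the operational unit a species occupies; evolution is a
continuous-time Markov chain with generator **Q** on a dated, ultrametric
tree (checked to 1e-6 relative tolerance, offending tip pair named).
Structures: ER (one rate; default, identifiable on small trees) and ARD
(k(k−1) rates). The root prior is uniform 1/k. Likelihood is computed by
Felsenstein pruning with per-node rescaling; transition matrices come from
an eigendecomposition of **Q** applied to all branch lengths at once, with
a dense `expm` fallback when the eigenvector matrix is ill-conditioned
(condition number > 1e8). Fitting maximises the log-likelihood over
log-rates bounded in [1e-9, 1e3] events/Myr (bounded scalar minimisation
for ER, L-BFGS-B for ARD, started from the ER optimum and never reported
below it since ER nests in ARD). With all tips in one state the rate is
unidentifiable; the lower-bound model is returned with a warning.

Multi-unit species are reduced to the unit with their maximum occurrence
count, ties broken by lexicographically smallest unit name, all-zero
species dropped with a warning — a documented convention, not an inference;
a power-set (DEC-style) state space is explicitly out of scope. Tips absent
from the coding (or species absent from the tree) are reported and dropped,
and the tree is pruned accordingly.

Mapping samples node states from their exact joint conditional distribution
(root from its posterior, then pre-order conditional draws using the stored
pruning partials), then samples each branch path conditional on its
endpoint states. Path sampling is by rejection (forward simulation until
the endpoint matches), switching to an exact uniformization sampler either
after 1,000 rejected attempts or immediately when the expected uniformized
jump count μ·t exceeds 5 (where rejection is near-certain wasted work; both
samplers draw from the same endpoint-conditioned distribution). The
uniformization route truncates the Poisson number-of-jumps distribution at
the 1−1e-12 quantile. The analytic cross-check — the conditional expected
number of state changes — is computed by an independent truncated
uniformization series (`expected_transitions`), sharing no code with the
sampler.

## Dispersal counting

A transition A→B at age *a* falls in bin ⌊a / w⌋ (default w = 10 Myr), so
bins are lower-inclusive from the present and an event exactly at a bin
edge belongs to the older bin. Lineage counts use bin midpoints, with each
branch occupying the age interval (child age, parent age] — closed at the
older end — so a bifurcation at exactly the midpoint contributes its two
daughters, not the parent. Relative dispersal divides the absolute count by
the midpoint lineage count and is **undefined (NaN), not zero**, in bins
older than the root. Across trees and maps, means and sample standard
deviations are reported over all (tree × map) samples.

## Synthetic data

The generators produce: globally uniform localities (uniform in lon/lat
*degrees*, not equal-area — the aim is exercising the geometry, not
geographic realism); grids of square units sharing two corners with each
neighbour; a square densified to any vertex count (same region, more
edges); linear west→east elevation ramps; ultrametric constant-rate
birth–death trees (simulation stopped uniformly within the interval during
which exactly n lineages are alive, extinct lineages pruned); and exact
forward CTMC simulations that retain their full event logs.

All generators are pure functions of (parameters, seed). Benchmark-style
sizes default to 10¹–10⁵ in tests; nothing prevents larger runs, but they
prove throughput, not correctness.

What passing tests show — and do not. The synthetic data have no
coordinate uncertainty, no spatial sampling bias, no taxonomic synonymy and
no correlated misidentification; calibration results therefore validate the
*algorithms* (geometry, thresholding, resampling, likelihood, path
sampling, binning), not the fitness of any particular empirical dataset.
The rate-recovery experiment uses 500-tip trees scaled to a root age of
25 Myr with a true rate of 0.1 events/Myr, i.e. ~200 expected character
changes per tree — enough information that the 25 % recovery criterion
tests estimator correctness rather than simulation luck.

## Known limitations

* Planar geometry only; no spherical polygons, no reprojection (WGS84
  lon/lat assumed), no polygons with holes, no anti-meridian-crossing
  rings (split them).
* GeoTIFF rasters are not read; convert to ESRI ASCII grid.
* The Mk machinery assumes ultrametric trees (no fossil tips) and a single
  occupancy state per species; range-evolution models with joint ranges
  (DEC, DEC+J) are out of scope.
* The coexistence matrix is limited to < 40 species by design.
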