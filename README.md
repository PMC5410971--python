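# rangecoder

Fast, reproducible coding of geo-referenced species occurrences into
user-defined **operational units** — named polygons, optionally intersected
with an elevation or depth band — plus the downstream analyses that coding
feeds: presence/absence matrices for ancestral-range reconstruction,
biodiversity summary statistics, a Monte-Carlo test of how specimen
misidentification would perturb the coding, and dispersal-through-time
curves obtained by stochastic character mapping on dated phylogenies.

It is aimed at biogeographers and systematists who hold a table of
occurrence records (their own, or a GBIF download), a set of polygons
digitised in a GIS, and optionally a dated tree, and who need the species ×
area 0/1 matrix that programs for historical biogeography consume — together
with an audit trail of every record that was accepted, rejected or flagged.

## What it computes

**Coding.** Each occurrence *(species, latitude, longitude)* is tested
against every unit polygon with a planar even–odd (ray-casting)
point-in-polygon test (boundary points count as inside, tolerance 1e-9°);
with an elevation band *(m_min, m_max)* the nearest-cell raster elevation
*e* must also satisfy m_min ≤ e < m_max. Counts *n(s,u)* become presences
via a threshold *t* (default 1): *P(s,u) = 1 iff n(s,u) ≥ t*. Counts with
*1 ≤ n(s,u) < t* are flagged as candidate outlier localities. Summary
statistics: species per area, occurrences per species per area, and relative
occurrence *n(s,u)/Σ_u n(s,u)*; for < 40 species, a per-unit species ×
species coexistence matrix.

**Sensitivity.** Every occurrence is removed independently with probability
*r* (default r ∈ {0.05, 0.10, 0.25, 0.50}) and the coding recomputed, 10,000
times; a species is *affected* when its 0/1 row changes. For disjoint units
this has the exact form *P(change) = 1 − Π_u P(Binom(k_u, 1−r) ≥ t)*, which
the Monte-Carlo machinery is verified against.

**Dispersal.** Tip states (one unit per species, majority rule) evolve under
a k-state Mk model with generator **Q** (equal-rates by default), fitted by
maximum likelihood via Felsenstein pruning. Stochastic mapping samples full
character histories conditional on tips and **Q** (node states from the
joint conditional distribution; branch paths by rejection sampling with an
exact uniformization sampler for hard branches). Transitions A→B at age *a*
are counted in 10-Myr bins (*⌊a/10⌋*), absolutely and relative to the number
of contemporaneous lineages.

## Worked example

`examples/02_sensitivity.py` builds three species with known per-unit
occurrence counts — `widespread` (5 + 4 records in two units), `narrow`
(2 in one unit), `rare` (a singleton) — and runs the sensitivity test:

```
Per-species change frequency over 10,000 replicates (vs exact):
  widespread    r=0.05: 0.0000 (0.0000)  r=0.10: 0.0001 (0.0001)  r=0.25: 0.0045 (0.0049)  r=0.50: 0.0917 (0.0918)
  narrow        r=0.05: 0.0023 (0.0025)  r=0.10: 0.0101 (0.0100)  r=0.25: 0.0646 (0.0625)  r=0.50: 0.2477 (0.2500)
  rare          r=0.05: 0.0501 (0.0500)  r=0.10: 0.0994 (0.1000)  r=0.25: 0.2526 (0.2500)  r=0.50: 0.4981 (0.5000)

Mean +- sd of affected species per error rate:
  r=0.05: 0.052 +- 0.223
  ...
```

A singleton's coded range is lost exactly with probability *r* (0.0501 vs
0.05); the well-sampled species barely moves until *r* is large. The number
in parentheses is the closed-form probability the simulation is checked
against. The other examples cover the coding pipeline (`01`), stochastic
mapping and dispersal curves (`03`), and the CLI workflow (`04`).

## Command line

```sh
rangecoder code occ.tsv units.tsv [--gbif] [--elevation dem.asc] [--threshold 2] -o out
rangecoder sensitivity occ.tsv units.tsv --reps 10000 --seed 1 -o out
rangecoder dispersal occ.tsv units.tsv trees.nwk --model ER --nmaps 100 --bin 10 --seed 1 -o out
rangecoder simulate localities|grid|elevation|trees -o fixtures
```

Input dialects (all tab-separated, documented in `docs/methods.md`):
occurrence tables with header `species/latitude/longitude` or the GBIF
`species/decimalLatitude/decimalLongitude` dialect; unit files with lines
`name<TAB>lon,lat lon,lat ...<TAB>min:max` (the elevation band is optional;
`-30:0` codes a 0–30 m depth range) or GeoJSON polygons with a `name`
property; ESRI ASCII elevation grids; Newick trees, one per line. Outputs:
a NEXUS presence/absence matrix (`DATATYPE=STANDARD`, `SYMBOLS="01"`),
TSV summary/sensitivity/dispersal tables, a GeoJSON export of all in-unit
localities, and a machine-readable `run_log.json` with seeds, versions and
row-level rejection accounting; exit codes are 0 (success), 1 (runtime
failure), 2 (usage/validation error).

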