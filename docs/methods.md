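# Methods

## Problem and model

Regionalized life-cycle impact assessment provides land-occupation
characterization factors (CFs) at the ecoregion scale, in units of
potentially disappeared fraction of species per km² of occupied
cropland (PDF/km²), separately for Annual and Permanent cropland.
Country-scale analyses — in particular environmentally extended
multi-regional input–output (EE-MRIO) studies — need one CF per
(country, crop). This package implements and contrasts two upward
aggregation estimators over the polygons formed by intersecting the
political layer with the ecoregion layer:

* **flow-weighted** (crop-specific): the CF of crop *j* in region *x*
  is the production-weighted mean over polygons *i*,

  LC_jx = Σᵢ ( P_ijx / Σᵢ P_ijx ) · C_ix ,

  where P_ijx is the physical production area (km²) of crop *j* in
  polygon *i* and C_ix the native CF of the polygon's ecoregion for the
  crop's land-use type;
* **area-weighted** (baseline): the ecoregion land-share weighted mean
  per (region, land-use type), broadcast to every crop of that type —
  the aggregation used by regionalized LCIA databases when no
  production-location data are available.

Both are convex combinations of native CFs. When production is
proportional to polygon area they coincide; when cropland concentrates
in ecologically sensitive (high-CF) ecoregions — the pattern of
northern temperate countries, where agriculture and species richness
crowd into the same southern fraction of the territory — the
flow-weighted CF is strictly larger.

Aggregated CFs enter a Leontief model as the characterization matrix C
(one column per region/sector, rows per region/crop stressor).
Pressure accounts are E = S L y (consumption perspective, by consuming
region) and F = S diag(x) (production perspective); biodiversity
accounts are D_cba = C ⊙ SLy and D_pba = C ⊙ F in PDF·yr. Direct
pressures of final demand are excluded: the accounts cover production
serving final demand. On a balanced system x = Z·1 + y·1 implies
x = L(y·1) and hence ΣD_pba = ΣD_cba globally; this identity is a
standing test.

## Missing-data rules

Native CF tables have gaps. The rules, in order:

1. **Nearest same-realm, same-biome proxy.** A gap ecoregion that
   carries crop production of the affected land-use type receives the
   CF of the nearest ecoregion sharing both realm and biome that has an
   observed CF. "Nearest" is the Euclidean distance between ecoregion
   centroids (the source data do not define a metric); ties go to the
   smaller ecoregion id and are logged. The alternative rule — the
   unweighted mean of all touching neighbours' observed CFs — is kept
   as a validation route, and `compare_proxy_methods` reports the
   per-(region, crop) relative difference between the two.
2. **Treat-as-zero exclusion.** Gap ecoregions without crops (and gaps
   the proxy could not resolve) are excluded from both the numerator
   and the normalizer of the weighted mean; the renormalization over
   characterizable polygons is recorded in the output table's metadata,
   and the `coverage` column reports the characterized fraction of the
   weight. A (region, crop) with positive production and nothing
   characterizable is a hard error, never a silent zero.
3. **Alias-then-continent fallback.** A region with no aggregate at all
   takes an aliased region's CFs if an alias is configured, else its
   continent's CF recomputed with the same estimator over the pooled
   member polygons (not by averaging national CFs, so the estimator is
   identical at both scales). Provenance is recorded per row.
4. **Marginality diagnostic.** Per (region, crop), the fraction of crop
   area lying in proxied ecoregions; flagged strictly above 3%, the
   level above which the proxy assumption stops being a marginal
   correction.

Zero-production (region, crop) pairs receive the area-weighted CF with
coverage 0 rather than NaN, so characterization matrices stay dense.

## Units

The internal CF unit is PDF/km². PDF/m² input is supported through an
explicit conversion flag (×10⁶, exact in floating point); pressure
accounts must be in km² before characterization, and a mismatch raises
rather than silently mixing scales.

## Synthetic worlds

The generator produces the statistical structure the analysis assumes,
so every stage is testable offline:

* **Grid.** Regions are planar x-bands, ecoregions y-blocks within
  them; each (region, ecoregion) block receives a fixed number of cells
  with log-uniform areas over [10, 1000] km² (deliberately unequal
  ecoregion areas). Coordinates are abstract and planar: the
  nearest-neighbour rule needs a metric, and geodesy adds nothing at
  this scale. Ecoregion adjacency (for the touching-average rule)
  follows shared block edges.
* **Native CFs.** Lognormal around 10⁻⁹ PDF/km² (σ = 1) with a shared
  per-ecoregion sensitivity so the Annual and Permanent factors of an
  ecoregion are correlated. The magnitude anchors to cropland
  land-occupation endpoint factors, which reach order 10⁻¹⁴ PDF/m²
  (10⁻⁸ PDF/km²) in the most sensitive regions; the lognormal shape is
  a modeling convenience, not an empirically fitted distribution.
  Realm labels cycle by region and biome labels with period 2 within a
  region, so realistic proxy candidates (and some genuinely unresolvable
  gaps) both occur. Gaps are drawn only among ecoregions that are not
  their region's sole ecoregion, keeping every region characterizable.
* **Production.** Per region, 30% of the land area is cropland, split
  across crops by a seeded Dirichlet. Cells receive production with
  weight area × exp(4 · concentration · z), with z the rank-normalized
  ecoregion CF of the crop's land-use type: `concentration = 0` gives
  allocation exactly proportional to cell area, `concentration = 1`
  makes production density strictly increasing in the ecoregion CF (the
  one-knob reproduction of the concentration pattern). Totals are
  rescaled per region if any cell would exceed 90% of its area, which
  preserves all share structure. An optional lognormal per-cell jitter
  (`production_noise`, default 0) roughens the allocation.
* **MRIO.** One sector per crop plus an aggregate rest-of-economy
  sector per region, mirroring product-resolved crop stressors at
  minimal size. Crop-sector prices are powers of two so that
  S·diag(x) reproduces the generated crop areas exactly in floating
  point. Random technical coefficients have column sums below 0.6
  (spectral radius < 1 by construction); rows whose implied final
  demand would fall below 2% of output are damped, with a bounded
  number of halvings before a hard error. Final demand is split across
  consuming regions by a seeded Dirichlet with an exact-sum closure on
  the last column.

What the generator does **not** emulate: real country or ecoregion
shapes, farming-system disaggregation of the gridded crop data,
price heterogeneity and trade structure of a real MRIO, or any
empirical CF distribution. Passing tests therefore demonstrate the
correctness of the estimators, rules and accounting identities — not
the magnitude of real-world footprints, which depend entirely on the
external databases.

## Numerical choices

* Aggregations are weighted means computed per (region, crop) group;
  group sums in mass-conserving paths (production allocation, crop
  concordance) use compensated summation (`math.fsum`), so each group
  total is the correctly rounded sum of its members and conservation
  can be asserted exactly at group granularity.
* The Leontief inverse is a dense linear solve of (I − A)X = I, never
  an explicit inverse; spectral radius ≥ 1 raises a
  non-productive-economy error.
* Cell-to-polygon allocation is whole-cell by centroid (the source
  raster's granularity does not support sub-cell splitting); a centroid
  exactly on a shared boundary goes to the lexicographically smallest
  polygon id, logged. Invalid geometries are repaired by zero-width
  buffering; unrepairable or empty features are hard errors, because
  silently dropping features corrupts land shares.
* Percent changes are computed on PDF·yr totals only; a zero baseline
  yields a flagged undefined row with the flow value preserved, never a
  crash or a dropped row. CF-level distribution summaries (quartiles
  across regions per crop and method) are a separate output.
* All randomness flows from a single integer seed through fixed
  per-stage substreams, so every layer and every downstream artifact is
  byte-for-byte reproducible for a fixed spec.

## Default problem sizes

Tests and the acceptance script run worlds of 1–4 regions, 1–4
ecoregions per region and 1–10 cells per ecoregion (≤ 16 polygons,
≤ 8 crops), with oracle sweeps over ~50–120 random worlds. These sizes
exercise every code path — degenerate single-cell worlds up to
multi-region systems with gaps, proxies and fallbacks — while keeping
the whole suite in the order of seconds.

## Known limitations

* Pasture cropland and land-transformation impacts are out of scope;
  only land-occupation for Annual and Permanent cropland is
  characterized. Blue-water consumption is likewise not covered.
* The touching-average proxy needs an externally supplied adjacency
  edge list for real data; the synthetic world derives it from its
  block layout.
* The EXIOBASE-style loader surface is limited to the package's own
  CSV dialect; real MRIO ingestion requires reshaping to that dialect.
* The packaged source-crop concordance is a plausible default, marked
  unverified row by row; analyses of real data should supply an audited
  table.
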