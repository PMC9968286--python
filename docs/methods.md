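# Methods

This note documents the models implemented in `liveability`, the defaults
and why, the synthetic data the tests run on, and the numerical choices
made where the design was genuinely open.

## Geometry and units

All geometry is planar with coordinates in metres (a local projected frame
of the kind national studies use, e.g. an equal-area conic); no geodesy is
implemented, since every measure is a metric network-length or area
quantity. Lengths are metres, areas m² (reported as hectares or km² where
the indicator is defined that way), and network distances are stored as
integer metres, rounded half up, matching how published distance arrays are
typed.

## Pedestrian network model (`pednet`)

The network is an undirected graph whose edges carry polyline geometries
and lengths. Parallel edges between one node pair keep the shorter for
routing. Connected components are labelled; anchors (addresses,
destinations, open-space entry points) are the nearest point on the nearest
edge, with ties broken by smallest edge id and no maximum snap distance —
extreme snaps are logged, and validity is governed by the exclusion rules,
not by snapping.

**Intersections** are nodes of degree ≥ 3, clustered by single linkage
within a 12 m tolerance and replaced by cluster centroids. Dead ends and
pass-through (degree ≤ 2) nodes never contribute. Single linkage at a
fixed threshold (implemented as union–find over a k-d tree's within-radius
pairs) is exactly the "merge everything within the tolerance window to its
centroid" behaviour of standard network-simplification tools; the 12 m
default is the tolerance urban street-network studies in Australian
settings settled on after sensitivity analysis across city morphologies.
Whether "intersections" should count all simplified nodes or only degree
≥ 3 nodes is not uniquely defined in the literature; degree ≥ 3 is used,
matching common connectivity practice and the `dead_ends=False` convention
of the consolidation tools.

**Walkable catchments** take every edge portion within 1600 m network
distance of the anchor (frontier edges clipped linearly at the residual
distance; an edge is fully reached when the residual reach from its two
endpoints covers its length), then buffer the reached sub-network at 50 m
with round caps and joins. For an anchor on an isolated straight line the
area follows the closed form 2·L·w + π·w² with L the total reached length,
which the tests verify to 0.5%. A catchment below 16.5 ha — slightly less
than the ≈ 16.8 ha of a single bare 1600 m path — is implausible for a real
urban address and flags invalid network topology. Dwelling density counts
whole mesh blocks that intersect the catchment polygon (no areal
interpolation, boundary touch included) per catchment hectare; street
connectivity counts consolidated intersections inside or on the polygon
per km².

## Accessibility (`access`)

Distance arrays record all destinations of a category within 3200 m (twice
the walkable catchment) sorted ascending, plus the closest destination
computed without cutoff. Arrays for transit stops use an 800 m cutoff and
carry stop ids. Where one concept has two independent sources (supermarkets
from a mapped source and a web-scraped chain list), the closest estimates
are pooled by row-wise minimum, treating null as unreachable; pooled arrays
refuse count-within queries so destinations are never double counted.
Count-within and hard-threshold comparisons are inclusive (≤).

The soft threshold is the logistic s(d) = 1/(1 + exp(k(d − T)/T)) with
k = 5: 0.5 at the threshold, ≈ 0.99 at d = 0, ≈ 0.007 at 2T. The
steepness is exposed as a parameter; k = 5 is the conventional default of
the soft-threshold accessibility literature. Unreachable (null) distances
score 0 rather than propagating nulls, so category means stay defined;
pathological addresses are handled by the exclusion rules instead.

## Open space (`open_space`)

Raw tagged polygons dissolve into areas of open space (AOS) by spatial
connectivity (union–find over pairwise intersection, so abutting parcels
merge). Public geometry is the union of public-tagged parts minus
restricted sub-areas; water geometry is the union of water-tagged parts.
Amenities within 100 m (Euclidean, of the overall geometry) are attached as
co-located. Entry points sample each public exterior ring at 20 m
arc-length intervals starting from the stored ring start vertex (no
duplicate sample at ring closure) and are retained when within 30 m of a
network edge; the 30 m test is Euclidean point-to-edge distance — the
along-network alternative is not used — and the gap is configurable. An
address's AOS access list keeps, per AOS within 3200 m, the minimum network
distance over that AOS's entry points; an address inside a park still
routes to a boundary entry point. Typology queries follow the published
notation exactly: area bounds are strict ">" and inclusive "≤". The large
public open space indicator requires > 1.5 ha public area, scored at 400 m.

## Transit (`transit`)

Per stop and weekday within the analysis window, the daily headway is the
mean gap between consecutive departures whose endpoints both lie in the
closed daytime window 07:00–19:00; the stop's mean headway averages daily
means over days with ≥ 2 such departures (days served is configurable,
default ≥ 1). Averaging within day and then across days — rather than
pooling all gaps — follows the tidy-transit headway workflow granularity
and is order-independent; the alternative pooled reading is noted here as
the open choice. A stop is regular when the mean headway is ≤ 30 minutes
(boundary inclusive). The address indicator filters the 800 m stop array
to regular stops and scores the closest at 400 m.

## Sub-indicators and walkability (`indicators`)

The destination registry fixes the category members and thresholds
(metres): community/culture/leisure — community centre 1000, cinema/theatre
3200, library 1000, museum/gallery 3200; education — state primary 1600,
state secondary 1600; health — aged care, pharmacy, community health,
dentist, GP, maternal/child health, all 1000; sport/recreation — swimming
pool 1200, sport facility 1200; early years — quality-flagged childcare 800
and out-of-school-hours care 1600 (the quality requirement is a boolean
attribute on destination points); food — fruit/vegetable 1000,
meat/seafood 3200, supermarket 1000; convenience — convenience store 1000,
newsagent 3200, petrol station 1000. The first five categories contribute
the 16 members of the social-infrastructure mix.

Scoring defaults to soft for index inputs and is switchable to hard
per call; percent-meeting area indicators use hard splits. Walkability is
the sum of component z-scores (population SD) of dwelling density, street
connectivity and daily living access, standardised within city or pooled
nationally; daily living uses soft member scores inside the index for
consistency with the other index inputs, with hard mode exposed.

## Urban Liveability Index (`uli`)

Pipeline per scope (each city separately, or all addresses pooled):
polarity alignment (housing stress negated so larger means more
affordable), per-column conditional capping, per-column normalisation to
mean 100 / SD 10 using the population SD (so the moment contract is exact),
then per row ULI = M − S²/M.

The capping rule is applied independently per tail using the pre-capping
mean and SD in a single pass: only if a tail has a value beyond 3 SD are
that tail's values beyond 2 SD linearly mapped so the extreme terminates
exactly at 3 SD; values within 2 SD are left bit-identical and rank order
is preserved. Of the readings the compressed published wording admits
(winsorising; post-cap moments; cap-then-normalise order), this linear
pre-cap-moments reading is pinned and test-covered; capping operates on raw
columns before normalisation. Binary sub-indicators pass through the same
pipeline; with two levels the cap condition cannot trigger.

A reference address "at the standardisation-scope mean" is defined at the
normalisation step, i.e. against post-capping column means. Because
appending the reference row itself perturbs the pre-capping moments,
`uli.scope_mean_row` computes it as the fixed point of v → post-capping
column means with v appended (a contraction of order 1/n); its composite
score is then exactly the benchmark 100. When capping does not trigger
this reduces to the plain column means.

## Exclusions, aggregation and export (`aggregate_export`)

Exclusion priority is not-urban (mesh block not urban or zero dwellings) →
no disadvantage index at SA1 → invalid topology (catchment < 16.5 ha, or
null neighbourhood results), with each address counted once, so the tally
rows are disjoint and sum to the total; percentages recompute from counts,
rounded half-up to two decimals to match the published formatting.
Mesh-block summaries are unweighted means over included addresses (nulls
averaged out, counts reported); larger scales aggregate mesh-block
summaries — not raw addresses — with dwelling (default) or person weights,
which makes aggregation telescope exactly: city values computed from SA1
summaries equal those computed from mesh blocks to 1e-9. Exports write the
published shapes (CSV/PSV/TSV, WKT geometry columns, empty string for
null) with a machine-readable data dictionary per file.

## Synthetic city (`synthetic_city`)

The generator emulates the input data model of a national liveability
study at desk scale, seeded and deterministic (equal seeds give
byte-identical fixture sets):

* Street grid of `grid_rows × grid_cols` cells at 200 m spacing (12 × 12
  default — a 2.4 km city, larger than the 1600 m catchment so location
  matters); mesh blocks are the cells, with 30–60 dwellings each (the
  typical mesh-block size), and SA1…SA4/suburb/LGA codes formed by
  recursive 2×2 unions so the hierarchy nests exactly.
* 400 addresses by default, placed inside blocks with probability
  proportional to dwellings.
* Destination counts per category default to 3–10 points; half of each
  category concentrates in a designated "activity centre" district (the
  top-left ninth of the grid, which also draws dwellings from the upper
  half of the range) — cities have such districts, and the contrast gives
  the parameter-recovery tests a known signal.
* Open-space parcels in ~12% of cells, 0.35–0.95 of the cell side
  (≈ 0.5–3.6 ha, straddling the 1.5 ha threshold), including one pair of
  abutting halves (exercises dissolving), one park with a restricted inner
  parcel, occasional water sub-areas, sport tags and boundary toilets.
* Transit: three routes (bus 15 min, tram 25 min, train 45 min headways,
  spanning the 30 min regularity boundary) over the spring-term window
  2019-10-08 to 2019-12-05; weekday departures 07:00–19:00 at the fixed
  headway, weekend service at 3× the headway so wrong day-filtering is
  detectable.
* Pathological features on purpose: two zero-dwelling blocks, two
  non-urban blocks, one SA1 without the disadvantage index, and a
  configurable fraction of addresses (2% default) on a street segment
  placed > 3200 m from the main network, so every exclusion rule fires.
* SA1 covariates: housing stress U(5, 35)%, local employment U(20, 80)%,
  disadvantage index N(1000, 50) — realistic ranges for small-area census
  covariates.

What the generator does **not** emulate: realistic street morphology
(everything is a grid), destination co-location patterns, OSM tag
vocabulary beyond category labels, population synthesis beyond counts, or
GTFS complexities (transfers, frequency-based trips, timezones). Passing
tests therefore demonstrate correctness of the measures and their
compositional properties on a faithful *data model*, not calibration
against any real city's values — the published national indicator values
require the original national inputs and are out of scope.

## Problem sizes and determinism

The test suite uses an 8 × 8-grid city with 150 addresses for integration
tests and a default-grid city with 500 addresses for the composite-index
checks; the acceptance script uses the 500-address city, a 1,000 × 13
synthetic matrix for the normalisation moments, and 100 random columns for
the capping bound. These sizes keep a full run in tens of seconds while
leaving every structural feature (hierarchy depth, disconnection,
district contrast) intact. All randomness flows from explicit seeds;
property-based tests are derandomised.

## Known limitations

* Routing is undirected and unimodal; no turn restrictions, elevation or
  travel-time weighting.
* The 30 m entry-point proximity rule is Euclidean, not along-network.
* Street connectivity counts intersections of the consolidated set only;
  alternative intersection definitions change its scale.
* `pool_closest` pools closest distances, not full arrays; pooled
  count-within queries are deliberately refused.
* Percentages in the exclusion tally round half-up at two decimals, so
  printed percentages of sub-groups need not sum exactly to their parent
  row.
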