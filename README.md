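# liveability

Address-level built-environment liveability indicators for urban health
research: from a city model — pedestrian street network, residential address
points, mesh-block census counts, destination points, areas of open space
and a transit schedule — to walkable-catchment measures, destination
accessibility scores, composite walkability, the variance-penalised Urban
Liveability Index (ULI), and dwelling-weighted small-area aggregates.

The package is aimed at spatial epidemiologists and urban-planning
researchers who need reproducible, testable implementations of these
measures. Because the national inputs such measures are usually computed
from (geocoded address files, OpenStreetMap extracts, census tables, GTFS
feeds) are large and external, the package ships a deterministic
synthetic-city generator that emulates their statistical and structural
properties, so the entire pipeline runs and is tested without any download.

## The measures

**Walkable catchment.** For each address snapped to the pedestrian network,
the sub-network reachable within 1600 m is buffered at 50 m (a "sausage
buffer"). Catchments smaller than a plausible minimum of 16.5 ha indicate
broken network topology and exclude the address. On the catchment:
dwelling density (dwellings of intersecting mesh blocks per hectare) and
street connectivity (consolidated intersections per km²; intersections are
degree ≥ 3 nodes clustered by single linkage within 12 m).

**Access scores.** Network distances to all destinations of each category
within 3200 m are recorded, plus the closest regardless of cutoff.
Distance *d* against a threshold *T* is scored either hard
(1 if *d* ≤ *T*) or soft,

    s(d) = 1 / (1 + exp(k (d − T) / T)),   k = 5,

which equals 0.5 at the threshold. Category scores average their members
(e.g. fresh food: fruit/vegetable grocer 1000 m, meat/seafood 3200 m,
supermarket 1000 m — supermarket distance pooled as the row-wise minimum of
two independent sources). `daily_living_access_1600m` (0–3) sums
supermarket, any transit stop and convenience store at 1600 m;
`social_infrastructure_mix` (0–16) sums 16 social-infrastructure members at
their own thresholds. Regular public transport means an average daytime
(07:00–19:00) weekday headway ≤ 30 min; large public open space means
> 1.5 ha of publicly accessible area, reached through entry points sampled
every 20 m along boundaries within 30 m of the network; both scored at
400 m.

**Walkability** is the sum of z-scores of dwelling density, street
connectivity and daily living access, standardised within a city or
nationally.

**Urban Liveability Index.** Thirteen sub-indicators (seven access
categories, regular transport, large open space, density, connectivity,
housing-stress % reverse-scaled to affordability, local-employment %) are
conditionally capped (values beyond 3 SD pull that tail's > 2 SD values
linearly back to terminate at 3 SD), normalised to mean 100 / SD 10 within
scope, and combined per address with the Mazziotta–Pareto variance penalty:

    ULI = M − S² / M,

where *M*, *S* are the mean and population SD of the address's 13
normalised scores. An address at the scope mean on every sub-indicator
scores the benchmark 100; uneven performance is penalised.

**Aggregation.** After exclusions (non-urban or zero-dwelling mesh block;
no area disadvantage index; invalid catchment — tallied once each, in that
priority order), indicators average unweighted per mesh block and then
aggregate dwelling- or person-weighted to SA1–SA4, suburb, LGA and city,
with percent-meeting-threshold variants.

## Worked example

```python
import liveability as lv

city = lv.generate_city(lv.CityConfig(seed=1))   # 12x12 grid, 400 addresses
result = lv.run_pipeline(city)

print(result.tally.table().to_string(index=False))
included = result.addresses[result.addresses["included"]]
district = included["mb_code"].isin(city.district_mb_codes)
print("mean ULI, activity-centre district :", round(included.loc[district, "uli_city"].mean(), 1))
print("mean ULI, rest of the city         :", round(included.loc[~district, "uli_city"].mean(), 1))
print("dwelling-weighted city ULI         :", round(result.area_summaries["city"]["uli_city"].iloc[0], 1))
```

prints

```
                                           group  count    pct
                         total address locations    400 100.00
                does not meet inclusion criteria     11   2.75
                                       not urban      7   1.75
           not in an SA1 with disadvantage index      4   1.00
                        invalid network topology      8   2.00
  catchment area below 16.5 ha plausible minimum      8   2.00
        other connectivity issues (null results)      0   0.00
                         included (not excluded)    381  95.25

mean ULI, activity-centre district : 105.1
mean ULI, rest of the city         : 98.4
dwelling-weighted city ULI         : 99.3
```

The tally shows the exclusion groups the generator builds in on purpose
(zero-dwelling and non-urban blocks, an SA1 without the disadvantage index,
and a cluster of addresses on a street segment disconnected from the main
network, whose catchments fall below 16.5 ha). The generator concentrates
half of all destinations and denser housing in one district; its mean ULI
sits ~7 points above the rest of the city, while the dwelling-weighted
city-wide ULI stays just below the benchmark 100 because of the variance
penalty.

`liveability.pipeline.export_results` writes the published file shapes:
address indicator CSV, distance-to-closest CSV, distance-array PSV
(comma-separated integer lists in pipe-separated fields), per-stop headway
CSV with WKT geometry, AOS CSV with three WKT geometry columns, od_aos TSV,
area summaries per scale, and a machine-readable data dictionary per file.

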