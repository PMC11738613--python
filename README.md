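# twosfca

Spatial accessibility of antivenom-stocked hospitals on a road network,
implemented as a reusable pipeline:

1. **demand surface** — linearly correct a ~100 m population raster so each
   administrative unit's zonal sum matches its census total, tile the study
   area with a 2 km fishnet, and emit population-weighted demand points at
   the cell centroids;
2. **road network** — build an undirected travel-time graph from a
   nine-class road layer (class speeds 100/80/60/20/20/20/30/15/5 km/h),
   snap demand points and facilities to nodes, and compute the
   origin–destination cost matrix (minutes, plus network km along the
   time-optimal path);
3. **accessibility** — Gaussian two-step floating catchment area (2SFCA)
   scores per demand point, for hospital beds and for health technicians,
   with a bounded Gaussian decay kernel (G(0)=1, G(d0)=0; default
   catchment d0 = 40 km network distance, a minute-based threshold is also
   supported);
4. **band report** — nearest-facility travel-time bands
   (≤30 / 30–60 / 60–90 / 90–120 / >120 min) per antivenom subset
   (all equipped facilities, each of the four antivenom types, facilities
   stocking all four), with count, percentage share, covered area
   (4 km² per cell) and resident population per band, plus a
   >threshold population roll-up.

A fully deterministic synthetic-province generator
(`twosfca.synthetic_province`) emulates all four inputs — a multi-class
road lattice, a heterogeneous population raster whose per-unit sums
deliberately disagree with "census" totals, rectangular admin units and
facilities with supply and antivenom-type flags — so the whole pipeline is
testable offline.

## File formats

Vectors are GeoJSON (roads need a `road_class` property; admin polygons a
`unit_id`); the raster is a single-band ESRI ASCII grid (`.asc`); the
census (`unit_id,census_pop`) and facility tables
(`facility_id,x,y,beds,technicians,hyalys,naja,bungarus,acutus`) are CSV.
All layers must share one projected metric coordinate system; the tool
never reprojects.

## CLI

```sh
# generate a synthetic province into ./data
twosfca synth --seed 7 --out data

# run the full analysis
twosfca run --roads data/roads.geojson --raster data/population.asc \
    --admin data/admin_units.geojson --census data/census.csv \
    --facilities data/facilities.csv --out out \
    --d0 40 --cost-basis distance
```

Outputs: `demand_points.csv` (per-point population, nearest facility,
travel time, band, A_beds, A_tech), `band_summary.csv` (one block per
antivenom subset), `demand_points.geojson`, and `manifest.json` with row
counts.

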