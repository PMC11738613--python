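"""Reading, validation and writing of the four input layers and all pipeline outputs.

Vector layers are GeoJSON (RFC 7946) handled through :mod:`json` plus
shapely's ``shape``/``mapping``; rasters are single-band ESRI ASCII grids
(``.asc``), a plain-text format every desktop GIS reads; tables are UTF-8
CSV with a header row.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, mapping, shape

logger = logging.getLogger(__name__)

#: Canonical antivenom type labels, in fixed order (column order in the
#: facility CSV): Agkistrodon Hyalys, Naja, Bungarus Multicnctus,
#: Agkistrodon Acutus.
ANTIVENOM_TYPES = ("hyalys", "naja", "bungarus", "acutus")

#: The nine canonical road classes a segment may carry.
ROAD_CLASSES = (
    "highway",
    "expressway",
    "arterial",
    "feeder",
    "other",
    "internal",
    "rural",
    "bicycle",
    "pedestrian",
)


class LayerError(ValueError):
    """Raised when an input layer fails validation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoadSegment:
    """One classified polyline of the road network (planar metric coords)."""

    segment_id: str
    geometry: LineString
    road_class: str

    def __post_init__(self) -> None:
        if self.road_class not in ROAD_CLASSES:
            raise LayerError(
                f"segment {self.segment_id!r}: unknown road class {self.road_class!r}"
            )
        if len(self.geometry.coords) < 2:
            raise LayerError(f"segment {self.segment_id!r}: fewer than 2 vertices")


@dataclass
class RoadLayer:
    """A classified road network in one projected metric coordinate system."""

    segments: list[RoadSegment]
    coordinate_system_id: str = "local-metric"

    def __post_init__(self) -> None:
        if not self.segments:
            raise LayerError("road layer is empty")

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class PopulationRaster:
    """Gridded population counts.

    ``values`` is a (nrows, ncols) float array with row 0 the northernmost
    row (ESRI ASCII grid convention); the cell at (row r, col c) covers
    ``[xll + c*cs, xll + (c+1)*cs) x [yll + (nrows-1-r)*cs, yll + (nrows-r)*cs)``.
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise LayerError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise LayerError("raster cell size must be positive")
        if np.any(self.values < 0):
            raise LayerError("raster contains negative populations")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened x and y coordinates of every cell center (C order)."""
        cs = self.cellsize
        xs = self.xll + (np.arange(self.ncols) + 0.5) * cs
        ys = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * cs
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class AdminUnit:
    """Administrative unit polygon carrying its census population total."""

    unit_id: str
    geometry: Polygon
    census_pop: float

    def __post_init__(self) -> None:
        if self.census_pop < 0:
            raise LayerError(f"unit {self.unit_id!r}: negative census population")


@dataclass
class Facility:
    """A supply site: location, beds, health technicians, stocked antivenom types."""

    facility_id: str
    x: float
    y: float
    beds: int
    technicians: int
    stocked_types: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.beds < 0 or self.technicians < 0:
            raise LayerError(f"facility {self.facility_id!r}: negative supply")
        unknown = set(self.stocked_types) - set(ANTIVENOM_TYPES)
        if unknown:
            raise LayerError(
                f"facility {self.facility_id!r}: unknown antivenom types {sorted(unknown)}"
            )

    @property
    def all_types(self) -> bool:
        """True iff the facility stocks every one of the four antivenom types."""
        return set(self.stocked_types) == set(ANTIVENOM_TYPES)

    @property
    def location(self) -> Point:
        return Point(self.x, self.y)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_roads(path: str, class_map: dict[str, str] | None = None) -> RoadLayer:
    """Read a GeoJSON road layer with a ``road_class`` property.

    ``class_map`` translates source-specific class labels to the nine
    canonical ones; classes that are neither canonical nor mapped are a hard
    error (silently dropping them would bias travel times).

    ESRI Shapefile input is not supported in this build (no shapefile driver
    in the runtime); convert to GeoJSON first.
    """
    if str(path).lower().endswith((".shp", ".shz")):
        raise LayerError(
            "Shapefile input is not supported in this build; convert the road "
            "layer to GeoJSON (e.g. `ogr2ogr -f GeoJSON roads.geojson roads.shp`)"
        )
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    features = doc.get("features", [])
    if not features:
        raise LayerError(f"{path}: road layer contains no features")

    class_map = class_map or {}
    segments: list[RoadSegment] = []
    unmapped: dict[str, int] = {}
    for i, feat in enumerate(features):
        props = feat.get("properties") or {}
        if "road_class" not in props:
            raise LayerError(f"{path}: feature {i} is missing the 'road_class' attribute")
        raw = props["road_class"]
        cls = class_map.get(raw, raw)
        if cls not in ROAD_CLASSES:
            unmapped[raw] = unmapped.get(raw, 0) + 1
            continue
        geom = shape(feat["geometry"])
        if not isinstance(geom, LineString):
            raise LayerError(f"{path}: feature {i} is not a LineString")
        seg_id = str(props.get("segment_id", i))
        segments.append(RoadSegment(segment_id=seg_id, geometry=geom, road_class=cls))
    if unmapped:
        listing = ", ".join(f"{k!r} (n={v})" for k, v in sorted(unmapped.items()))
        raise LayerError(
            f"{path}: unrecognized road classes with no mapping: {listing}"
        )
    crs = doc.get("crs", {}).get("properties", {}).get("name", "local-metric")
    return RoadLayer(segments=segments, coordinate_system_id=crs)


def write_roads(layer: RoadLayer, path: str) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(seg.geometry),
            "properties": {"segment_id": seg.segment_id, "road_class": seg.road_class},
        }
        for seg in layer.segments
    ]
    _dump_geojson(features, path)


def read_raster(path: str) -> PopulationRaster:
    """Read a single-band ESRI ASCII grid; NODATA cells become population 0."""
    header: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    values = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
    nodata = header.get("nodata_value")
    if nodata is not None:
        mask = values == nodata
        if mask.any():
            logger.warning("%s: %d NODATA cells treated as population 0", path, mask.sum())
            values = np.where(mask, 0.0, values)
    return PopulationRaster(
        values=values,
        xll=header.get("xllcorner", 0.0),
        yll=header.get("yllcorner", 0.0),
        cellsize=header.get("cellsize", 1.0),
    )


def write_raster(raster: PopulationRaster, path: str, nodata: float = -9999) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:.6f}\n")
        fh.write(f"yllcorner {raster.yll:.6f}\n")
        fh.write(f"cellsize {raster.cellsize:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in raster.values:
            fh.write(" ".join(format(v, ".10g") for v in row) + "\n")


def read_admin_units(geojson_path: str, census_csv_path: str) -> list[AdminUnit]:
    """Read admin polygons (GeoJSON, ``unit_id`` property) joined to a census CSV."""
    census = pd.read_csv(census_csv_path, dtype={"unit_id": str})
    if not {"unit_id", "census_pop"} <= set(census.columns):
        raise LayerError(f"{census_csv_path}: needs columns unit_id,census_pop")
    if census["unit_id"].duplicated().any():
        raise LayerError(f"{census_csv_path}: duplicate unit_id values")
    totals = dict(zip(census["unit_id"], census["census_pop"].astype(float)))

    with open(geojson_path, encoding="utf-8") as fh:
        doc = json.load(fh)
    units = []
    for feat in doc.get("features", []):
        uid = str((feat.get("properties") or {}).get("unit_id"))
        if uid not in totals:
            raise LayerError(f"unit {uid!r} has no census row")
        units.append(AdminUnit(unit_id=uid, geometry=shape(feat["geometry"]), census_pop=totals[uid]))
    if not units:
        raise LayerError(f"{geojson_path}: no admin units")
    return units


def write_admin_units(units: list[AdminUnit], geojson_path: str, census_csv_path: str) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(u.geometry),
            "properties": {"unit_id": u.unit_id},
        }
        for u in units
    ]
    _dump_geojson(features, geojson_path)
    with open(census_csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["unit_id", "census_pop"])
        for u in units:
            writer.writerow([u.unit_id, format(u.census_pop, ".10g")])


FACILITY_COLUMNS = ("facility_id", "x", "y", "beds", "technicians") + ANTIVENOM_TYPES


def read_facilities(path: str) -> list[Facility]:
    """Read the facility table CSV (one 0/1 flag column per antivenom type)."""
    df = pd.read_csv(path, dtype={"facility_id": str})
    missing = set(FACILITY_COLUMNS) - set(df.columns)
    if missing:
        raise LayerError(f"{path}: missing columns {sorted(missing)}")
    if df["facility_id"].duplicated().any():
        dupes = df.loc[df["facility_id"].duplicated(), "facility_id"].tolist()
        raise LayerError(f"{path}: duplicate facility_id values {dupes}")
    if (df["beds"] < 0).any() or (df["technicians"] < 0).any():
        raise LayerError(f"{path}: negative beds or technicians")
    facilities = []
    for row in df.itertuples(index=False):
        stocked = frozenset(t for t in ANTIVENOM_TYPES if int(getattr(row, t)) == 1)
        facilities.append(
            Facility(
                facility_id=row.facility_id,
                x=float(row.x),
                y=float(row.y),
                beds=int(row.beds),
                technicians=int(row.technicians),
                stocked_types=stocked,
            )
        )
    return facilities


def write_facilities(facilities: list[Facility], path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(FACILITY_COLUMNS)
        for f in facilities:
            writer.writerow(
                [f.facility_id, format(f.x, ".6f"), format(f.y, ".6f"), f.beds, f.technicians]
                + [1 if t in f.stocked_types else 0 for t in ANTIVENOM_TYPES]
            )


def facility_type_counts(facilities: list[Facility]) -> dict[str, int]:
    """Per-type stocking counts plus the ``all_types`` count."""
    counts = {t: sum(1 for f in facilities if t in f.stocked_types) for t in ANTIVENOM_TYPES}
    counts["all_types"] = sum(1 for f in facilities if f.all_types)
    return counts


# ---------------------------------------------------------------------------
# Output writer
# ---------------------------------------------------------------------------

POINT_TABLE_COLUMNS = (
    "point_id", "x", "y", "population", "nearest_facility_id",
    "travel_min", "band", "A_beds", "A_tech",
)

BAND_TABLE_COLUMNS = (
    "subset", "band", "n_points", "proportion_pct", "area_km2",
    "population_persons", "population_1e4",
)


def write_outputs(results, out_dir: str) -> dict:
    """Write the per-point score table, the band summary and a GeoJSON of
    scored demand points; returns a manifest mapping file name -> row count.

    ``results`` is a :class:`twosfca.pipeline.PipelineResult` (anything with
    ``point_table`` and ``band_table`` DataFrames works).
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict[str, int] = {}

    points: pd.DataFrame = results.point_table
    points = points.reindex(columns=list(POINT_TABLE_COLUMNS))
    points_path = os.path.join(out_dir, "demand_points.csv")
    points.to_csv(points_path, index=False)
    manifest["demand_points.csv"] = len(points)

    bands: pd.DataFrame = results.band_table
    bands = bands.reindex(columns=list(BAND_TABLE_COLUMNS))
    bands_path = os.path.join(out_dir, "band_summary.csv")
    bands.to_csv(bands_path, index=False)
    manifest["band_summary.csv"] = len(bands)

    features = []
    for row in points.itertuples(index=False):
        props = {c: _jsonable(getattr(row, c)) for c in POINT_TABLE_COLUMNS if c not in ("x", "y")}
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(row.x), float(row.y)]}
                if pd.notna(row.x)
                else None,
                "properties": props,
            }
        )
    geojson_path = os.path.join(out_dir, "demand_points.geojson")
    _dump_geojson(features, geojson_path)
    manifest["demand_points.geojson"] = len(features)

    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating, float)):
        f = float(v)
        return None if math.isnan(f) else f
    if pd.isna(v):
        return None
    return v


def _dump_geojson(features: list[dict], path: str) -> None:
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")
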