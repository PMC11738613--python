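"""Self-contained synthetic "province" generator.

Emits the four layers the pipeline consumes — a multi-class road lattice, a
heterogeneous 100 m population raster whose per-unit sums deliberately
disagree with "census" totals, rectangular admin units, and facilities with
supply fields and antivenom-type flags — all in one planar metric
coordinate system, fully determined by the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, box

from . import gis_io
from .gis_io import (
    ANTIVENOM_TYPES,
    AdminUnit,
    Facility,
    PopulationRaster,
    RoadLayer,
    RoadSegment,
)

#: Road classes cycled over lattice lines; three distinct speeds (80/60/30).
LATTICE_CLASSES = ("arterial", "expressway", "rural")


@dataclass(frozen=True)
class ProvinceSpec:
    """Parameters of the synthetic province."""

    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 20000.0, 20000.0)
    n_admin_units: int = 4
    raster_resolution: float = 100.0
    road_lattice_spacing: float = 2000.0
    n_facilities: int = 25
    fishnet_cell_edge: float = 2000.0
    antivenom_types: tuple[str, ...] = ANTIVENOM_TYPES
    census_distortion: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        w, h = xmax - xmin, ymax - ymin
        if w <= 0 or h <= 0:
            raise ValueError("degenerate extent (zero area)")
        if self.n_facilities < 1:
            raise ValueError("n_facilities must be at least 1")
        if self.n_admin_units < 1:
            raise ValueError("n_admin_units must be at least 1")
        if abs(self.fishnet_cell_edge / self.raster_resolution % 1.0) > 1e-9:
            raise ValueError("raster_resolution must divide the fishnet cell edge")
        lo, hi = self.census_distortion
        if not (0 < lo <= hi):
            raise ValueError("census_distortion must satisfy 0 < lo <= hi")

    @property
    def area(self) -> float:
        xmin, ymin, xmax, ymax = self.extent
        return (xmax - xmin) * (ymax - ymin)


@dataclass
class ProvinceBundle:
    """All generated layers plus the correction factors actually recorded
    (census total / raster zonal sum per admin unit)."""

    spec: ProvinceSpec
    roads: RoadLayer
    raster: PopulationRaster
    admin_units: list[AdminUnit]
    facilities: list[Facility]
    distortion_factors: dict[str, float] = field(default_factory=dict)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return self.spec.extent


def _lattice_roads(spec: ProvinceSpec) -> RoadLayer:
    """Full grid of vertical+horizontal lines, one polyline per line with a
    vertex at every crossing so intersections become shared graph nodes."""
    xmin, ymin, xmax, ymax = spec.extent
    s = spec.road_lattice_spacing
    xs = np.arange(xmin, xmax + 1e-9, s)
    ys = np.arange(ymin, ymax + 1e-9, s)
    segments = []
    for i, x in enumerate(xs):
        cls = LATTICE_CLASSES[i % len(LATTICE_CLASSES)]
        coords = [(float(x), float(y)) for y in ys]
        segments.append(RoadSegment(segment_id=f"v{i}", geometry=LineString(coords), road_class=cls))
    for j, y in enumerate(ys):
        cls = LATTICE_CLASSES[j % len(LATTICE_CLASSES)]
        coords = [(float(x), float(y)) for x in xs]
        segments.append(RoadSegment(segment_id=f"h{j}", geometry=LineString(coords), road_class=cls))
    return RoadLayer(segments=segments)


def _population_raster(spec: ProvinceSpec, rng: np.random.Generator) -> PopulationRaster:
    """Heavy-tailed settlement field: log-normal noise plus a few Gaussian
    'town' bumps, integer-rounded per cell."""
    xmin, ymin, xmax, ymax = spec.extent
    res = spec.raster_resolution
    ncols = int(round((xmax - xmin) / res))
    nrows = int(round((ymax - ymin) / res))
    vals = rng.lognormal(mean=0.0, sigma=1.0, size=(nrows, ncols))
    cy, cx = np.mgrid[0:nrows, 0:ncols]
    for _ in range(3):
        tx = rng.uniform(0, ncols)
        ty = rng.uniform(0, nrows)
        sigma = rng.uniform(0.03, 0.12) * max(nrows, ncols)
        peak = rng.uniform(10, 60)
        vals += peak * np.exp(-((cx - tx) ** 2 + (cy - ty) ** 2) / (2 * sigma**2))
    vals = np.rint(vals)
    return PopulationRaster(values=vals, xll=xmin, yll=ymin, cellsize=res)


def _admin_units(
    spec: ProvinceSpec, raster: PopulationRaster, rng: np.random.Generator
) -> tuple[list[AdminUnit], dict[str, float]]:
    """Vertical strips partitioning the extent; census totals are the zonal
    raster sums times a per-unit distortion factor drawn from the configured
    range, integer-rounded. The recorded factor is the post-rounding ratio
    census / zonal-sum."""
    from .demand_surface import zonal_sum

    xmin, ymin, xmax, ymax = spec.extent
    n = spec.n_admin_units
    edges = np.linspace(xmin, xmax, n + 1)
    units = [
        AdminUnit(unit_id=f"U{i:02d}", geometry=box(edges[i], ymin, edges[i + 1], ymax),
                  census_pop=0.0)
        for i in range(n)
    ]
    sums = zonal_sum(raster, units)
    lo, hi = spec.census_distortion
    factors: dict[str, float] = {}
    for u in units:
        zs = sums[u.unit_id]
        draw = rng.uniform(lo, hi)
        census = float(np.rint(zs * draw))
        u.census_pop = census
        factors[u.unit_id] = census / zs if zs > 0 else float("nan")
    return units, factors


def _facilities(spec: ProvinceSpec, rng: np.random.Generator) -> list[Facility]:
    """Facilities sit on lattice nodes (so fixture travel costs are exact);
    every antivenom type ends up stocked by at least one facility."""
    xmin, ymin, xmax, ymax = spec.extent
    s = spec.road_lattice_spacing
    xs = np.arange(xmin, xmax + 1e-9, s)
    ys = np.arange(ymin, ymax + 1e-9, s)
    nodes = [(float(x), float(y)) for x in xs for y in ys]
    if spec.n_facilities > len(nodes):
        raise ValueError("more facilities than lattice nodes")
    picks = rng.choice(len(nodes), size=spec.n_facilities, replace=False)
    n_types = len(spec.antivenom_types)
    flags = rng.random((spec.n_facilities, n_types)) < 0.5
    for t in range(n_types):
        if not flags[:, t].any():
            flags[int(rng.integers(spec.n_facilities)), t] = True
    facilities = []
    for i, k in enumerate(sorted(picks)):
        x, y = nodes[k]
        facilities.append(
            Facility(
                facility_id=f"F{i:02d}",
                x=x,
                y=y,
                beds=int(rng.integers(20, 800)),
                technicians=int(rng.integers(30, 1200)),
                stocked_types=frozenset(
                    t for t, on in zip(spec.antivenom_types, flags[i]) if on
                ),
            )
        )
    return facilities


def generate_province(spec: ProvinceSpec) -> ProvinceBundle:
    """Generate the full synthetic bundle; deterministic for a fixed seed."""
    if spec.area < 100 * spec.fishnet_cell_edge**2:
        raise ValueError("extent must cover at least 100 fishnet cells")
    rng = np.random.default_rng(spec.seed)
    roads = _lattice_roads(spec)
    raster = _population_raster(spec, rng)
    units, factors = _admin_units(spec, raster, rng)
    facilities = _facilities(spec, rng)
    return ProvinceBundle(
        spec=spec, roads=roads, raster=raster, admin_units=units,
        facilities=facilities, distortion_factors=factors,
    )


def known_answer_scenario() -> ProvinceBundle:
    """Fixed micro-scenario whose 2SFCA solution is hand-computable.

    One facility (supply 10 beds and 10 technicians, all types) at the
    origin of a straight 20 km arterial road with vertices every 1 km; the
    population is 100 persons in the fishnet cell centred on the facility
    and 100 in the cell centred 20 km along the road. With the default
    40 km network-distance catchment:

    * G(20, 40) = (e^-0.125 - e^-0.5) / (1 - e^-0.5) ~= 0.701372
    * R = 10 / (100 + 100*G) ~= 0.058776
    * A(0 km) = R ~= 0.058776, A(20 km) = G*R ~= 0.041226
    * conservation: 100*A(0) + 100*A(20) = 10 = total supply
    """
    extent = (-1000.0, -1000.0, 21000.0, 1000.0)
    spec = ProvinceSpec(
        seed=0, extent=extent, n_admin_units=1, raster_resolution=100.0,
        road_lattice_spacing=1000.0, n_facilities=1, fishnet_cell_edge=2000.0,
        census_distortion=(1.0, 1.0),
    )

    coords = [(float(x), 0.0) for x in np.arange(0.0, 20000.0 + 1e-9, 1000.0)]
    roads = RoadLayer(
        segments=[RoadSegment(segment_id="spine", geometry=LineString(coords),
                              road_class="arterial")]
    )

    nrows = int(round((extent[3] - extent[1]) / 100.0))
    ncols = int(round((extent[2] - extent[0]) / 100.0))
    vals = np.zeros((nrows, ncols))
    # cell centers nearest (0, 0) and (20000, 0): the whole 100-person mass
    # of each fishnet cell sits in one raster cell inside it
    def put(x, y, pop):
        c = int(np.floor((x - extent[0]) / 100.0))
        r = nrows - 1 - int(np.floor((y - extent[1]) / 100.0))
        vals[r, c] = pop

    put(0.0, 0.0, 100.0)
    put(20000.0, 0.0, 100.0)
    raster = PopulationRaster(values=vals, xll=extent[0], yll=extent[1], cellsize=100.0)

    unit = AdminUnit(unit_id="U00", geometry=box(*extent), census_pop=200.0)
    facility = Facility(
        facility_id="F00", x=0.0, y=0.0, beds=10, technicians=10,
        stocked_types=frozenset(ANTIVENOM_TYPES),
    )
    return ProvinceBundle(
        spec=spec, roads=roads, raster=raster, admin_units=[unit],
        facilities=[facility], distortion_factors={"U00": 1.0},
    )


def write_bundle(bundle: ProvinceBundle, out_dir: str) -> dict[str, str]:
    """Serialise all four layers to disk in the pipeline's input formats."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "roads": os.path.join(out_dir, "roads.geojson"),
        "raster": os.path.join(out_dir, "population.asc"),
        "admin": os.path.join(out_dir, "admin_units.geojson"),
        "census": os.path.join(out_dir, "census.csv"),
        "facilities": os.path.join(out_dir, "facilities.csv"),
    }
    gis_io.write_roads(bundle.roads, paths["roads"])
    gis_io.write_raster(bundle.raster, paths["raster"])
    gis_io.write_admin_units(bundle.admin_units, paths["admin"], paths["census"])
    gis_io.write_facilities(bundle.facilities, paths["facilities"])
    return paths


def read_bundle(paths: dict[str, str], spec: ProvinceSpec | None = None) -> ProvinceBundle:
    """Load a bundle previously written by :func:`write_bundle`."""
    roads = gis_io.read_roads(paths["roads"])
    raster = gis_io.read_raster(paths["raster"])
    units = gis_io.read_admin_units(paths["admin"], paths["census"])
    facilities = gis_io.read_facilities(paths["facilities"])
    if spec is None:
        xmin, ymin = raster.xll, raster.yll
        xmax = xmin + raster.ncols * raster.cellsize
        ymax = ymin + raster.nrows * raster.cellsize
        spec = ProvinceSpec(
            seed=-1, extent=(xmin, ymin, xmax, ymax), n_admin_units=len(units),
            raster_resolution=raster.cellsize, n_facilities=len(facilities),
        )
    return ProvinceBundle(spec=spec, roads=roads, raster=raster,
                          admin_units=units, facilities=facilities)
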