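"""Census correction of the population raster, fishnet construction and
population-weighted demand points.

Every raster cell is assigned to at most one admin unit and exactly one
fishnet cell by its center point, which makes both aggregation stages exact
partitions: per-unit sums after correction equal census totals, and the
fishnet preserves the corrected total population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, box

from .gis_io import AdminUnit, PopulationRaster

logger = logging.getLogger(__name__)

DEFAULT_CELL_EDGE_M = 2000.0  # 2 km fishnet cell


@dataclass(frozen=True)
class FishnetCell:
    """One square fishnet cell; centroid is the center of the full square."""

    cell_id: str
    geometry: Polygon
    centroid: Point
    population: float = 0.0


@dataclass(frozen=True)
class DemandPoint:
    """Population center-of-mass point: fishnet centroid carrying cell population."""

    point_id: str
    x: float
    y: float
    population: float


@dataclass
class CorrectionResult:
    """Corrected raster plus the per-unit correction factors actually applied."""

    raster: PopulationRaster
    factors: dict[str, float]
    unassigned_cells: int
    uniform_spread_units: list[str]


def assign_cells_to_units(
    raster: PopulationRaster, units: list[AdminUnit]
) -> np.ndarray:
    """Index of the admin unit owning each raster cell (flattened, C order).

    Ownership is by cell center; a center on a shared boundary goes to the
    first unit (input order) that touches it, so each cell is counted at most
    once. Cells inside no unit get -1.
    """
    xs, ys = raster.cell_centers()
    owner = np.full(xs.size, -1, dtype=int)
    for ui, unit in enumerate(units):
        free = owner < 0
        if not free.any():
            break
        hit = shapely.intersects_xy(unit.geometry, xs[free], ys[free])
        idx = np.flatnonzero(free)[hit]
        owner[idx] = ui
    return owner


def correct_raster(
    raster: PopulationRaster, units: list[AdminUnit]
) -> CorrectionResult:
    """Linear census correction: every cell in a unit is multiplied by
    ``census_pop / raster_sum`` for that unit, so post-correction zonal sums
    equal the census totals.

    A unit whose raster sum is zero but census is positive gets its census
    population spread uniformly over its cells (with a warning); cells that
    fall in no unit are left unchanged and counted.
    """
    owner = assign_cells_to_units(raster, units)
    flat = raster.values.ravel().astype(float).copy()
    factors: dict[str, float] = {}
    spread_units: list[str] = []
    for ui, unit in enumerate(units):
        mask = owner == ui
        zsum = float(flat[mask].sum())
        if zsum > 0:
            f = unit.census_pop / zsum
            flat[mask] *= f
            factors[unit.unit_id] = f
        elif unit.census_pop > 0:
            n = int(mask.sum())
            if n == 0:
                logger.warning(
                    "unit %s has census %.0f but contains no raster cells; population lost",
                    unit.unit_id, unit.census_pop,
                )
                factors[unit.unit_id] = float("nan")
                continue
            flat[mask] = unit.census_pop / n
            factors[unit.unit_id] = float("inf")
            spread_units.append(unit.unit_id)
            logger.warning(
                "unit %s: zero raster population, census %.0f spread uniformly over %d cells",
                unit.unit_id, unit.census_pop, n,
            )
        else:
            factors[unit.unit_id] = 1.0
    unassigned = int((owner < 0).sum())
    n_unassigned_pop = int(((owner < 0) & (flat > 0)).sum())
    if n_unassigned_pop:
        logger.warning(
            "%d populated raster cells fall in no admin unit and were left unchanged",
            n_unassigned_pop,
        )
    corrected = PopulationRaster(
        values=flat.reshape(raster.values.shape),
        xll=raster.xll, yll=raster.yll, cellsize=raster.cellsize,
    )
    return CorrectionResult(
        raster=corrected, factors=factors,
        unassigned_cells=unassigned, uniform_spread_units=spread_units,
    )


def build_fishnet(
    extent: tuple[float, float, float, float],
    cell_edge: float = DEFAULT_CELL_EDGE_M,
) -> list[FishnetCell]:
    """Axis-aligned square grid tiling ``extent`` from its lower-left corner.

    Partial cells at the right/top edges are kept as full squares (their
    centroid is the square center); columns are fastest-varying in the output
    order and in the ``r{row}c{col}`` cell ids.
    """
    if cell_edge <= 0:
        raise ValueError("cell_edge must be positive")
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate extent")
    ncols = int(np.ceil((xmax - xmin) / cell_edge - 1e-12))
    nrows = int(np.ceil((ymax - ymin) / cell_edge - 1e-12))
    cells = []
    for r in range(nrows):
        y0 = ymin + r * cell_edge
        for c in range(ncols):
            x0 = xmin + c * cell_edge
            cells.append(
                FishnetCell(
                    cell_id=f"r{r}c{c}",
                    geometry=box(x0, y0, x0 + cell_edge, y0 + cell_edge),
                    centroid=Point(x0 + cell_edge / 2, y0 + cell_edge / 2),
                )
            )
    return cells


def make_demand_points(
    cells: list[FishnetCell],
    corrected_raster: PopulationRaster,
    drop_empty: bool = False,
) -> list[DemandPoint]:
    """One demand point per fishnet cell, carrying the sum of corrected raster
    cells whose centers fall inside it.

    The fishnet is assumed to come from :func:`build_fishnet` (regular grid
    anchored at the extent's lower-left corner), so raster-center-to-cell
    assignment is exact index arithmetic and each raster cell counts once.
    Zero-population cells are retained by default; ``drop_empty`` removes them.
    """
    if not cells:
        return []
    edge = cells[0].geometry.bounds[2] - cells[0].geometry.bounds[0]
    xmin = min(c.geometry.bounds[0] for c in cells)
    ymin = min(c.geometry.bounds[1] for c in cells)
    ncols = round((max(c.geometry.bounds[2] for c in cells) - xmin) / edge)
    nrows = round((max(c.geometry.bounds[3] for c in cells) - ymin) / edge)

    xs, ys = corrected_raster.cell_centers()
    vals = corrected_raster.values.ravel()
    col = np.floor((xs - xmin) / edge).astype(int)
    row = np.floor((ys - ymin) / edge).astype(int)
    inside = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
    outside_pop = float(vals[~inside].sum())
    if outside_pop > 0:
        logger.warning("%.1f persons in raster cells outside the fishnet were dropped",
                       outside_pop)
    pop = np.zeros(nrows * ncols)
    np.add.at(pop, row[inside] * ncols + col[inside], vals[inside])

    points = []
    for cell in cells:
        r = round((cell.geometry.bounds[1] - ymin) / edge)
        c = round((cell.geometry.bounds[0] - xmin) / edge)
        p = float(pop[r * ncols + c])
        if drop_empty and p == 0:
            continue
        points.append(
            DemandPoint(point_id=cell.cell_id, x=cell.centroid.x, y=cell.centroid.y,
                        population=p)
        )
    return points


def zonal_sum(raster: PopulationRaster, units: list[AdminUnit]) -> dict[str, float]:
    """Per-unit raster population by cell-center assignment (same partition
    rule as :func:`correct_raster`)."""
    owner = assign_cells_to_units(raster, units)
    flat = raster.values.ravel()
    return {
        unit.unit_id: float(flat[owner == ui].sum()) for ui, unit in enumerate(units)
    }
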