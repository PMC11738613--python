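"""End-to-end orchestration: demand surface -> travel network -> OD matrix
-> 2SFCA scores -> travel-time band report."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import accessibility, band_report, demand_surface, road_network
from .accessibility import AccessibilityScore, DecayParams
from .band_report import BandScheme, TypeReport
from .demand_surface import DemandPoint
from .road_network import ODMatrix, SpeedTable
from .synthetic_province import ProvinceBundle


@dataclass
class PipelineResult:
    demand: list[DemandPoint]
    od: ODMatrix
    scores: list[AccessibilityScore]
    reports: dict[str, TypeReport]
    correction: demand_surface.CorrectionResult
    n_generated: int  # fishnet centroids generated
    n_routed: int  # centroids with a finite route to the primary subset
    params: DecayParams = field(default_factory=DecayParams)

    @property
    def point_table(self) -> pd.DataFrame:
        """Per-point table keyed on the all-equipped ('equipped') subset."""
        rep = self.reports.get("equipped")
        scheme = BandScheme()
        rows = []
        for i, p in enumerate(self.demand):
            if rep is not None:
                band_idx = int(rep.band_indices[i])
                band = scheme.labels[band_idx] if band_idx >= 0 else "unreachable"
                near = rep.nearest_ids[i]
                minutes = float(rep.nearest_minutes[i])
                minutes = minutes if np.isfinite(minutes) else None
            else:
                band, near, minutes = None, None, None
            rows.append(
                {
                    "point_id": p.point_id, "x": p.x, "y": p.y,
                    "population": p.population,
                    "nearest_facility_id": near, "travel_min": minutes,
                    "band": band,
                    "A_beds": self.scores[i].A_beds, "A_tech": self.scores[i].A_tech,
                }
            )
        return pd.DataFrame(rows, columns=list(pd.Index(
            ["point_id", "x", "y", "population", "nearest_facility_id",
             "travel_min", "band", "A_beds", "A_tech"])))

    @property
    def band_table(self) -> pd.DataFrame:
        return band_report.report_frame(self.reports)


def run_pipeline(
    bundle: ProvinceBundle,
    params: DecayParams | None = None,
    speeds: SpeedTable | None = None,
    cell_edge: float | None = None,
    max_snap_m: float = road_network.DEFAULT_MAX_SNAP_M,
    drop_empty_cells: bool = False,
    scheme: BandScheme | None = None,
) -> PipelineResult:
    """Run the full analysis on a province bundle.

    Stages: census-correct the raster against the admin units, build the
    fishnet and demand points, build the travel graph, snap demand centroids
    and facilities to nodes, compute the OD cost matrix, run Gaussian 2SFCA
    for beds and technicians, and band the nearest-facility times per
    antivenom subset.
    """
    params = params or DecayParams()
    scheme = scheme or BandScheme()
    cell_edge = cell_edge or bundle.spec.fishnet_cell_edge

    correction = demand_surface.correct_raster(bundle.raster, bundle.admin_units)
    cells = demand_surface.build_fishnet(bundle.extent, cell_edge)
    demand = demand_surface.make_demand_points(
        cells, correction.raster, drop_empty=drop_empty_cells
    )

    network = road_network.build_graph(bundle.roads, speeds)
    demand_xy = np.array([[p.x, p.y] for p in demand])
    fac_sorted = sorted(bundle.facilities, key=lambda f: f.facility_id)
    fac_xy = np.array([[f.x, f.y] for f in fac_sorted])
    snap_d = road_network.snap_points(demand_xy, network, max_snap_m)
    snap_f = road_network.snap_points(fac_xy, network, max_snap_m)

    od = road_network.od_cost_matrix(
        network, snap_d.node_ids, snap_f.node_ids,
        point_ids=[p.point_id for p in demand],
        facility_ids=[f.facility_id for f in fac_sorted],
    )

    scores = accessibility.run_2sfca(fac_sorted, demand, od, params)
    reports = band_report.per_type_report(fac_sorted, demand, od, scheme)
    primary = reports.get("equipped")
    return PipelineResult(
        demand=demand, od=od, scores=scores, reports=reports,
        correction=correction, n_generated=len(cells),
        n_routed=primary.n_routed if primary else 0, params=params,
    )
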