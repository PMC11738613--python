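"""Gaussian two-step floating catchment area (2SFCA) accessibility.

Step 1: each facility j gets a supply-to-weighted-demand ratio
``R_j = S_j / sum_{k: d_jk <= d0} G(d_jk) D_k``.
Step 2: each demand point i gets an accessibility score
``A_i = sum_{j: d_ij <= d0} G(d_ij) R_j``.

G is the bounded Gaussian kernel normalised so G(0) = 1 and G(d0) = 0; the
catchment cost d0 may be a network distance (km, the default, matching a
40 km service radius) or a travel time (minutes). Because the same weights
appear in both steps, the identity ``sum_i D_i A_i = sum_j S_j`` holds
exactly over facilities with non-empty catchments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demand_surface import DemandPoint
from .gis_io import Facility
from .road_network import ODMatrix

COST_BASES = ("distance", "time")


@dataclass(frozen=True)
class DecayParams:
    """Catchment threshold d0 and which OD cost it applies to.

    ``cost_basis="distance"`` reads d0 in network km (default 40 km);
    ``cost_basis="time"`` reads it in minutes.
    """

    d0: float = 40.0
    cost_basis: str = "distance"

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.cost_basis not in COST_BASES:
            raise ValueError(f"cost_basis must be one of {COST_BASES}")


@dataclass(frozen=True)
class SupplyDemandRatio:
    """Facility-level supply per weighted person (R_j); ``empty_catchment``
    flags facilities whose weighted demand is zero (R forced to 0 and the
    facility excluded from step 2)."""

    facility_id: str
    R: float
    catchment_weighted_demand: float
    empty_catchment: bool = False


@dataclass(frozen=True)
class AccessibilityScore:
    """Per-demand-point accessibility, in supply units per person, for beds
    and for health technicians (plus per-1000-person convenience fields)."""

    point_id: str
    A_beds: float
    A_tech: float

    @property
    def A_beds_per_1000(self) -> float:
        return 1000.0 * self.A_beds

    @property
    def A_tech_per_1000(self) -> float:
        return 1000.0 * self.A_tech


def gaussian_decay(d, params: DecayParams):
    """Bounded Gaussian kernel weight for cost ``d`` (scalar or array).

    ``G(d) = (exp(-(d/d0)^2 / 2) - exp(-1/2)) / (1 - exp(-1/2))`` for
    ``d < d0`` and 0 at or beyond d0. Continuous and strictly decreasing on
    [0, d0] with G(0) = 1.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("negative cost passed to gaussian_decay")
    e_half = np.exp(-0.5)
    with np.errstate(invalid="ignore"):
        g = (np.exp(-0.5 * (arr / params.d0) ** 2) - e_half) / (1.0 - e_half)
    g = np.where(np.isfinite(arr) & (arr < params.d0), g, 0.0)
    if np.isscalar(d) or np.ndim(d) == 0:
        return float(g)
    return g


def _cost_matrix(od: ODMatrix, params: DecayParams) -> np.ndarray:
    return od.dist_km if params.cost_basis == "distance" else od.time_min


def decay_weights(od: ODMatrix, params: DecayParams) -> np.ndarray:
    """(n_points, n_facilities) kernel weight matrix; 0 outside catchments."""
    return gaussian_decay(_cost_matrix(od, params), params)


def supply_demand_ratios(
    facilities: list[Facility],
    demand: list[DemandPoint],
    od: ODMatrix,
    params: DecayParams,
    supply_field: str,
) -> list[SupplyDemandRatio]:
    """Step 1: R_j = S_j / sum_k G(d_jk) D_k over demand within the catchment.

    ``supply_field`` is ``"beds"`` or ``"technicians"``. The undirected
    network makes d_jk identical to d_kj, so the demand->facility OD matrix
    serves both steps.
    """
    _check_alignment(facilities, demand, od)
    if supply_field not in ("beds", "technicians"):
        raise ValueError(f"unknown supply field {supply_field!r}")
    w = decay_weights(od, params)
    d_vec = np.array([p.population for p in demand], dtype=float)
    weighted_demand = w.T @ d_vec  # per facility
    out = []
    for j, fac in enumerate(facilities):
        s = float(getattr(fac, supply_field))
        wd = float(weighted_demand[j])
        if wd > 0:
            out.append(SupplyDemandRatio(fac.facility_id, s / wd, wd))
        else:
            out.append(SupplyDemandRatio(fac.facility_id, 0.0, 0.0, empty_catchment=True))
    return out


def accessibility_scores(
    ratios: list[SupplyDemandRatio],
    demand: list[DemandPoint],
    od: ODMatrix,
    params: DecayParams,
) -> np.ndarray:
    """Step 2: A_i = sum_j G(d_ij) R_j over facilities within d0 of point i.

    Returns the A vector aligned with ``demand``; empty-catchment facilities
    are excluded from the sum.
    """
    if [r.facility_id for r in ratios] != list(od.facility_ids):
        raise ValueError("ratios are not aligned with the OD matrix facilities")
    w = decay_weights(od, params)
    r_vec = np.array([0.0 if r.empty_catchment else r.R for r in ratios])
    return w @ r_vec


def run_2sfca(
    facilities: list[Facility],
    demand: list[DemandPoint],
    od: ODMatrix,
    params: DecayParams | None = None,
) -> list[AccessibilityScore]:
    """Run both 2SFCA steps twice — once with beds as supply, once with
    health technicians — and return one score record per demand point."""
    params = params or DecayParams()
    a = {}
    for fld in ("beds", "technicians"):
        ratios = supply_demand_ratios(facilities, demand, od, params, fld)
        a[fld] = accessibility_scores(ratios, demand, od, params)
    return [
        AccessibilityScore(point_id=p.point_id, A_beds=float(a["beds"][i]),
                           A_tech=float(a["technicians"][i]))
        for i, p in enumerate(demand)
    ]


def _check_alignment(facilities, demand, od: ODMatrix) -> None:
    if [f.facility_id for f in facilities] != list(od.facility_ids):
        raise ValueError("facilities are not aligned with the OD matrix columns")
    if [p.point_id for p in demand] != list(od.point_ids):
        raise ValueError("demand points are not aligned with the OD matrix rows")
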