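"""Travel-time band classification and the per-antivenom-type summary report.

Demand points are binned by nearest-facility travel time into five bands —
[0, 30], (30, 60], (60, 90], (90, 120], (120, inf) minutes — and each band
is summarised by point count, percentage share, covered area (count x the
nominal 4 km2 fishnet cell) and resident population. Populations are stored
in persons and also displayed in a 10^4-person unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .demand_surface import DemandPoint
from .gis_io import ANTIVENOM_TYPES, Facility
from .road_network import ODMatrix, nearest_facility

DEFAULT_CELL_AREA_KM2 = 4.0  # 2 km x 2 km fishnet cell

DEFAULT_BAND_LABELS = ("<=30", "30<m<=60", "60<m<=90", "90<m<=120", ">120")


@dataclass(frozen=True)
class BandScheme:
    """Ordered half-open travel-time intervals partitioning [0, inf) minutes.

    ``boundaries`` are the upper edges of all bands but the last; a value
    exactly on a boundary belongs to the band below it (30.0 min is in the
    first band).
    """

    boundaries: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0)
    labels: tuple[str, ...] = DEFAULT_BAND_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError("need exactly one more label than boundaries")
        if list(self.boundaries) != sorted(self.boundaries) or len(set(self.boundaries)) != len(self.boundaries):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return len(self.labels)

    def band_lower_bound(self, band_index: int) -> float:
        return 0.0 if band_index == 0 else self.boundaries[band_index - 1]


@dataclass(frozen=True)
class BandSummaryRow:
    """One band's row of the summary table."""

    label: str
    n_points: int
    proportion_pct: float
    area_km2: float
    population_persons: float

    @property
    def population_1e4(self) -> float:
        """Population in the report's 10^4-person display unit, 1 decimal."""
        return round_half_up(self.population_persons / 1e4, 1)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.05 -> 0.1), matching report rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def classify_bands(minutes, scheme: BandScheme | None = None) -> np.ndarray:
    """Band index (0-based) for each finite travel time.

    Boundary values go to the lower band; non-finite times (unreachable
    points) get index -1 and must be handled by the caller.
    """
    scheme = scheme or BandScheme()
    arr = np.asarray(minutes, dtype=float)
    finite = np.isfinite(arr)
    if np.any(arr[finite] < 0):
        raise ValueError("negative travel time")
    idx = np.searchsorted(np.asarray(scheme.boundaries), arr, side="left")
    idx = np.where(finite, idx, -1)
    return idx.astype(int)


def summarize_bands(
    band_indices,
    populations,
    scheme: BandScheme | None = None,
    n_total: int | None = None,
    cell_area_km2: float = DEFAULT_CELL_AREA_KM2,
) -> list[BandSummaryRow]:
    """Aggregate per-point band assignments into one row per band.

    ``n_total`` defaults to the number of classified (index >= 0) points;
    proportions are 100*n/N rounded half-up to one decimal, areas are exactly
    ``n_points * cell_area_km2``.
    """
    scheme = scheme or BandScheme()
    idx = np.asarray(band_indices, dtype=int)
    pops = np.asarray(populations, dtype=float)
    if idx.shape != pops.shape:
        raise ValueError("band indices and populations differ in length")
    routed = idx >= 0
    n = int(routed.sum()) if n_total is None else int(n_total)
    if n == 0:
        raise ValueError("no routed demand points to summarise")
    rows = []
    for b in range(scheme.n_bands):
        in_band = idx == b
        count = int(in_band.sum())
        rows.append(
            BandSummaryRow(
                label=scheme.labels[b],
                n_points=count,
                proportion_pct=round_half_up(100.0 * count / n, 1),
                area_km2=count * cell_area_km2,
                population_persons=float(pops[in_band].sum()),
            )
        )
    return rows


def over_threshold_population(
    rows: list[BandSummaryRow],
    scheme: BandScheme | None = None,
    threshold_min: float = 60.0,
) -> float:
    """Total population (persons) in all bands strictly above ``threshold_min``.

    The threshold must coincide with a band boundary, otherwise the roll-up
    would split a band.
    """
    scheme = scheme or BandScheme()
    if threshold_min not in scheme.boundaries:
        raise ValueError(
            f"threshold {threshold_min} is not a band boundary {scheme.boundaries}"
        )
    if len(rows) != scheme.n_bands:
        raise ValueError("row list does not match the band scheme")
    return float(
        sum(r.population_persons for b, r in enumerate(rows)
            if scheme.band_lower_bound(b) >= threshold_min)
    )


#: Facility subsets reported on, in report order: every equipped facility,
#: each antivenom type, then facilities stocking all four types.
REPORT_SUBSETS = ("equipped",) + ANTIVENOM_TYPES + ("all_types",)


def facility_subset_ids(facilities: list[Facility], subset: str) -> list[str]:
    """Facility ids belonging to a named report subset."""
    if subset == "equipped":
        return [f.facility_id for f in facilities]
    if subset == "all_types":
        return [f.facility_id for f in facilities if f.all_types]
    if subset in ANTIVENOM_TYPES:
        return [f.facility_id for f in facilities if subset in f.stocked_types]
    raise ValueError(f"unknown facility subset {subset!r}")


@dataclass
class TypeReport:
    """Band summary for one facility subset plus its per-point assignments."""

    subset: str
    facility_ids: list[str]
    nearest_ids: np.ndarray
    nearest_minutes: np.ndarray
    band_indices: np.ndarray
    rows: list[BandSummaryRow]
    n_routed: int
    n_unreachable: int


def per_type_report(
    facilities: list[Facility],
    demand: list[DemandPoint],
    od: ODMatrix,
    scheme: BandScheme | None = None,
    subsets: tuple[str, ...] = REPORT_SUBSETS,
) -> dict[str, TypeReport]:
    """Nearest-facility banding for each facility subset (all equipped, one
    per antivenom type, all-types stockers). Empty subsets are skipped with a
    warning; unreachable points are excluded from N and counted separately.
    """
    import logging

    scheme = scheme or BandScheme()
    pops = np.array([p.population for p in demand], dtype=float)
    out: dict[str, TypeReport] = {}
    for subset in subsets:
        ids = facility_subset_ids(facilities, subset)
        if not ids:
            logging.getLogger(__name__).warning("subset %r is empty; skipped", subset)
            continue
        near_ids, minutes = nearest_facility(od, ids)
        band_idx = classify_bands(minutes, scheme)
        routed = band_idx >= 0
        rows = summarize_bands(band_idx, pops, scheme)
        out[subset] = TypeReport(
            subset=subset,
            facility_ids=ids,
            nearest_ids=near_ids,
            nearest_minutes=minutes,
            band_indices=band_idx,
            rows=rows,
            n_routed=int(routed.sum()),
            n_unreachable=int((~routed).sum()),
        )
    return out


def report_frame(reports: dict[str, TypeReport]) -> pd.DataFrame:
    """Flatten per-subset band rows into one tidy table."""
    records = []
    for subset, rep in reports.items():
        for row in rep.rows:
            records.append(
                {
                    "subset": subset,
                    "band": row.label,
                    "n_points": row.n_points,
                    "proportion_pct": row.proportion_pct,
                    "area_km2": row.area_km2,
                    "population_persons": row.population_persons,
                    "population_1e4": row.population_1e4,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["subset", "band", "n_points", "proportion_pct", "area_km2",
                 "population_persons", "population_1e4"],
    )
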