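"""Per-cell elasticity metrics.

For each cell the analysis compares the trapped state against the free
and stretched states:

* percent difference in radius   %DR = 100·(R − R_T)/R
* percent difference in area     %DA = 100·(A − A_T)/A
* stiffness                      k = ΔF/ΔR  (pN/μm = μN/m)
* axis ratio                     r_max/r_min

where R/A is the free or stretched radius/area, R_T/A_T the trapped one,
ΔR the longitudinal radius change from trapped to stretched, and ΔF the
net stretching force.  Stiffer cells (sickle-anemia HbSS) show smaller
percent differences and larger k than trait (HbAS) cells.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import (IncompleteRecordError, InvalidArgumentError,
                     UndefinedStiffnessError)
from .records import CellRecord, GeometryMeasurement


@dataclass(frozen=True)
class ElasticityResult:
    """Bundle of per-cell elasticity metrics; stiffness and the
    stretched-state comparisons are None for morphology-only records."""

    cell_id: str
    pct_dr_free: float
    pct_da_free: float
    pct_dr_stretch: Optional[float]
    pct_da_stretch: Optional[float]
    stiffness: Optional[float]      # μN/m
    axis_ratio: float               # of the stretched state when present, else trapped


def percent_diff_radius(reference_radius: float, trapped_radius: float) -> float:
    """%DR = 100·(R − R_T)/R, signed (negative when the trapped cell is larger)."""
    if reference_radius == 0:
        raise ZeroDivisionError("reference_radius must be nonzero")
    if reference_radius < 0:
        raise InvalidArgumentError("reference_radius must be > 0")
    return 100.0 * (reference_radius - trapped_radius) / reference_radius


def percent_diff_area(reference_area: float, trapped_area: float) -> float:
    """%DA = 100·(A − A_T)/A, signed."""
    if reference_area == 0:
        raise ZeroDivisionError("reference_area must be nonzero")
    if reference_area < 0:
        raise InvalidArgumentError("reference_area must be > 0")
    return 100.0 * (reference_area - trapped_area) / reference_area


def stiffness(record: CellRecord, force_mode: str = "net",
              radius_key: str = "r_max") -> float:
    """Cell stiffness k = ΔF/ΔR in μN/m.

    ΔR is the longitudinal (r_max) radius change from trapped to
    stretched — the stretch acts along the drag axis — and ΔF is the net
    stretching force drag − trap (``force_mode="net"``, default) or the
    drag force alone (``force_mode="drag"``).  With forces in pN and
    radii in μm the ratio is already in μN/m.
    """
    if record.stretched is None or record.trapped is None:
        raise IncompleteRecordError(
            f"cell {record.cell_id!r}: stiffness needs trapped and stretched states")
    if force_mode not in ("net", "drag"):
        raise InvalidArgumentError(f"force_mode must be net|drag, got {force_mode!r}")
    if radius_key not in ("r_max", "r_equiv"):
        raise InvalidArgumentError(f"radius_key must be r_max|r_equiv, got {radius_key!r}")
    delta_r = getattr(record.stretched, radius_key) - getattr(record.trapped, radius_key)
    if delta_r == 0:
        raise UndefinedStiffnessError(
            f"cell {record.cell_id!r}: stretched and trapped radius are equal")
    delta_f = record.drag_force_pN - record.trap_force_pN if force_mode == "net" \
        else record.drag_force_pN
    return delta_f / delta_r


def axis_ratio(measurement: GeometryMeasurement) -> float:
    """Longitudinal over transverse semi-axis, >= 1."""
    if measurement.r_min == 0:
        raise ZeroDivisionError("r_min must be nonzero")
    return measurement.r_max / measurement.r_min


def evaluate_cell(record: CellRecord, force_mode: str = "net",
                  radius_key: str = "r_max") -> ElasticityResult:
    """All per-cell metrics; stretched-state metrics are None when absent."""
    if record.trapped is None:
        raise IncompleteRecordError(
            f"cell {record.cell_id!r}: elasticity metrics need a trapped state")
    try:
        free_r = getattr(record.free, radius_key)
        trap_r = getattr(record.trapped, radius_key)
        pct_dr_free = percent_diff_radius(free_r, trap_r)
        pct_da_free = percent_diff_area(record.free.area, record.trapped.area)
        if record.stretched is not None:
            stretch_r = getattr(record.stretched, radius_key)
            pct_dr_stretch = percent_diff_radius(stretch_r, trap_r)
            pct_da_stretch = percent_diff_area(record.stretched.area, record.trapped.area)
            k = stiffness(record, force_mode=force_mode, radius_key=radius_key)
            ratio = axis_ratio(record.stretched)
        else:
            pct_dr_stretch = pct_da_stretch = k = None
            ratio = axis_ratio(record.trapped)
    except (InvalidArgumentError, ZeroDivisionError) as exc:
        raise type(exc)(f"cell {record.cell_id!r}: {exc}") from exc
    return ElasticityResult(
        cell_id=record.cell_id,
        pct_dr_free=pct_dr_free, pct_da_free=pct_da_free,
        pct_dr_stretch=pct_dr_stretch, pct_da_stretch=pct_da_stretch,
        stiffness=k, axis_ratio=ratio)


#: columns of the per-cell metrics table built by :func:`evaluate_table`
METRIC_COLUMNS = [
    "cell_id", "cohort", "subgroup", "free_rmax_um", "trap_force_pN",
    "drag_force_pN", "pct_dr_free", "pct_da_free", "pct_dr_stretch",
    "pct_da_stretch", "stiffness_uN_per_m", "axis_ratio", "delta_radius_um",
]


def evaluate_table(records: Sequence[CellRecord], force_mode: str = "net",
                   radius_key: str = "r_max") -> pd.DataFrame:
    """Per-cell metrics table for a list of records (one row per cell)."""
    rows = []
    for rec in records:
        res = evaluate_cell(rec, force_mode=force_mode, radius_key=radius_key)
        delta_r = (rec.stretched.r_max - rec.trapped.r_max
                   if rec.stretched is not None else math.nan)
        rows.append({
            "cell_id": rec.cell_id, "cohort": rec.cohort, "subgroup": rec.subgroup,
            "free_rmax_um": rec.free.r_max, "trap_force_pN": rec.trap_force_pN,
            "drag_force_pN": rec.drag_force_pN,
            "pct_dr_free": res.pct_dr_free, "pct_da_free": res.pct_da_free,
            "pct_dr_stretch": res.pct_dr_stretch, "pct_da_stretch": res.pct_da_stretch,
            "stiffness_uN_per_m": res.stiffness, "axis_ratio": res.axis_ratio,
            "delta_radius_um": delta_r,
        })
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
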