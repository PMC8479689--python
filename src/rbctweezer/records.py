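"""Per-cell measurement records and their CSV schema.

One :class:`CellRecord` holds the geometry of a cell in up to three
states — free, trapped, and stretched (trapped + dragged) — together
with the forces acting on it and its cohort/subgroup membership.  The
CSV schema is flat, one row per cell, with units embedded in the column
names (μm, μm², pN, μm/s).
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Optional

from .errors import InvalidArgumentError, SchemaError

SCHEMA_VERSION = "1"

#: measurement states a record may carry
STATES = ("free", "trapped", "stretched")


@dataclass(frozen=True)
class GeometryMeasurement:
    """Size measurements of one cell outline.

    ``r_max``/``r_min`` are the longitudinal/transverse semi-axes (μm) of
    the equivalent ellipse, ``r_equiv`` the equivalent circular radius
    √(area/π), ``area`` in μm², ``orientation`` the major-axis angle in
    radians.
    """

    r_max: float
    r_min: float
    area: float
    orientation: float = 0.0

    def __post_init__(self) -> None:
        problems = []
        for name in ("r_max", "r_min", "area", "orientation"):
            v = getattr(self, name)
            if not math.isfinite(v):
                problems.append(f"{name} must be finite, got {v!r}")
        if not problems:
            if not (self.r_max >= self.r_min > 0):
                problems.append(f"need r_max >= r_min > 0, got ({self.r_max}, {self.r_min})")
            if self.area <= 0:
                problems.append("area must be > 0")
        if problems:
            raise InvalidArgumentError("invalid GeometryMeasurement: " + "; ".join(problems))

    @property
    def r_equiv(self) -> float:
        """Equivalent circular radius √(area/π), μm."""
        return math.sqrt(self.area / math.pi)

    @property
    def axis_ratio(self) -> float:
        return self.r_max / self.r_min


@dataclass(frozen=True)
class CellRecord:
    """One cell's measurements, forces and cohort membership.

    ``trapped``/``stretched`` are optional so morphology-only surveys
    (free cells only) share the schema.  Forces are in pN, stage speed in
    μm/s.
    """

    cell_id: str
    cohort: str
    free: GeometryMeasurement
    trapped: Optional[GeometryMeasurement] = None
    stretched: Optional[GeometryMeasurement] = None
    subgroup: Optional[int] = None
    stage_speed_um_s: float = 0.0
    trap_force_pN: float = 0.0
    drag_force_pN: float = 0.0

    def __post_init__(self) -> None:
        problems = []
        if self.subgroup is not None and not (1 <= self.subgroup <= 7):
            problems.append(f"subgroup must be in 1..7, got {self.subgroup}")
        if self.trap_force_pN < 0 or self.drag_force_pN < 0:
            problems.append("forces must be >= 0")
        if self.stage_speed_um_s < 0:
            problems.append("stage_speed_um_s must be >= 0")
        if self.stretched is not None and self.trapped is None:
            problems.append("stretched state requires a trapped state")
        if problems:
            raise InvalidArgumentError(f"invalid CellRecord {self.cell_id!r}: " + "; ".join(problems))

    def measurement(self, state: str) -> Optional[GeometryMeasurement]:
        if state not in STATES:
            raise InvalidArgumentError(f"unknown state {state!r}")
        return getattr(self, state)


def _state_columns(state: str) -> list[str]:
    return [f"{state}_rmax_um", f"{state}_rmin_um", f"{state}_area_um2",
            f"{state}_orientation_rad"]


CSV_COLUMNS = (
    ["cell_id", "cohort", "subgroup", "stage_speed_um_s",
     "trap_force_pN", "drag_force_pN"]
    + _state_columns("free") + _state_columns("trapped") + _state_columns("stretched")
)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_records(records: list[CellRecord], path) -> None:
    """Write records to CSV, one row per cell; floats round-trip exactly."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            row = [rec.cell_id, rec.cohort,
                   "" if rec.subgroup is None else rec.subgroup,
                   _fmt(rec.stage_speed_um_s), _fmt(rec.trap_force_pN),
                   _fmt(rec.drag_force_pN)]
            for state in STATES:
                m = rec.measurement(state)
                if m is None:
                    row += ["", "", "", ""]
                else:
                    row += [_fmt(m.r_max), _fmt(m.r_min), _fmt(m.area),
                            _fmt(m.orientation)]
            writer.writerow(row)


def _parse_float(text: str, row: int, column: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise SchemaError(
            f"row {row}, column {column!r}: cannot parse {text!r} as number") from exc


def _parse_state(fields: dict, state: str, row: int) -> Optional[GeometryMeasurement]:
    cols = _state_columns(state)
    values = [fields[c] for c in cols]
    if all(v == "" for v in values):
        return None
    parsed = [_parse_float(v, row, c) for v, c in zip(values, cols)]
    return GeometryMeasurement(r_max=parsed[0], r_min=parsed[1],
                               area=parsed[2], orientation=parsed[3])


def read_records(path) -> list[CellRecord]:
    """Read a record CSV written by :func:`write_records`.

    Raises :class:`SchemaError` naming the missing column or the
    offending row/column on malformed input.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        records = []
        for i, fields in enumerate(reader, start=2):  # header is row 1
            subgroup_text = fields["subgroup"]
            subgroup = int(_parse_float(subgroup_text, i, "subgroup")) if subgroup_text else None
            try:
                rec = CellRecord(
                    cell_id=fields["cell_id"],
                    cohort=fields["cohort"],
                    subgroup=subgroup,
                    stage_speed_um_s=_parse_float(fields["stage_speed_um_s"], i, "stage_speed_um_s"),
                    trap_force_pN=_parse_float(fields["trap_force_pN"], i, "trap_force_pN"),
                    drag_force_pN=_parse_float(fields["drag_force_pN"], i, "drag_force_pN"),
                    free=_parse_state(fields, "free", i),
                    trapped=_parse_state(fields, "trapped", i),
                    stretched=_parse_state(fields, "stretched", i),
                )
            except InvalidArgumentError as exc:
                raise SchemaError(f"row {i}: {exc}") from exc
            if rec.free is None:
                raise SchemaError(f"row {i}: free-state measurement is required")
            records.append(rec)
    return records
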