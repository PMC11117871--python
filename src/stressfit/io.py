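"""CSV / TOML input-output for traces, geometry and coefficient tables.

Trace dialect: comma-separated, "." decimal, LF line endings, UTF-8, header
columns ``time_s, force_N, displacement_mm``.  Geometry travels separately
(never inferred from data) as a small TOML sidecar or explicit arguments.
Coefficient tables mirror the published appendix layout: one row per fitted
model, stress rows carrying c0..c3 and stretch rows d2..d0, with unused
cells left empty, numbers at 6 significant digits, fixed column order —
so identical inputs and seed produce byte-identical files.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, TraceFormatError, TraceOrderingError
from .mechanics import LoadTestRecord, SpecimenGeometry

__all__ = [
    "CoefficientTableRow",
    "read_trace_csv",
    "write_trace_csv",
    "read_geometry_toml",
    "write_geometry_toml",
    "read_coefficient_table",
    "write_coefficient_table",
]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("time_s", "force_N", "displacement_mm")

COEFFICIENT_COLUMNS = (
    "specimen",
    "experiment",
    "cycle",
    "type",
    "direction",
    "c0",
    "c1",
    "c2",
    "c3",
    "d2",
    "d1",
    "d0",
    "r_squared",
    "mode",
    "time_origin_s",
)


@dataclass(frozen=True)
class CoefficientTableRow:
    """One row of the output coefficient table.

    ``record_type`` is "stress" (4 coefficients, c0..c3) or "stretch"
    (3 coefficients, d2, d1, d0).
    """

    specimen_id: str
    experiment_id: str
    cycle_index: int
    record_type: str
    direction: str
    coefficients: tuple
    r_squared: float
    fit_mode: str
    time_origin_s: float

    def __post_init__(self):
        expected = {"stress": 4, "stretch": 3}.get(self.record_type)
        if expected is None:
            raise InvalidArgumentError(f"record_type must be stress|stretch, got {self.record_type!r}")
        if len(self.coefficients) != expected:
            raise InvalidArgumentError(
                f"{self.record_type} rows carry exactly {expected} coefficients, "
                f"got {len(self.coefficients)}"
            )


# ---------------------------------------------------------------------------
# traces


def read_trace_csv(
    path,
    geometry: SpecimenGeometry | None = None,
    geometry_path=None,
    specimen_id: str = "",
    experiment_id: str = "",
) -> LoadTestRecord:
    """Read a raw trace CSV into a validated :class:`LoadTestRecord`.

    Rows containing non-finite values are dropped with their CSV line
    numbers logged.  Missing columns raise :class:`TraceFormatError` naming
    the column; non-monotone time raises :class:`TraceOrderingError`.
    """
    if geometry is None and geometry_path is None:
        raise InvalidArgumentError("specimen geometry required (argument or sidecar file)")
    if geometry is None:
        geometry = read_geometry_toml(geometry_path)

    df = pd.read_csv(path, float_precision="round_trip")
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise TraceFormatError(f"{path}: missing required column {col!r}")
    df = df[list(TRACE_COLUMNS)].apply(pd.to_numeric, errors="coerce")

    bad = ~np.isfinite(df.to_numpy()).all(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header line and 1-based numbering
        logger.warning("%s: dropping %d row(s) with non-finite values at line(s) %s",
                       path, int(bad.sum()), lines)
        df = df[~bad]

    t = df["time_s"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise TraceOrderingError(f"{path}: time_s is not strictly increasing")
    return LoadTestRecord(
        time_s=t,
        force_n=df["force_N"].to_numpy(),
        displacement_mm=df["displacement_mm"].to_numpy(),
        geometry=geometry,
        specimen_id=specimen_id,
        experiment_id=experiment_id,
    )


def write_trace_csv(record: LoadTestRecord, path) -> None:
    """Write a trace in the package dialect (lossless float formatting)."""
    df = pd.DataFrame(
        {
            "time_s": record.time_s,
            "force_N": record.force_n,
            "displacement_mm": record.displacement_mm,
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# geometry sidecars


def read_geometry_toml(path) -> SpecimenGeometry:
    """Read specimen geometry from a TOML sidecar (keys length_mm, surface_mm2, ...)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    try:
        return SpecimenGeometry(
            length_mm=data["length_mm"],
            surface_mm2=data["surface_mm2"],
            delta_length_mm=data.get("delta_length_mm"),
            delta_surface_mm2=data.get("delta_surface_mm2"),
        )
    except KeyError as exc:
        raise TraceFormatError(f"{path}: missing geometry key {exc}") from exc


def write_geometry_toml(geometry: SpecimenGeometry, path) -> None:
    lines = [
        f"length_mm = {geometry.length_mm!r}",
        f"surface_mm2 = {geometry.surface_mm2!r}",
    ]
    if geometry.delta_length_mm is not None:
        lines.append(f"delta_length_mm = {geometry.delta_length_mm!r}")
    if geometry.delta_surface_mm2 is not None:
        lines.append(f"delta_surface_mm2 = {geometry.delta_surface_mm2!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# coefficient tables


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_coefficient_table(rows, path) -> None:
    """Write fitted coefficients as CSV (6 significant digits, fixed columns)."""
    out_lines = [",".join(COEFFICIENT_COLUMNS)]
    for row in rows:
        cells = dict.fromkeys(COEFFICIENT_COLUMNS, "")
        cells["specimen"] = str(row.specimen_id)
        cells["experiment"] = str(row.experiment_id)
        cells["cycle"] = str(row.cycle_index)
        cells["type"] = row.record_type
        cells["direction"] = row.direction
        names = ("c0", "c1", "c2", "c3") if row.record_type == "stress" else ("d2", "d1", "d0")
        for name, value in zip(names, row.coefficients):
            cells[name] = _fmt(value)
        cells["r_squared"] = _fmt(row.r_squared)
        cells["mode"] = row.fit_mode
        cells["time_origin_s"] = _fmt(row.time_origin_s)
        out_lines.append(",".join(cells[c] for c in COEFFICIENT_COLUMNS))
    Path(path).write_text("\n".join(out_lines) + "\n", encoding="utf-8", newline="\n")


def read_coefficient_table(path) -> list[CoefficientTableRow]:
    """Parse a coefficient table written by :func:`write_coefficient_table`."""
    df = pd.read_csv(path, dtype={"specimen": str, "experiment": str})
    missing = set(COEFFICIENT_COLUMNS) - set(df.columns)
    if missing:
        raise TraceFormatError(f"{path}: missing coefficient columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        record_type = r["type"]
        names = ("c0", "c1", "c2", "c3") if record_type == "stress" else ("d2", "d1", "d0")
        rows.append(
            CoefficientTableRow(
                specimen_id=str(r["specimen"]),
                experiment_id=str(r["experiment"]),
                cycle_index=int(r["cycle"]),
                record_type=record_type,
                direction=r["direction"],
                coefficients=tuple(float(r[n]) for n in names),
                r_squared=float(r["r_squared"]),
                fit_mode=r["mode"],
                time_origin_s=float(r["time_origin_s"]),
            )
        )
    return rows
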