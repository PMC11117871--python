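"""Conversion of raw machine output to stress and stretch.

A compression test machine records time (s), load force (N) and crosshead
displacement (mm).  Given the specimen geometry — length ``L`` between the
loading surfaces and loading surface area ``S`` — the engineering stress is
``sigma = F / S`` (MPa, since N/mm^2 = MPa) and the stretch is
``lambda = (L - l) / L``, which equals 1 at rest and decreases under
compression.  Compressive force and stress are taken positive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError, InvalidArgumentError

__all__ = ["SpecimenGeometry", "LoadTestRecord", "StressStretchTrace", "to_stress_stretch"]


@dataclass(frozen=True)
class SpecimenGeometry:
    """Specimen geometry with optional measurement uncertainties.

    Parameters
    ----------
    length_mm : vertebra length L between the loading surfaces (mm).
    surface_mm2 : loading surface area S (mm^2).
    delta_length_mm, delta_surface_mm2 : optional half-width uncertainties
        of the two measurements (same units), used by the error budget.
    """

    length_mm: float
    surface_mm2: float
    delta_length_mm: float | None = None
    delta_surface_mm2: float | None = None

    def __post_init__(self):
        if not (np.isfinite(self.length_mm) and self.length_mm > 0):
            raise GeometryError(f"length_mm must be positive, got {self.length_mm}")
        if not (np.isfinite(self.surface_mm2) and self.surface_mm2 > 0):
            raise GeometryError(f"surface_mm2 must be positive, got {self.surface_mm2}")
        for name in ("delta_length_mm", "delta_surface_mm2"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v >= 0):
                raise GeometryError(f"{name} must be >= 0, got {v}")


def _column(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidArgumentError(f"{name} must be 1-D")
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class LoadTestRecord:
    """One raw compression-test record: time, force, displacement + geometry.

    ``ground_truth`` is populated by the synthetic generators with the
    per-segment model pair actually used (after continuity adjustment), so
    round-trip tests can compare fits against the exact generating models.
    """

    time_s: np.ndarray
    force_n: np.ndarray
    displacement_mm: np.ndarray
    geometry: SpecimenGeometry
    specimen_id: str = ""
    experiment_id: str = ""
    ground_truth: tuple | None = field(default=None, compare=False)

    def __post_init__(self):
        t = _column(self.time_s, "time_s")
        f = _column(self.force_n, "force_n")
        d = _column(self.displacement_mm, "displacement_mm")
        if not (len(t) == len(f) == len(d)):
            raise InvalidArgumentError(
                f"column length mismatch: time={len(t)}, force={len(f)}, displacement={len(d)}"
            )
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise InvalidArgumentError("time_s must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "force_n", f)
        object.__setattr__(self, "displacement_mm", d)

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class StressStretchTrace:
    """Per-sample stress (MPa) and stretch derived from a load-test record."""

    time_s: np.ndarray
    stress_mpa: np.ndarray
    stretch: np.ndarray
    source: LoadTestRecord | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.time_s)


def to_stress_stretch(record: LoadTestRecord, rezero_displacement: bool = True) -> StressStretchTrace:
    """Convert force to stress (``F/S``) and displacement to stretch (``(L-l)/L``).

    With ``rezero_displacement`` (default) the displacement is taken relative
    to the first sample, so every record starts at stretch 1; this matches
    the convention under which fitted stretch intercepts sit at ~1.0 for
    loading segments.  Raw signals are not smoothed or filtered here.
    """
    geom = record.geometry
    disp = record.displacement_mm
    if rezero_displacement and len(disp):
        disp = disp - disp[0]
    stress = record.force_n / geom.surface_mm2
    stretch = (geom.length_mm - disp) / geom.length_mm
    return StressStretchTrace(
        time_s=record.time_s,
        stress_mpa=stress,
        stretch=stretch,
        source=record,
    )
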