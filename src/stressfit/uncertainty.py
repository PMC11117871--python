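"""Measurement uncertainty: confidence intervals and error propagation.

Specimen geometry is measured a handful of times; the 95% confidence
half-width of such a measurement set is ``t * s / sqrt(n)`` with ``s`` the
sample standard deviation (n - 1 divisor) and ``t`` the two-sided Student-t
critical value at n - 1 degrees of freedom (4.303 for three repeats).

Machine errors propagate to the derived quantities as

* relative stress error:  ``delta_sigma / |sigma| = sqrt((dF/F)^2 + (dS/S)^2)``
  (quadrature sum for a quotient of independent quantities);
* stretch error: by the source convention ``delta_lambda = delta_l / L^2``.
  Dimensional analysis of lambda = (L - l)/L gives d(lambda)/d(l) = 1/L, so
  a ``convention="dimensional"`` switch selects ``delta_l / L`` instead;
  the verbatim form remains the default for fidelity to the published
  procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidArgumentError

__all__ = [
    "MeasurementSet",
    "ErrorBudget",
    "student_t_critical",
    "confidence_halfwidth",
    "propagate_stress_error",
    "propagate_stretch_error",
]


@dataclass(frozen=True)
class MeasurementSet:
    """Repeated measurements of one quantity, evaluated at a fixed 95% level."""

    values: tuple
    confidence_level: float = 0.95

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 2:
            raise InvalidArgumentError("a measurement set needs at least 2 values")
        if not all(np.isfinite(v) for v in vals):
            raise InvalidArgumentError("measurement values must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def std(self) -> float:
        """Sample standard deviation (n - 1 divisor)."""
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class ErrorBudget:
    """Instrument uncertainties and the errors they induce on stress and stretch."""

    delta_force_n: float
    delta_surface_mm2: float
    delta_displacement_mm: float
    relative_stress_error: float
    delta_stretch: float

    def __post_init__(self):
        for name in (
            "delta_force_n",
            "delta_surface_mm2",
            "delta_displacement_mm",
            "relative_stress_error",
            "delta_stretch",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise InvalidArgumentError(f"{name} must be >= 0, got {v}")


def student_t_critical(df: int, confidence: float = 0.95) -> float:
    """Two-sided Student-t critical value (e.g. 4.303 at df = 2, 95%)."""
    if df < 1:
        raise InvalidArgumentError(f"df must be >= 1, got {df}")
    if not 0 < confidence < 1:
        raise InvalidArgumentError(f"confidence must be in (0, 1), got {confidence}")
    return float(stats.t.ppf(0.5 + confidence / 2.0, df))


def confidence_halfwidth(measurements: MeasurementSet, t_value: float | None = None) -> float:
    """Confidence half-width ``t * s / sqrt(n)`` of a measurement set.

    ``t_value`` defaults to the two-sided critical value at n - 1 degrees of
    freedom for the set's confidence level.
    """
    if t_value is None:
        t_value = student_t_critical(measurements.n - 1, measurements.confidence_level)
    if t_value <= 0:
        raise InvalidArgumentError(f"t_value must be positive, got {t_value}")
    return t_value * measurements.std / np.sqrt(measurements.n)


def propagate_stress_error(
    force_n: float, delta_force_n: float, surface_mm2: float, delta_surface_mm2: float
) -> float:
    """Relative stress error sqrt((dF/F)^2 + (dS/S)^2) for sigma = F/S."""
    if force_n == 0 or surface_mm2 == 0:
        raise InvalidArgumentError("force and surface must be non-zero")
    if delta_force_n < 0 or delta_surface_mm2 < 0:
        raise InvalidArgumentError("uncertainties must be >= 0")
    return float(np.hypot(delta_force_n / force_n, delta_surface_mm2 / surface_mm2))


def propagate_stretch_error(
    delta_displacement_mm: float, length_mm: float, convention: str = "paper"
) -> float:
    """Stretch uncertainty induced by the displacement measurement.

    ``convention="paper"`` (default) applies the published form
    ``delta_l / L^2``; ``convention="dimensional"`` applies ``delta_l / L``,
    the derivative of (L - l)/L with respect to l.
    """
    if length_mm <= 0:
        raise InvalidArgumentError(f"length_mm must be positive, got {length_mm}")
    if delta_displacement_mm < 0:
        raise InvalidArgumentError("delta_displacement_mm must be >= 0")
    if convention == "paper":
        return delta_displacement_mm / length_mm**2
    if convention == "dimensional":
        return delta_displacement_mm / length_mm
    raise InvalidArgumentError(f"unknown convention {convention!r} (use 'paper' or 'dimensional')")
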