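"""Parametric models for compressive load-test curves.

A half-cycle of a compression test is described by two curves sharing the
time parameter ``t``:

* a *modified logistic* stress model

  .. math:: \\sigma(t) = C_0 + \\frac{C_1}{1 + e^{-C_2 (t - C_3)}}

  where ``C0`` shifts the sigmoid along the stress axis, ``C0 + C1`` is the
  upper asymptote (the theoretical ultimate-strength limit), ``C2`` sets the
  exponential rise/fall scale and ``C3`` marks the curve midpoint;

* a quadratic stretch model ``lambda(t) = D2 t^2 + D1 t + D0``.

Evaluating both on a common time grid traces the stress-stretch curve in
parametric form.  When the stretch is (effectively) linear in time the pair
collapses analytically to a logistic function *of stretch* with transformed
coefficients ``C2' = C2 / D1`` and ``C3' = D0 + D1 C3``; this module
implements that transformation and the midpoint tangent ``C1 C2 / 4``.

All evaluations go through :func:`scipy.special.expit`, which saturates to
the asymptotes for arbitrarily large ``|C2 (t - C3)|`` instead of
overflowing (sharp near-step fits reach ``C2`` of several hundred).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.special import expit

from .exceptions import (
    DegenerateStretchError,
    InvalidArgumentError,
    NonLinearStretchError,
)

__all__ = [
    "LogisticStressModel",
    "QuadraticStretchModel",
    "ParametricCyclePair",
    "eval_stress",
    "eval_stretch",
    "tangent_at_midpoint",
    "to_stretch_domain",
    "compose_stress_stretch",
]

Direction = Literal["load", "unload"]

#: Default absolute bound on |D2| below which stretch counts as linear in
#: time.  Published linear segments sit at |D2| <= ~3e-2 while genuinely
#: curved ones exceed 20, so 1e-3 separates the regimes with wide margin.
DEFAULT_D2_TOLERANCE = 1e-3


def _require_finite_params(name: str, *values: float) -> None:
    for v in values:
        if not np.isfinite(v):
            raise InvalidArgumentError(f"{name}: coefficients must be finite, got {values}")


def _as_finite_array(t, what: str = "t") -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError(f"{what} must be finite")
    return arr


@dataclass(frozen=True)
class LogisticStressModel:
    """Modified logistic stress curve ``C0 + C1 / (1 + exp(-C2 (t - C3)))``.

    The independent variable is segment-local time in seconds in the usual
    (time-domain) mode, or stretch when the model was fitted with stretch as
    the independent variable.  Stress is in MPa.
    """

    c0: float
    c1: float
    c2: float
    c3: float

    def __post_init__(self):
        _require_finite_params("LogisticStressModel", self.c0, self.c1, self.c2, self.c3)

    def predict(self, t):
        """Evaluate the stress curve; saturates (never overflows) for large exponents."""
        arr = _as_finite_array(t)
        out = self.c0 + self.c1 * expit(self.c2 * (arr - self.c3))
        return out if arr.ndim else float(out)

    __call__ = predict

    @property
    def midpoint_slope(self) -> float:
        """Slope of the curve at its midpoint t = C3: tan(alpha) = C1 C2 / 4."""
        return self.c1 * self.c2 / 4.0

    @property
    def upper_asymptote(self) -> float:
        """C0 + C1 — the theoretical ultimate-strength limit for a rising curve."""
        return self.c0 + self.c1

    def canonical(self) -> "LogisticStressModel":
        """Equivalent model with C1 > 0.

        The logistic family has the exact symmetry
        ``(C0, C1, C2, C3) == (C0 + C1, -C1, -C2, C3)``; this picks the
        representative with positive amplitude so that a falling (unloading)
        curve is encoded by C2 < 0.
        """
        if self.c1 < 0:
            return replace(self, c0=self.c0 + self.c1, c1=-self.c1, c2=-self.c2)
        return self


@dataclass(frozen=True)
class QuadraticStretchModel:
    """Quadratic stretch-time curve ``D2 t^2 + D1 t + D0`` (stretch is dimensionless)."""

    d2: float
    d1: float
    d0: float

    def __post_init__(self):
        _require_finite_params("QuadraticStretchModel", self.d2, self.d1, self.d0)

    def predict(self, t):
        arr = _as_finite_array(t)
        out = (self.d2 * arr + self.d1) * arr + self.d0
        return out if arr.ndim else float(out)

    __call__ = predict

    def linearized(self) -> "QuadraticStretchModel":
        """Copy with the quadratic term dropped (D2 = 0)."""
        return replace(self, d2=0.0)


@dataclass(frozen=True)
class ParametricCyclePair:
    """Stress and stretch models for one half-cycle k, on a shared local clock."""

    stress: LogisticStressModel
    stretch: QuadraticStretchModel
    cycle_index: int = 1
    direction: Direction = "load"

    def __post_init__(self):
        if self.cycle_index < 1:
            raise InvalidArgumentError(f"cycle_index must be >= 1, got {self.cycle_index}")
        if self.direction not in ("load", "unload"):
            raise InvalidArgumentError(f"direction must be 'load' or 'unload', got {self.direction!r}")


def eval_stress(model: LogisticStressModel, t):
    """Stress at time (or stretch) ``t`` under the modified logistic model."""
    return model.predict(t)


def eval_stretch(model: QuadraticStretchModel, t):
    """Stretch at time ``t`` under the quadratic model."""
    return model.predict(t)


def tangent_at_midpoint(model: LogisticStressModel) -> float:
    """Slope of the logistic stress curve at its midpoint, ``C1 C2 / 4`` (MPa/s)."""
    return model.midpoint_slope


def to_stretch_domain(
    pair: ParametricCyclePair,
    d2_tolerance: float = DEFAULT_D2_TOLERANCE,
) -> LogisticStressModel:
    """Re-express a time-parameterized half-cycle as stress vs. stretch.

    Requires stretch effectively linear in time (|D2| <= ``d2_tolerance``).
    Substituting ``t = (lambda - D0) / D1`` into the stress model gives a
    logistic in stretch with ``C2' = C2 / D1`` and ``C3' = D0 + D1 C3``
    (offset and amplitude unchanged).

    Raises
    ------
    NonLinearStretchError
        If |D2| exceeds the tolerance; such half-cycles (they do occur in
        real cyclic tests) have no single-valued stress-stretch logistic.
    DegenerateStretchError
        If D1 = 0 (stretch constant in time).
    """
    d2 = pair.stretch.d2
    if abs(d2) > d2_tolerance:
        raise NonLinearStretchError(
            f"|D2| = {abs(d2):g} exceeds tolerance {d2_tolerance:g}: stretch is not "
            "linear in time, stress-stretch transformation undefined for this segment"
        )
    d1 = pair.stretch.d1
    if d1 == 0:
        raise DegenerateStretchError("D1 = 0: stretch does not vary with time")
    s = pair.stress
    return LogisticStressModel(
        c0=s.c0,
        c1=s.c1,
        c2=s.c2 / d1,
        c3=pair.stretch.d0 + d1 * s.c3,
    )


def compose_stress_stretch(pair: ParametricCyclePair, t_grid) -> np.ndarray:
    """Trace the parametric stress-stretch curve on a time grid.

    Returns an array of shape ``(n, 2)`` with columns ``(stretch, stress)``
    — the fitted curve as it is drawn against experimental hysteresis loops.
    """
    grid = _as_finite_array(t_grid, "t_grid")
    if grid.ndim != 1 or grid.size == 0:
        raise InvalidArgumentError("t_grid must be a non-empty 1-D array")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise InvalidArgumentError("t_grid must be strictly increasing")
    return np.column_stack([pair.stretch.predict(grid), pair.stress.predict(grid)])
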