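"""Per-segment least-squares estimation of the stress and stretch models.

The logistic stress model is fitted by derivative-based nonlinear least
squares (Levenberg-Marquardt with an analytic Jacobian) from a heuristic
initial guess; the quadratic stretch model by ordinary least squares on the
quadratic basis, which is exact for polynomial data.  Goodness of fit is
the coefficient of determination R^2 = 1 - SSres/SStot.

Conventions
-----------
* Each segment is fitted on its own re-zeroed clock, t' = t - t_start; the
  time origin used is carried on the fit so coefficient tables stay
  interpretable.
* Logistic fits are canonicalized to C1 > 0 (exact model symmetry), so a
  falling (unloading) stress segment is encoded by C2 < 0.
* Unloading segments are fitted on forward time; no time reversal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .exceptions import DegenerateDataError, FitConvergenceError, InvalidArgumentError
from .models import LogisticStressModel, ParametricCyclePair, QuadraticStretchModel
from .segmentation import CycleSegment

__all__ = [
    "LogisticStressFit",
    "QuadraticStretchFit",
    "CycleFitResult",
    "r_squared",
    "fit_logistic_stress",
    "fit_quadratic_stretch",
    "fit_cycle",
]

logger = logging.getLogger(__name__)

FitMode = Literal["time", "stretch"]

_MIN_LOGISTIC_SAMPLES = 5
_MIN_QUADRATIC_SAMPLES = 4
_MAX_RESTARTS = 5
_LSQ_TOL = 1e-12


@dataclass(frozen=True)
class LogisticStressFit:
    """A converged logistic stress fit for one segment."""

    model: LogisticStressModel
    r_squared: float
    mode: FitMode = "time"
    n_obs: int = 0
    time_origin_s: float = 0.0
    cost: float = 0.0
    segment: CycleSegment | None = None


@dataclass(frozen=True)
class QuadraticStretchFit:
    """An OLS quadratic stretch fit for one segment.

    ``direction_label`` follows the sign of the fitted linear rate D1:
    "down" for compression (stretch decreasing), "up" for recovery.
    """

    model: QuadraticStretchModel
    r_squared: float
    direction_label: Literal["down", "up"] = "down"
    n_obs: int = 0
    time_origin_s: float = 0.0
    segment: CycleSegment | None = None


@dataclass(frozen=True)
class CycleFitResult:
    """Both fits for one half-cycle; ``pair`` composes them parametrically."""

    stress: LogisticStressFit
    stretch: QuadraticStretchFit | None
    pair: ParametricCyclePair | None
    time_origin_s: float = 0.0


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SSres/SStot.

    Raises :class:`DegenerateDataError` when the observed series has zero
    variance (SStot = 0), for which R^2 is undefined.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise InvalidArgumentError("observed and predicted must be equal-length 1-D, n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDataError("observed series is constant: R^2 undefined (SStot = 0)")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def _initial_guess(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Heuristic start for the logistic fit.

    C0 <- min stress, C1 <- stress range, C3 <- abscissa of the half-range
    crossing, and C2 from inverting the midpoint-slope relation
    tan(alpha) = C1 C2 / 4 with the slope approximated as the range covered
    over half the span (so C2_0 ~ 8/span), sign-matched to the trend.
    """
    ymin, ymax = float(y.min()), float(y.max())
    yrange = ymax - ymin
    span = float(x[-1] - x[0])  # negative when x decreases (stretch under load)
    if span == 0:
        raise DegenerateDataError("independent variable has zero span")
    c3 = float(x[int(np.argmin(np.abs(y - (ymin + 0.5 * yrange))))])
    slope = (ymax - ymin if y[-1] >= y[0] else ymin - ymax) / (0.5 * span)
    c2 = 4.0 * slope / yrange
    return np.array([ymin, yrange, c2, c3])


def _residuals_and_jac(x: np.ndarray, y: np.ndarray):
    def fun(p):
        c0, c1, c2, c3 = p
        return c0 + c1 * expit(c2 * (x - c3)) - y

    def jac(p):
        _c0, c1, c2, c3 = p
        e = expit(c2 * (x - c3))
        de = e * (1.0 - e)
        return np.column_stack([np.ones_like(x), e, c1 * de * (x - c3), -c1 * c2 * de])

    return fun, jac


def fit_logistic_stress(
    x,
    stress,
    mode: FitMode = "time",
    init: LogisticStressModel | None = None,
    seed: int = 0,
    max_restarts: int = _MAX_RESTARTS,
    bounds=None,
    time_origin_s: float = 0.0,
    segment: CycleSegment | None = None,
) -> LogisticStressFit:
    """Fit the modified logistic stress model by nonlinear least squares.

    Parameters
    ----------
    x : independent variable — segment-local time (``mode="time"``) or
        stretch (``mode="stretch"``, the load-to-fracture convention).
    stress : observed stress, MPa.
    init : optional explicit starting model; default is the heuristic guess.
    seed : seeds the jittered restarts tried if the optimizer fails.
    bounds : optional ``(lower, upper)`` 4-vectors; switches the optimizer
        from Levenberg-Marquardt to a trust-region reflective method.

    Raises
    ------
    DegenerateDataError : constant stress (no amplitude to fit).
    FitConvergenceError : optimizer failure after all restarts, with
        diagnostics attached.
    """
    xarr = np.asarray(x, dtype=float)
    yarr = np.asarray(stress, dtype=float)
    if xarr.shape != yarr.shape or xarr.ndim != 1:
        raise InvalidArgumentError("x and stress must be equal-length 1-D arrays")
    if xarr.size < _MIN_LOGISTIC_SAMPLES:
        raise InvalidArgumentError(
            f"logistic fit needs >= {_MIN_LOGISTIC_SAMPLES} samples, got {xarr.size}"
        )
    if not (np.all(np.isfinite(xarr)) and np.all(np.isfinite(yarr))):
        raise InvalidArgumentError("non-finite values in fit input")
    if np.ptp(yarr) == 0.0:
        raise DegenerateDataError("stress is constant: logistic amplitude unidentifiable")

    p0 = (
        np.array([init.c0, init.c1, init.c2, init.c3], dtype=float)
        if init is not None
        else _initial_guess(xarr, yarr)
    )
    fun, jac = _residuals_and_jac(xarr, yarr)
    rng = np.random.default_rng(seed)
    scale = np.where(np.abs(p0) > 0, np.abs(p0), 1.0)

    last_diag: dict = {}
    for attempt in range(max_restarts + 1):
        p_start = p0 if attempt == 0 else p0 + 0.3 * scale * rng.standard_normal(4)
        try:
            res = least_squares(
                fun,
                p_start,
                jac=jac,
                method="lm" if bounds is None else "trf",
                bounds=bounds if bounds is not None else (-np.inf, np.inf),
                xtol=_LSQ_TOL,
                ftol=_LSQ_TOL,
                gtol=_LSQ_TOL,
                max_nfev=20000,
            )
        except (ValueError, np.linalg.LinAlgError) as exc:  # pathological Jacobian
            last_diag = {"attempt": attempt, "error": str(exc)}
            continue
        last_diag = {
            "attempt": attempt,
            "status": res.status,
            "message": res.message,
            "cost": float(res.cost),
        }
        if res.success and np.all(np.isfinite(res.x)) and res.x[1] != 0.0:
            model = LogisticStressModel(*res.x).canonical()
            r2 = r_squared(yarr, model.predict(xarr))
            logger.info(
                "logistic fit (%s): C=%s R2=%.6g after %d restart(s)",
                mode, np.round(res.x, 6).tolist(), r2, attempt,
            )
            return LogisticStressFit(
                model=model,
                r_squared=r2,
                mode=mode,
                n_obs=xarr.size,
                time_origin_s=time_origin_s,
                cost=float(res.cost),
                segment=segment,
            )
    raise FitConvergenceError(
        f"logistic fit did not converge after {max_restarts} restarts", last_diag
    )


def fit_quadratic_stretch(
    t,
    stretch,
    time_origin_s: float = 0.0,
    segment: CycleSegment | None = None,
) -> QuadraticStretchFit:
    """Fit the quadratic stretch-time model by ordinary least squares.

    Uses a scaled-domain polynomial fit (numerically well conditioned) and
    converts back to power-basis coefficients; exact to round-off for
    noiseless quadratic input.  A constant stretch series is fitted exactly
    by the intercept and reported with R^2 = 1.
    """
    tarr = np.asarray(t, dtype=float)
    yarr = np.asarray(stretch, dtype=float)
    if tarr.shape != yarr.shape or tarr.ndim != 1:
        raise InvalidArgumentError("t and stretch must be equal-length 1-D arrays")
    if tarr.size < _MIN_QUADRATIC_SAMPLES:
        raise InvalidArgumentError(
            f"quadratic fit needs >= {_MIN_QUADRATIC_SAMPLES} samples, got {tarr.size}"
        )
    if not (np.all(np.isfinite(tarr)) and np.all(np.isfinite(yarr))):
        raise InvalidArgumentError("non-finite values in fit input")
    if np.unique(tarr).size < 3:
        raise DegenerateDataError("need >= 3 distinct time values for a quadratic fit")

    poly = np.polynomial.Polynomial.fit(tarr, yarr, deg=2).convert()
    coef = np.zeros(3)
    coef[: poly.coef.size] = poly.coef  # trailing zero coefficients may be trimmed
    d0, d1, d2 = coef
    model = QuadraticStretchModel(d2=float(d2), d1=float(d1), d0=float(d0))

    pred = model.predict(tarr)
    if np.ptp(yarr) == 0.0:
        r2 = 1.0  # exact constant fit; variance-based R^2 is undefined
    else:
        r2 = r_squared(yarr, pred)
    return QuadraticStretchFit(
        model=model,
        r_squared=r2,
        direction_label="down" if d1 < 0 else "up",
        n_obs=tarr.size,
        time_origin_s=time_origin_s,
        segment=segment,
    )


def fit_cycle(
    segment: CycleSegment,
    mode: FitMode = "time",
    seed: int = 0,
    bounds=None,
) -> CycleFitResult:
    """Fit one half-cycle on its re-zeroed local clock.

    In time mode both models are fitted against t' = t - t_start and paired
    for parametric composition.  In stretch mode (load-to-fracture style,
    valid when the crosshead moves at constant velocity) the logistic is
    fitted with stretch as the independent variable and the quadratic fit
    is skipped.
    """
    t_origin = float(segment.time_s[0])
    t_local = segment.time_s - t_origin
    # Decorrelate restart jitter across segments while staying reproducible.
    seg_seed = (seed + 977 * segment.cycle_index + (1 if segment.direction == "unload" else 0)) % (2**31)

    if mode == "stretch":
        sfit = fit_logistic_stress(
            segment.stretch, segment.stress_mpa, mode="stretch",
            seed=seg_seed, bounds=bounds, time_origin_s=t_origin, segment=segment,
        )
        return CycleFitResult(stress=sfit, stretch=None, pair=None, time_origin_s=t_origin)

    sfit = fit_logistic_stress(
        t_local, segment.stress_mpa, mode="time",
        seed=seg_seed, bounds=bounds, time_origin_s=t_origin, segment=segment,
    )
    qfit = fit_quadratic_stretch(t_local, segment.stretch, time_origin_s=t_origin, segment=segment)
    pair = ParametricCyclePair(
        stress=sfit.model,
        stretch=qfit.model,
        cycle_index=segment.cycle_index,
        direction=segment.direction,
    )
    return CycleFitResult(stress=sfit, stretch=qfit, pair=pair, time_origin_s=t_origin)
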