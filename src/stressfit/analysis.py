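"""High-level modelling interface: build a test, fit it, inspect results.

Follows the model/results convention of statistical modelling packages:

>>> test = CompressionTest.from_record(record)        # or from_csv / from_arrays
>>> res = test.fit()
>>> print(res.summary())
>>> res.frame()            # tidy coefficient DataFrame
>>> res.to_csv("coeffs.csv")

`CompressionTest` holds the data and configuration; `fit()` segments the
stress trace into loading/unloading half-cycles and fits the logistic
stress and quadratic stretch models to each, returning a
`CompressionTestResults` that carries the per-cycle fits, midpoint
tangents, stretch-domain transformations and the measurement error budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import NonLinearStretchError, DegenerateStretchError, StressFitError
from .fitting import CycleFitResult, FitMode, fit_cycle
from .io import CoefficientTableRow, read_trace_csv, write_coefficient_table
from .mechanics import LoadTestRecord, SpecimenGeometry, StressStretchTrace, to_stress_stretch
from .models import DEFAULT_D2_TOLERANCE, LogisticStressModel, compose_stress_stretch
from .segmentation import segment_cycles
from .uncertainty import ErrorBudget, propagate_stress_error, propagate_stretch_error

__all__ = ["CompressionTest", "CompressionTestResults"]

#: Rated machine precisions used as default instrument uncertainties:
#: force to within +-0.1% of reading, displacement to within +-0.01 mm.
DEFAULT_FORCE_PRECISION_REL = 1e-3
DEFAULT_DISPLACEMENT_PRECISION_MM = 0.01


class CompressionTest:
    """A compression test ready to fit.

    Parameters
    ----------
    trace : derived stress/stretch series (use the class methods to start
        from a raw record, CSV file, or bare arrays).
    mode : "time" fits both models against segment-local time (cyclic
        experiments); "stretch" fits stress with stretch as the independent
        variable and skips the quadratic model (load-to-fracture style,
        valid under constant crosshead velocity).
    min_prominence, min_separation : segmentation thresholds; defaults are
        5% of the stress range and 1% of the trace length.
    exclude_first_cycle : drop cycle 1 (adjustment transients) before fitting.
    d2_tolerance : |D2| bound for the stretch-domain transformation.
    seed : seeds jittered optimizer restarts (used only on failure).
    """

    def __init__(
        self,
        trace: StressStretchTrace,
        mode: FitMode = "time",
        min_prominence: float | None = None,
        min_separation: int | None = None,
        exclude_first_cycle: bool = False,
        d2_tolerance: float = DEFAULT_D2_TOLERANCE,
        seed: int = 0,
    ):
        self.trace = trace
        self.mode: FitMode = mode
        self.min_prominence = min_prominence
        self.min_separation = min_separation
        self.exclude_first_cycle = exclude_first_cycle
        self.d2_tolerance = d2_tolerance
        self.seed = seed

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_record(cls, record: LoadTestRecord, **kwargs) -> "CompressionTest":
        return cls(to_stress_stretch(record), **kwargs)

    @classmethod
    def from_csv(
        cls,
        path,
        geometry: SpecimenGeometry | None = None,
        geometry_path=None,
        specimen_id: str = "",
        experiment_id: str = "",
        **kwargs,
    ) -> "CompressionTest":
        record = read_trace_csv(
            path,
            geometry=geometry,
            geometry_path=geometry_path,
            specimen_id=specimen_id,
            experiment_id=experiment_id,
        )
        return cls.from_record(record, **kwargs)

    @classmethod
    def from_arrays(
        cls,
        time_s,
        force_n,
        displacement_mm,
        length_mm: float,
        surface_mm2: float,
        **kwargs,
    ) -> "CompressionTest":
        record = LoadTestRecord(
            time_s=np.asarray(time_s, float),
            force_n=np.asarray(force_n, float),
            displacement_mm=np.asarray(displacement_mm, float),
            geometry=SpecimenGeometry(length_mm=length_mm, surface_mm2=surface_mm2),
        )
        return cls.from_record(record, **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "CompressionTestResults":
        """Segment the trace and fit every half-cycle."""
        segments = segment_cycles(
            self.trace,
            min_prominence=self.min_prominence,
            min_separation=self.min_separation,
            exclude_first_cycle=self.exclude_first_cycle,
        )
        cycle_fits = [fit_cycle(seg, mode=self.mode, seed=self.seed) for seg in segments]
        return CompressionTestResults(self, cycle_fits)


@dataclass
class CompressionTestResults:
    """Fitted per-cycle models, goodness of fit and derived quantities."""

    test: CompressionTest
    cycle_fits: list[CycleFitResult]

    # -- tabular views ------------------------------------------------------

    def _ids(self) -> tuple[str, str]:
        src = self.test.trace.source
        return (src.specimen_id, src.experiment_id) if src is not None else ("", "")

    def coefficient_rows(self) -> list[CoefficientTableRow]:
        """Flat rows (stress + stretch per half-cycle) for the table writer."""
        specimen, experiment = self._ids()
        rows: list[CoefficientTableRow] = []
        for cf in self.cycle_fits:
            seg = cf.stress.segment
            rows.append(
                CoefficientTableRow(
                    specimen_id=specimen,
                    experiment_id=experiment,
                    cycle_index=seg.cycle_index,
                    record_type="stress",
                    direction=seg.direction,
                    coefficients=(
                        cf.stress.model.c0,
                        cf.stress.model.c1,
                        cf.stress.model.c2,
                        cf.stress.model.c3,
                    ),
                    r_squared=cf.stress.r_squared,
                    fit_mode=cf.stress.mode,
                    time_origin_s=cf.time_origin_s,
                )
            )
            if cf.stretch is not None:
                rows.append(
                    CoefficientTableRow(
                        specimen_id=specimen,
                        experiment_id=experiment,
                        cycle_index=seg.cycle_index,
                        record_type="stretch",
                        direction=cf.stretch.direction_label,
                        coefficients=(
                            cf.stretch.model.d2,
                            cf.stretch.model.d1,
                            cf.stretch.model.d0,
                        ),
                        r_squared=cf.stretch.r_squared,
                        fit_mode="time",
                        time_origin_s=cf.time_origin_s,
                    )
                )
        return rows

    def frame(self) -> pd.DataFrame:
        """Coefficient table as a tidy DataFrame."""
        rows = self.coefficient_rows()
        records = []
        for r in rows:
            rec = {
                "specimen": r.specimen_id,
                "experiment": r.experiment_id,
                "cycle": r.cycle_index,
                "type": r.record_type,
                "direction": r.direction,
                "r_squared": r.r_squared,
                "mode": r.fit_mode,
                "time_origin_s": r.time_origin_s,
            }
            names = ("c0", "c1", "c2", "c3") if r.record_type == "stress" else ("d2", "d1", "d0")
            rec.update(dict(zip(names, r.coefficients)))
            records.append(rec)
        return pd.DataFrame(records)

    def to_csv(self, path) -> None:
        write_coefficient_table(self.coefficient_rows(), path)

    # -- derived quantities --------------------------------------------------

    def tangents(self) -> pd.DataFrame:
        """Midpoint tangent slope C1*C2/4 of every stress fit."""
        recs = [
            {
                "cycle": cf.stress.segment.cycle_index,
                "direction": cf.stress.segment.direction,
                "tangent": cf.stress.model.midpoint_slope,
            }
            for cf in self.cycle_fits
        ]
        return pd.DataFrame(recs)

    def stretch_domain_models(self) -> dict[tuple[int, str], LogisticStressModel | None]:
        """Stress-vs-stretch logistic per half-cycle, where stretch is linear.

        Cycles whose |D2| exceeds the tolerance (curved stretch-time
        relation) or whose stretch is constant map to ``None``.
        """
        out: dict[tuple[int, str], LogisticStressModel | None] = {}
        from .models import to_stretch_domain

        for cf in self.cycle_fits:
            key = (cf.stress.segment.cycle_index, cf.stress.segment.direction)
            if cf.pair is None:
                out[key] = cf.stress.model if cf.stress.mode == "stretch" else None
                continue
            try:
                out[key] = to_stretch_domain(cf.pair, self.test.d2_tolerance)
            except (NonLinearStretchError, DegenerateStretchError):
                out[key] = None
        return out

    def error_budget(
        self,
        delta_force_n: float | None = None,
        delta_displacement_mm: float = DEFAULT_DISPLACEMENT_PRECISION_MM,
    ) -> ErrorBudget | None:
        """Propagated measurement uncertainty at peak load.

        Defaults assume the rated machine precisions (force +-0.1% of the
        peak reading, displacement +-0.01 mm) and the geometry's recorded
        surface uncertainty (0 if absent).  Returns ``None`` when the trace
        has no source record (no geometry to propagate through).
        """
        src = self.test.trace.source
        if src is None:
            return None
        geom = src.geometry
        peak_force = float(np.max(np.abs(src.force_n)))
        if peak_force == 0:
            raise StressFitError("zero peak force: relative stress error undefined")
        if delta_force_n is None:
            delta_force_n = DEFAULT_FORCE_PRECISION_REL * peak_force
        delta_s = geom.delta_surface_mm2 or 0.0
        return ErrorBudget(
            delta_force_n=delta_force_n,
            delta_surface_mm2=delta_s,
            delta_displacement_mm=delta_displacement_mm,
            relative_stress_error=propagate_stress_error(
                peak_force, delta_force_n, geom.surface_mm2, delta_s
            ),
            delta_stretch=propagate_stretch_error(delta_displacement_mm, geom.length_mm),
        )

    def fitted_curves(self, points_per_segment: int = 200) -> list[np.ndarray]:
        """Composed (stretch, stress) fitted curve per half-cycle (time mode)."""
        curves = []
        for cf in self.cycle_fits:
            if cf.pair is None:
                continue
            seg = cf.stress.segment
            t_local = np.linspace(0.0, float(seg.time_s[-1] - seg.time_s[0]), points_per_segment)
            curves.append(compose_stress_stretch(cf.pair, t_local))
        return curves

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit report."""
        specimen, experiment = self._ids()
        lines = []
        lines.append("Compression test fit" + (f" — specimen {specimen}" if specimen else ""))
        if experiment:
            lines.append(f"Experiment: {experiment}")
        lines.append(
            f"Mode: {self.test.mode}-domain logistic stress"
            + ("" if self.test.mode == "stretch" else " + quadratic stretch")
        )
        lines.append(f"Samples: {len(self.test.trace)}   Half-cycles fitted: {len(self.cycle_fits)}")
        lines.append("")
        hdr = (
            f"{'cyc':>3} {'dir':<6} {'C0':>10} {'C1':>10} {'C2':>10} {'C3':>10}"
            f" {'R2':>9} {'tan(a)':>9}"
        )
        lines.append(hdr)
        lines.append("-" * len(hdr))
        for cf in self.cycle_fits:
            m = cf.stress.model
            seg = cf.stress.segment
            lines.append(
                f"{seg.cycle_index:>3} {seg.direction:<6} {m.c0:>10.4g} {m.c1:>10.4g}"
                f" {m.c2:>10.4g} {m.c3:>10.4g} {cf.stress.r_squared:>9.5f}"
                f" {m.midpoint_slope:>9.4g}"
            )
        stretch_fits = [cf for cf in self.cycle_fits if cf.stretch is not None]
        if stretch_fits:
            lines.append("")
            hdr2 = f"{'cyc':>3} {'dir':<6} {'D2':>10} {'D1':>10} {'D0':>10} {'R2':>9}"
            lines.append(hdr2)
            lines.append("-" * len(hdr2))
            for cf in stretch_fits:
                q = cf.stretch.model
                lines.append(
                    f"{cf.stretch.segment.cycle_index:>3} {cf.stretch.direction_label:<6}"
                    f" {q.d2:>10.4g} {q.d1:>10.4g} {q.d0:>10.4g} {cf.stretch.r_squared:>9.5f}"
                )
        budget = self.error_budget() if self.test.trace.source is not None else None
        if budget is not None:
            lines.append("")
            lines.append(
                "Error budget: relative stress error "
                f"{budget.relative_stress_error:.4g} "
                f"(dF = {budget.delta_force_n:.4g} N, dS = {budget.delta_surface_mm2:.4g} mm^2); "
                f"stretch error {budget.delta_stretch:.4g} "
                f"(dl = {budget.delta_displacement_mm:.4g} mm)"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed stress-stretch curve with fitted per-cycle curves overlaid.

        Requires matplotlib (optional dependency).
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        tr = self.test.trace
        ax.plot(tr.stretch, tr.stress_mpa, color="0.6", lw=0.8, label="observed")
        for i, curve in enumerate(self.fitted_curves()):
            ax.plot(curve[:, 0], curve[:, 1], lw=1.2, label="fitted" if i == 0 else None)
        ax.set_xlabel("stretch λ")
        ax.set_ylabel("stress σ (MPa)")
        ax.invert_xaxis()  # compression: stretch decreases left of 1
        ax.legend(loc="best")
        return ax
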