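"""Synthetic compression-test generators.

These build force-displacement records with the statistical structure the
analysis assumes — cyclic hysteresis tests and monotone load-to-fracture
ramps — from known stress/stretch model pairs, by inverting the mechanics
relations (force = sigma * S, displacement = L * (1 - lambda)) and adding
independent additive Gaussian noise.  Every pipeline stage is therefore
testable without any experimental download, and full-pipeline runs can be
checked against the exact generating coefficients.

Each generated :class:`~stressfit.mechanics.LoadTestRecord` carries the
resolved per-segment ground truth (the model pairs actually evaluated,
after continuity adjustment) in ``record.ground_truth``.

Default conditions
------------------
The default cyclic specification reproduces the published first-cycle
loading stress coefficients for vertebra L3 in the cyclic experiment,
repeated for ten compression-relaxation cycles.  The published per-segment
coefficient rows carry no common time base, so the unloading stress model
is the time-mirror of the loading one (the composite trace is then
continuous and the loops close with no baseline drift), and the stretch
models span lambda 1.0 -> 0.85 per half-cycle — linear compression down,
quadratic recovery up — matching the excursion of the published hysteresis
loops and giving the loop a genuine enclosed area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import reference
from .exceptions import InconsistentSpecError, InvalidArgumentError
from .mechanics import LoadTestRecord, SpecimenGeometry
from .models import LogisticStressModel, ParametricCyclePair, QuadraticStretchModel

__all__ = [
    "CyclicTestSpec",
    "FractureTestSpec",
    "default_cyclic_spec",
    "default_fracture_spec",
    "generate_cyclic",
    "generate_fracture",
]

#: Default specimen geometry: canine lumbar vertebra scale, with the
#: instrument-grade measurement uncertainties used in the error budget.
DEFAULT_GEOMETRY = SpecimenGeometry(
    length_mm=20.0, surface_mm2=100.0, delta_length_mm=0.01, delta_surface_mm2=1.0
)

#: Default stretch excursion per half-cycle (lambda from 1.0 down to 0.85).
_DEFAULT_STRETCH_DROP = 0.15


@dataclass(frozen=True)
class CyclicTestSpec:
    """Ground truth and sampling regime for a cyclic hysteresis test.

    ``load_pairs`` / ``unload_pairs`` hold one model pair per cycle (a
    single pair is recycled for every cycle).  All pairs are expressed on a
    forward segment-local clock spanning ``[0, cycle_duration_s / 2]``.
    """

    n_cycles: int = 10
    load_pairs: Sequence[ParametricCyclePair] = ()
    unload_pairs: Sequence[ParametricCyclePair] = ()
    cycle_duration_s: float = 12.9568
    sample_rate_hz: float = 50.0
    noise_sd_stress_mpa: float = 0.0
    noise_sd_displacement_mm: float = 0.0
    seed: int = 0
    geometry: SpecimenGeometry = DEFAULT_GEOMETRY
    max_junction_offset: float | None = None
    specimen_id: str = "SYN"
    experiment_id: str = "cyclic"

    def __post_init__(self):
        if self.n_cycles < 1:
            raise InvalidArgumentError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.cycle_duration_s <= 0 or self.sample_rate_hz <= 0:
            raise InvalidArgumentError("cycle_duration_s and sample_rate_hz must be positive")
        if self.noise_sd_stress_mpa < 0 or self.noise_sd_displacement_mm < 0:
            raise InvalidArgumentError("noise standard deviations must be >= 0")
        if not self.load_pairs or not self.unload_pairs:
            raise InvalidArgumentError("load_pairs and unload_pairs must be non-empty")


@dataclass(frozen=True)
class FractureTestSpec:
    """Ground truth and sampling regime for a monotone load-to-fracture test."""

    pair: ParametricCyclePair = field(
        default_factory=lambda: _default_fracture_pair()
    )
    duration_s: float | None = None
    post_peak_drop: float = 0.25
    drop_samples: int = 3
    sample_rate_hz: float = 200.0
    noise_sd_stress_mpa: float = 0.0
    noise_sd_displacement_mm: float = 0.0
    seed: int = 0
    geometry: SpecimenGeometry = DEFAULT_GEOMETRY
    specimen_id: str = "SYN"
    experiment_id: str = "fracture"

    def __post_init__(self):
        if not 0 <= self.post_peak_drop < 1:
            raise InvalidArgumentError("post_peak_drop must be in [0, 1)")
        if self.duration_s is not None and self.duration_s <= 0:
            raise InvalidArgumentError("duration_s must be positive")
        if self.sample_rate_hz <= 0:
            raise InvalidArgumentError("sample_rate_hz must be positive")
        if self.pair.stress.c2 <= 0:
            raise InvalidArgumentError("fracture ground truth must be a rising logistic (C2 > 0)")

    def resolved_duration(self) -> float:
        """Time to run the ramp: out to 12/C2 past the midpoint (within
        2e-4 of the upper asymptote) unless set explicitly."""
        if self.duration_s is not None:
            return self.duration_s
        return self.pair.stress.c3 + 12.0 / self.pair.stress.c2


def _default_fracture_pair() -> ParametricCyclePair:
    stress = reference.stress_model("L5", 3, "load")
    duration = stress.c3 + 12.0 / stress.c2
    stretch = QuadraticStretchModel(d2=0.0, d1=-0.2 / duration, d0=1.0)
    return ParametricCyclePair(stress=stress, stretch=stretch, cycle_index=1, direction="load")


def default_cyclic_spec(
    n_cycles: int = 10,
    noise_sd_stress_mpa: float = 0.0,
    noise_sd_displacement_mm: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 50.0,
    geometry: SpecimenGeometry = DEFAULT_GEOMETRY,
) -> CyclicTestSpec:
    """Cyclic spec built on the published L3 cyclic-experiment loading stress row.

    The loading half-cycle spans [0, ~2*C3] so the sigmoid midpoint sits
    near its centre; unloading mirrors it in time.  Stretch: linear
    compression to lambda = 0.85, quadratic recovery back to 1.0.  The
    half-cycle duration is snapped to the sample grid so segment junctions
    land exactly on samples and segment-local clocks match the generating
    ones.
    """
    load_stress = reference.stress_model("L3", 1, "load")
    half = round(2.0 * load_stress.c3 * sample_rate_hz) / sample_rate_hz
    unload_stress = LogisticStressModel(
        c0=load_stress.c0, c1=load_stress.c1, c2=-load_stress.c2, c3=half - load_stress.c3
    )
    drop = _DEFAULT_STRETCH_DROP
    load_stretch = QuadraticStretchModel(d2=0.0, d1=-drop / half, d0=1.0)
    # recovery: slow start, quadratic catch-up back to lambda = 1 at the
    # cycle end — a different path than loading, so the loop has area
    unload_stretch = QuadraticStretchModel(
        d2=0.75 * drop / half**2, d1=0.25 * drop / half, d0=1.0 - drop
    )
    return CyclicTestSpec(
        n_cycles=n_cycles,
        load_pairs=(ParametricCyclePair(load_stress, load_stretch, 1, "load"),),
        unload_pairs=(ParametricCyclePair(unload_stress, unload_stretch, 1, "unload"),),
        cycle_duration_s=2.0 * half,
        sample_rate_hz=sample_rate_hz,
        noise_sd_stress_mpa=noise_sd_stress_mpa,
        noise_sd_displacement_mm=noise_sd_displacement_mm,
        seed=seed,
        geometry=geometry,
    )


def default_fracture_spec(seed: int = 0, **kwargs) -> FractureTestSpec:
    """Fracture spec built on the published L5 load-to-fracture stress row."""
    return FractureTestSpec(seed=seed, **kwargs)


def _pair_for(pairs: Sequence[ParametricCyclePair], k: int) -> ParametricCyclePair:
    return pairs[0] if len(pairs) == 1 else pairs[k]


def _record_from_series(spec, t, stress, stretch, rng, ground_truth) -> LoadTestRecord:
    """Invert the mechanics relations and add measurement noise."""
    geom = spec.geometry
    if spec.noise_sd_stress_mpa > 0:
        stress = stress + rng.normal(0.0, spec.noise_sd_stress_mpa, size=stress.size)
    force = stress * geom.surface_mm2
    displacement = geom.length_mm * (1.0 - stretch)
    if spec.noise_sd_displacement_mm > 0:
        displacement = displacement + rng.normal(
            0.0, spec.noise_sd_displacement_mm, size=displacement.size
        )
    return LoadTestRecord(
        time_s=t,
        force_n=force,
        displacement_mm=displacement,
        geometry=geom,
        specimen_id=spec.specimen_id,
        experiment_id=spec.experiment_id,
        ground_truth=tuple(ground_truth),
    )


def generate_cyclic(spec: CyclicTestSpec) -> LoadTestRecord:
    """Generate a cyclic hysteresis record from per-half-cycle model pairs.

    Per cycle k the stress follows the loading pair's logistic over the
    first half-cycle and the unloading pair's over the second, each on its
    local clock.  Consecutive segments are joined continuously by an
    additive offset (C0/D0 shift) matching each segment's start to the
    previous segment's end; the offset-adjusted pairs are returned as
    ``record.ground_truth`` in segment order.  If ``max_junction_offset``
    is set, a junction needing a larger shift raises
    :class:`InconsistentSpecError`.
    """
    if len(spec.load_pairs) not in (1, spec.n_cycles) or len(spec.unload_pairs) not in (1, spec.n_cycles):
        raise InvalidArgumentError("pair sequences must have length 1 or n_cycles")

    half = spec.cycle_duration_s / 2.0
    dt = 1.0 / spec.sample_rate_hz
    n_samples = int(round(spec.n_cycles * spec.cycle_duration_s * spec.sample_rate_hz))
    t = np.arange(n_samples) * dt

    stress = np.empty(n_samples)
    stretch = np.empty(n_samples)
    resolved: list[ParametricCyclePair] = []
    prev_stress_end: float | None = None
    prev_stretch_end: float | None = None

    for s in range(2 * spec.n_cycles):
        k = s // 2
        direction = "load" if s % 2 == 0 else "unload"
        base = _pair_for(spec.load_pairs if direction == "load" else spec.unload_pairs, k)
        t_start = s * half
        mask = (t >= t_start) & (t < t_start + half) if s < 2 * spec.n_cycles - 1 else (t >= t_start)
        tau = t[mask] - t_start

        stress_model, stretch_model = base.stress, base.stretch
        if prev_stress_end is not None:
            off_sigma = prev_stress_end - stress_model.predict(0.0)
            off_lambda = prev_stretch_end - stretch_model.predict(0.0)
            if spec.max_junction_offset is not None and (
                abs(off_sigma) > spec.max_junction_offset
                or abs(off_lambda) > spec.max_junction_offset
            ):
                raise InconsistentSpecError(
                    f"segment {s} needs junction offset (stress {off_sigma:g}, "
                    f"stretch {off_lambda:g}) above max_junction_offset "
                    f"{spec.max_junction_offset:g}"
                )
            stress_model = replace(stress_model, c0=stress_model.c0 + off_sigma)
            stretch_model = replace(stretch_model, d0=stretch_model.d0 + off_lambda)

        stress[mask] = stress_model.predict(tau)
        stretch[mask] = stretch_model.predict(tau)
        prev_stress_end = stress_model.predict(half)
        prev_stretch_end = stretch_model.predict(half)
        resolved.append(
            ParametricCyclePair(stress_model, stretch_model, k + 1, direction)  # type: ignore[arg-type]
        )

    rng = np.random.default_rng(spec.seed)
    return _record_from_series(spec, t, stress, stretch, rng, resolved)


def generate_fracture(spec: FractureTestSpec) -> LoadTestRecord:
    """Generate a monotone ramp-to-fracture record.

    The noiseless stress rises along the logistic to (near) its upper
    asymptote C0 + C1; with ``post_peak_drop > 0`` an abrupt drop of that
    fraction of the peak stress is appended over ``drop_samples`` samples
    as the fracture marker.
    """
    duration = spec.resolved_duration()
    dt = 1.0 / spec.sample_rate_hz
    n_ramp = max(2, int(round(duration * spec.sample_rate_hz)) + 1)
    t_ramp = np.arange(n_ramp) * dt
    stress = spec.pair.stress.predict(t_ramp)
    stretch = spec.pair.stretch.predict(t_ramp)

    if spec.post_peak_drop > 0 and spec.drop_samples > 0:
        peak = stress[-1]
        t_drop = t_ramp[-1] + dt * np.arange(1, spec.drop_samples + 1)
        frac = np.arange(1, spec.drop_samples + 1) / spec.drop_samples
        stress_drop = peak - frac * spec.post_peak_drop * peak
        # stretch keeps creeping down at the terminal rate during the drop
        rate = (stretch[-1] - stretch[-2]) / dt if n_ramp > 1 else 0.0
        stretch_drop = stretch[-1] + rate * (t_drop - t_ramp[-1])
        t = np.concatenate([t_ramp, t_drop])
        stress = np.concatenate([stress, stress_drop])
        stretch = np.concatenate([stretch, stretch_drop])
    else:
        t = t_ramp

    rng = np.random.default_rng(spec.seed)
    return _record_from_series(spec, t, stress, stretch, rng, [spec.pair])
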