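"""Hysteresis-cycle segmentation of stress traces.

Cyclic compression produces a stress signal that rises to a peak and falls
back once per compression-relaxation cycle.  This module finds the stress
extrema (prominence-based peak picking) and cuts the trace into
loading (valley -> peak) and unloading (peak -> valley) half-cycles, which
downstream fitting treats independently.

The first and last samples are eligible as boundary extrema so that the
initial loading ramp — and, for fracture tests, the single monotone ramp —
is captured.  A trailing incomplete half-cycle is kept as a load-only
segment: a ramp-to-fracture record yields exactly one loading segment and
no unloading segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .exceptions import InvalidArgumentError, NoCyclesError
from .mechanics import StressStretchTrace
from .models import Direction

__all__ = ["CycleSegment", "find_extrema", "segment_cycles"]

logger = logging.getLogger(__name__)

#: Default minimum peak prominence, as a fraction of the trace's stress range.
DEFAULT_PROMINENCE_FRACTION = 0.05
#: Default minimum extremum separation, as a fraction of the trace length.
DEFAULT_SEPARATION_FRACTION = 0.01

_PEAK, _VALLEY = 1, -1


@dataclass(frozen=True)
class CycleSegment:
    """One loading or unloading half-cycle extracted from a trace.

    Index range is inclusive on both ends; the shared peak sample belongs to
    both the loading segment that ends there and the unloading segment that
    starts there, so both fits anchor the turning point.
    """

    cycle_index: int
    direction: Direction
    start_index: int
    end_index: int
    time_s: np.ndarray
    stress_mpa: np.ndarray
    stretch: np.ndarray

    def __post_init__(self):
        if self.start_index >= self.end_index:
            raise InvalidArgumentError("segment must span at least two samples")
        if not (len(self.time_s) == len(self.stress_mpa) == len(self.stretch)):
            raise InvalidArgumentError("segment sub-series lengths differ")

    def __len__(self) -> int:
        return len(self.time_s)


def _resolve_params(n: int, stress_range: float, min_prominence, min_separation):
    prom = (
        DEFAULT_PROMINENCE_FRACTION * stress_range
        if min_prominence is None
        else float(min_prominence)
    )
    dist = (
        max(1, int(round(DEFAULT_SEPARATION_FRACTION * n)))
        if min_separation is None
        else max(1, int(min_separation))
    )
    return prom, dist


def _plateau_start(s: np.ndarray, i: int) -> int:
    while i > 0 and s[i - 1] == s[i]:
        i -= 1
    return i


def _collapse_alternating(events: list[tuple[int, int]], s: np.ndarray) -> list[tuple[int, int]]:
    """Enforce strict peak/valley interleaving; within a same-kind run keep the
    most extreme sample (first on ties)."""
    out: list[tuple[int, int]] = []
    for idx, kind in events:
        if out and out[-1][1] == kind:
            prev_idx = out[-1][0]
            better = s[idx] > s[prev_idx] if kind == _PEAK else s[idx] < s[prev_idx]
            if better:
                out[-1] = (idx, kind)
        else:
            out.append((idx, kind))
    return out


def find_extrema(stress, min_prominence=None, min_separation=None):
    """Locate stress minima and maxima delimiting half-cycles.

    Parameters
    ----------
    stress : 1-D stress series (any array-like), length >= 3.
    min_prominence : minimum peak prominence in stress units
        (default: 5% of the series range).
    min_separation : minimum sample count between same-kind extrema
        (default: 1% of the series length, at least 1).

    Returns
    -------
    (minima, maxima) : two int arrays of sample indices whose union strictly
    interleaves valley/peak/valley/...  Boundary samples are included when
    the head (or a sufficiently long tail) of the series forms a half-cycle
    of at least the requested prominence.
    """
    s = np.asarray(stress, dtype=float)
    if s.ndim != 1 or s.size < 3:
        raise InvalidArgumentError("stress series must be 1-D with at least 3 samples")
    if not np.all(np.isfinite(s)):
        raise InvalidArgumentError("stress series contains non-finite values")

    stress_range = float(np.ptp(s))
    prom, dist = _resolve_params(s.size, stress_range, min_prominence, min_separation)
    if stress_range == 0.0:
        return np.array([], dtype=int), np.array([], dtype=int)

    maxima, _ = find_peaks(s, prominence=prom if prom > 0 else None, distance=dist)
    minima, _ = find_peaks(-s, prominence=prom if prom > 0 else None, distance=dist)
    # flat extrema: deterministically take the first sample of the plateau
    maxima = np.array([_plateau_start(s, int(i)) for i in maxima], dtype=int)
    minima = np.array([_plateau_start(s, int(i)) for i in minima], dtype=int)
    events = sorted(
        [(int(i), _PEAK) for i in maxima] + [(int(i), _VALLEY) for i in minima]
    )
    events = _collapse_alternating(events, s)

    if not events:
        # Monotone (or sub-prominence wiggly) series: boundary extrema only.
        if s[-1] - s[0] >= prom:
            events = [(int(np.argmin(s)), _VALLEY), (int(np.argmax(s)), _PEAK)]
        elif s[0] - s[-1] >= prom:
            events = [(int(np.argmax(s)), _PEAK), (int(np.argmin(s)), _VALLEY)]
        else:
            return np.array([], dtype=int), np.array([], dtype=int)
        events.sort()
    else:
        i0, k0 = events[0]
        j = int(np.argmin(s[: i0 + 1])) if k0 == _PEAK else int(np.argmax(s[: i0 + 1]))
        if j < i0 and abs(s[i0] - s[j]) >= prom:
            events.insert(0, (j, -k0))
        i_last, k_last = events[-1]
        tail = s[i_last:]
        j = i_last + (int(np.argmin(tail)) if k_last == _PEAK else int(np.argmax(tail)))
        # A trailing boundary extremum needs a tail at least min_separation
        # long; an abrupt post-fracture drop is deliberately not an extremum.
        if j > i_last and abs(s[j] - s[i_last]) >= prom and (s.size - 1 - i_last) >= dist:
            events.append((j, -k_last))
        events = _collapse_alternating(events, s)

    minima_out = np.array([i for i, k in events if k == _VALLEY], dtype=int)
    maxima_out = np.array([i for i, k in events if k == _PEAK], dtype=int)
    return minima_out, maxima_out


def segment_cycles(
    trace: StressStretchTrace,
    min_prominence=None,
    min_separation=None,
    exclude_first_cycle: bool = False,
) -> list[CycleSegment]:
    """Split a trace into per-cycle loading/unloading segments.

    Cycles are numbered k = 1.. in time order; each loading segment runs
    valley -> peak and each unloading segment peak -> valley, sharing the
    peak sample.  ``exclude_first_cycle`` drops cycle 1 (adjustment
    transients) and renumbers; it is off by default, matching the practice
    of fitting every cycle including the first.

    Raises :class:`NoCyclesError` if no peak is found.
    """
    minima, maxima = find_extrema(trace.stress_mpa, min_prominence, min_separation)
    if maxima.size == 0:
        raise NoCyclesError(
            f"no stress peaks detected ({len(trace)} samples, "
            f"stress range {float(np.ptp(trace.stress_mpa)):g} MPa)"
        )
    events = sorted(
        [(int(i), _PEAK) for i in maxima] + [(int(i), _VALLEY) for i in minima]
    )

    segments: list[CycleSegment] = []
    k = 0
    for (i0, k0), (i1, _k1) in zip(events, events[1:]):
        if k0 == _VALLEY:
            k += 1
            direction: Direction = "load"
        else:
            if k == 0:  # trace starts at a peak: count the opening unload as cycle 1
                k = 1
            direction = "unload"
        sl = slice(i0, i1 + 1)
        segments.append(
            CycleSegment(
                cycle_index=k,
                direction=direction,
                start_index=i0,
                end_index=i1,
                time_s=trace.time_s[sl].copy(),
                stress_mpa=trace.stress_mpa[sl].copy(),
                stretch=trace.stretch[sl].copy(),
            )
        )
        logger.info(
            "segment cycle=%d %s samples [%d, %d] t=[%.4g, %.4g] s",
            k, direction, i0, i1, trace.time_s[i0], trace.time_s[i1],
        )

    if exclude_first_cycle:
        segments = [
            CycleSegment(
                cycle_index=s.cycle_index - 1,
                direction=s.direction,
                start_index=s.start_index,
                end_index=s.end_index,
                time_s=s.time_s,
                stress_mpa=s.stress_mpa,
                stretch=s.stretch,
            )
            for s in segments
            if s.cycle_index > 1
        ]
        if not segments:
            raise NoCyclesError("no cycles remain after excluding the first cycle")
    return segments
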