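"""Published reference coefficients for canine lumbar vertebra compression tests.

The packaged table carries the published first-cycle fit coefficients for
vertebrae L3-L5 across three experiment types: two cyclic compression
experiments (experiments 1 and 2, fitted against segment-local time) and
one load-to-fracture experiment (experiment 3, fitted with stretch as the
independent variable; it has no unloading row).  Stress rows hold the
logistic coefficients C0..C3, stretch rows the quadratic coefficients
D2, D1, D0, each with the published R².

Stress values are treated as MPa and times as seconds throughout (the
source tables do not name units; this assumption is documented in the
package methods note).

These rows serve as ground truth for the synthetic generators and as the
coefficient sets the recovery tests must reproduce.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .exceptions import InvalidArgumentError
from .models import LogisticStressModel, ParametricCyclePair, QuadraticStretchModel

__all__ = [
    "load_reference_coefficients",
    "stress_rows",
    "stretch_rows",
    "stress_model",
    "stretch_model",
    "reference_pair",
]

#: Map between stress-row direction labels and stretch-row direction labels.
#: A loading half-cycle compresses the specimen, so its stretch goes "down".
_STRETCH_DIRECTION = {"load": "down", "unload": "up"}


@lru_cache(maxsize=1)
def _table() -> pd.DataFrame:
    with resources.files(__package__).joinpath("data/reference_coefficients.csv").open("r") as fh:
        return pd.read_csv(fh)


def load_reference_coefficients() -> pd.DataFrame:
    """Full reference coefficient table (copy) with both stress and stretch rows."""
    return _table().copy()


def stress_rows() -> pd.DataFrame:
    """Logistic stress coefficient rows (columns c0..c3, r_squared)."""
    df = _table()
    return df[df["kind"] == "stress"].reset_index(drop=True).copy()


def stretch_rows() -> pd.DataFrame:
    """Quadratic stretch coefficient rows (columns d2, d1, d0, r_squared)."""
    df = _table()
    return df[df["kind"] == "stretch"].reset_index(drop=True).copy()


def _select(kind: str, vertebra: str, experiment: int, direction: str) -> pd.Series:
    df = _table()
    hit = df[
        (df["kind"] == kind)
        & (df["vertebra"] == vertebra)
        & (df["experiment"] == experiment)
        & (df["direction"] == direction)
    ]
    if len(hit) != 1:
        raise InvalidArgumentError(
            f"no unique reference row for kind={kind}, vertebra={vertebra}, "
            f"experiment={experiment}, direction={direction}"
        )
    return hit.iloc[0]


def stress_model(vertebra: str, experiment: int, direction: str = "load") -> LogisticStressModel:
    """Published logistic stress model for one vertebra/experiment/direction."""
    row = _select("stress", vertebra, experiment, direction)
    return LogisticStressModel(row["c0"], row["c1"], row["c2"], row["c3"])


def stretch_model(vertebra: str, experiment: int, direction: str = "down") -> QuadraticStretchModel:
    """Published quadratic stretch model for one vertebra/experiment/direction."""
    row = _select("stretch", vertebra, experiment, direction)
    return QuadraticStretchModel(row["d2"], row["d1"], row["d0"])


def reference_pair(
    vertebra: str, experiment: int, direction: str = "load", cycle_index: int = 1
) -> ParametricCyclePair:
    """Published stress/stretch model pair for one half-cycle.

    Pairs the stress row with the stretch row of matching sense
    (load <-> down, unload <-> up).  Only experiments 1 and 2 have stretch
    rows; experiment 3 was fitted in the stretch domain and has none.
    """
    return ParametricCyclePair(
        stress=stress_model(vertebra, experiment, direction),
        stretch=stretch_model(vertebra, experiment, _STRETCH_DIRECTION[direction]),
        cycle_index=cycle_index,
        direction=direction,  # type: ignore[arg-type]
    )
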