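import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stressfit as sf
from stressfit import reference
from stressfit.fitting import fit_logistic_stress, fit_quadratic_stretch
from stressfit.models import LogisticStressModel, QuadraticStretchModel

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Noise level used throughout the noisy-synthetic tests: 0.5% of the
#: reference loading amplitude C1 = 7.163 MPa.
NOISE_SD_STRESS = 0.005 * 7.163


# ---------------------------------------------------------------------------
# shared helpers (imported by test modules via `from conftest import ...`)


def rel_err(estimate: float, truth: float) -> float:
    """Relative error, falling back to absolute when the truth is zero."""
    return abs(estimate - truth) / abs(truth) if truth != 0 else abs(estimate - truth)


def recovery_grid(c3: float, n_points: int = 400) -> np.ndarray:
    """Sampling grid spanning twice the sigmoid midpoint (symmetric coverage)."""
    return np.linspace(0.0, 2.0 * c3, n_points)


def recover_stress_row(row, n_points: int = 400):
    """Generate noiseless logistic data from one reference row and refit it."""
    truth = LogisticStressModel(row["c0"], row["c1"], row["c2"], row["c3"])
    t = recovery_grid(float(row["c3"]), n_points)
    fit = fit_logistic_stress(t, truth.predict(t))
    return truth, fit


def recover_stretch_row(row, n_points: int = 50):
    """Generate noiseless quadratic data from one reference row and refit it."""
    truth = QuadraticStretchModel(row["d2"], row["d1"], row["d0"])
    t = np.linspace(0.0, 1.0, n_points)
    fit = fit_quadratic_stretch(t, truth.predict(t))
    return truth, fit


def brute_force_r_squared(observed, predicted) -> float:
    """Direct elementwise evaluation of 1 - SSres/SStot, loop form."""
    y = list(map(float, observed))
    yhat = list(map(float, predicted))
    ybar = sum(y) / len(y)
    ss_res = sum((yi - yhi) ** 2 for yi, yhi in zip(y, yhat))
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    return 1.0 - ss_res / ss_tot


def brute_force_prominent_maxima(stress, min_prominence: float) -> list[int]:
    """O(n^2) scan for interior local maxima with at least the given prominence.

    Prominence of a local maximum is its height above the higher of the two
    lowest points separating it from higher terrain (or the trace edge) —
    evaluated by direct walking, independent of any peak-picking library.
    """
    s = np.asarray(stress, dtype=float)
    out = []
    for i in range(1, len(s) - 1):
        if not (s[i] > s[i - 1] and s[i] >= s[i + 1]):
            continue
        left = i
        left_min = s[i]
        while left > 0 and s[left - 1] <= s[i]:
            left -= 1
            left_min = min(left_min, s[left])
        right = i
        right_min = s[i]
        while right < len(s) - 1 and s[right + 1] <= s[i]:
            right += 1
            right_min = min(right_min, s[right])
        if s[i] - max(left_min, right_min) >= min_prominence:
            out.append(i)
    return out


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def stress_rows():
    return reference.stress_rows()


@pytest.fixture(scope="session")
def stretch_rows():
    return reference.stretch_rows()


@pytest.fixture(scope="session")
def noiseless_cyclic_record():
    return sf.generate_cyclic(sf.default_cyclic_spec(n_cycles=10, seed=11))


@pytest.fixture(scope="session")
def noisy_cyclic_record():
    return sf.generate_cyclic(
        sf.default_cyclic_spec(
            n_cycles=10,
            noise_sd_stress_mpa=NOISE_SD_STRESS,
            noise_sd_displacement_mm=0.005,
            seed=13,
        )
    )


@pytest.fixture(scope="session")
def fracture_record():
    return sf.generate_fracture(sf.default_fracture_spec(seed=7))
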