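"""Pure model layer: logistic stress, quadratic stretch, composition, transform."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stressfit import (
    InvalidArgumentError,
    LogisticStressModel,
    NonLinearStretchError,
    DegenerateStretchError,
    ParametricCyclePair,
    QuadraticStretchModel,
    compose_stress_stretch,
    eval_stress,
    eval_stretch,
    tangent_at_midpoint,
    to_stretch_domain,
)

L3_LOAD = LogisticStressModel(0.1133, 7.163, 1.4699, 3.2392)
L3_DOWN = QuadraticStretchModel(-0.00002, -0.4544, 1.00016)

finite_coeff = st.floats(-50, 50, allow_nan=False)


@pytest.mark.parametrize(
    "model, t, expected",
    [
        (LogisticStressModel(0, 1, 1, 0), 0.0, 0.5),  # sigmoid midpoint
        (L3_LOAD, 3.2392, 0.1133 + 7.163 / 2),  # midpoint identity C0 + C1/2
        (LogisticStressModel(2, 3, 5, 0), 1e6, 5.0),  # upper asymptote C0 + C1
    ],
)
def test_eval_stress_reference_points(model, t, expected):
    assert eval_stress(model, t) == pytest.approx(expected, rel=1e-12)


def test_eval_stress_saturates_without_overflow():
    """Sharp near-step sigmoids (C2 in the hundreds) must not overflow exp."""
    sharp = LogisticStressModel(-0.0566, 5.7441, 296.3236, 0.0453)
    with np.errstate(over="raise"):
        lo = sharp.predict(-1e3)
        hi = sharp.predict(1e3)
    assert lo == pytest.approx(sharp.c0)
    assert hi == pytest.approx(sharp.c0 + sharp.c1)


@pytest.mark.parametrize(
    "model, t, expected",
    [
        (QuadraticStretchModel(0, 0, 1), 17.3, 1.0),
        (L3_DOWN, 1.0, 0.54574),
        (QuadraticStretchModel(1, 2, 3), 2.0, 11.0),
    ],
)
def test_eval_stretch_reference_points(model, t, expected):
    assert eval_stretch(model, t) == pytest.approx(expected, rel=1e-12)


def test_eval_stretch_intercept_exact_at_zero():
    assert eval_stretch(L3_DOWN, 0.0) == 1.00016


@pytest.mark.parametrize(
    "c1, c2, expected",
    [(4, 1, 1.0), (7.163, 1.4699, 2.6322), (5, 0, 0.0)],
)
def test_tangent_at_midpoint(c1, c2, expected):
    model = LogisticStressModel(0.0, c1, c2, 1.0)
    assert tangent_at_midpoint(model) == pytest.approx(expected, abs=5e-5)


def test_tangent_matches_finite_difference():
    h = 1e-7
    fd = (L3_LOAD.predict(L3_LOAD.c3 + h) - L3_LOAD.predict(L3_LOAD.c3 - h)) / (2 * h)
    assert tangent_at_midpoint(L3_LOAD) == pytest.approx(fd, rel=1e-8)


@pytest.mark.parametrize("bad", [np.nan, np.inf])
def test_eval_rejects_non_finite_input(bad):
    with pytest.raises(InvalidArgumentError):
        L3_LOAD.predict(bad)
    with pytest.raises(InvalidArgumentError):
        LogisticStressModel(bad, 1, 1, 0)


@given(
    c0=finite_coeff,
    c1=st.floats(0.1, 50),
    c2=st.floats(0.05, 40),
    c3=finite_coeff,
    sign=st.sampled_from([1.0, -1.0]),
)
def test_logistic_monotone_in_direction_of_c2(c0, c1, c2, c3, sign):
    """C1 > 0: strictly increasing for C2 > 0, strictly decreasing for C2 < 0."""
    model = LogisticStressModel(c0, c1, sign * c2, c3)
    t = np.linspace(c3 - 3 / c2, c3 + 3 / c2, 50)
    diffs = np.diff(model.predict(t))
    assert np.all(diffs > 0) if sign > 0 else np.all(diffs < 0)


@given(c1=st.floats(0.5, 30), c2=st.floats(0.5, 20))
def test_logistic_range_approaches_amplitude(c1, c2):
    """sup - inf over a wide window approaches |C1| from below."""
    model = LogisticStressModel(1.0, c1, c2, 0.0)
    wide = model.predict(np.linspace(-50 / c2, 50 / c2, 201))
    spread = wide.max() - wide.min()
    assert spread <= c1 * (1 + 1e-12)
    assert spread == pytest.approx(c1, rel=1e-6)


def test_canonical_form_is_equivalent_and_positive():
    m = LogisticStressModel(5.0, -3.0, 2.0, 1.0)
    canon = m.canonical()
    assert canon.c1 > 0
    t = np.linspace(-3, 5, 50)
    np.testing.assert_allclose(canon.predict(t), m.predict(t), rtol=1e-14)


class TestStretchDomainTransform:
    def test_identity_stretch_keeps_coefficients(self):
        pair = ParametricCyclePair(L3_LOAD, QuadraticStretchModel(0, 1, 0))
        out = to_stretch_domain(pair)
        assert (out.c0, out.c1, out.c2, out.c3) == (
            L3_LOAD.c0,
            L3_LOAD.c1,
            L3_LOAD.c2,
            L3_LOAD.c3,
        )

    def test_reference_pair_transformed_coefficients(self):
        pair = ParametricCyclePair(L3_LOAD, L3_DOWN)
        out = to_stretch_domain(pair)
        assert out.c2 == pytest.approx(1.4699 / -0.4544, rel=1e-12)
        assert out.c3 == pytest.approx(1.00016 + (-0.4544) * 3.2392, rel=1e-12)
        assert out.c2 == pytest.approx(-3.2348, abs=5e-5)
        assert out.c3 == pytest.approx(-0.4717, abs=5e-5)

    def test_round_trip_reproduces_time_domain_stress(self):
        """Composing the transformed model with linearized stretch is exact."""
        pair = ParametricCyclePair(L3_LOAD, L3_DOWN)
        out = to_stretch_domain(pair)
        t = np.linspace(0.0, 6.5, 73)
        lam = pair.stretch.linearized().predict(t)
        np.testing.assert_allclose(out.predict(lam), pair.stress.predict(t), rtol=1e-12)

    def test_non_linear_stretch_rejected(self):
        curved = QuadraticStretchModel(0.5, -0.4, 1.0)
        pair = ParametricCyclePair(L3_LOAD, curved)
        with pytest.raises(NonLinearStretchError):
            to_stretch_domain(pair, d2_tolerance=1e-3)

    def test_constant_stretch_rejected(self):
        flat = QuadraticStretchModel(0.0, 0.0, 1.0)
        pair = ParametricCyclePair(L3_LOAD, flat)
        with pytest.raises(DegenerateStretchError):
            to_stretch_domain(pair)


class TestCompose:
    def test_constant_stretch_model_gives_constant_stretch_column(self):
        pair = ParametricCyclePair(L3_LOAD, QuadraticStretchModel(0, 0, 1))
        pts = compose_stress_stretch(pair, np.linspace(0, 5, 11))
        np.testing.assert_array_equal(pts[:, 0], 1.0)

    def test_midpoint_stress_on_reference_grid(self):
        pair = ParametricCyclePair(L3_LOAD, L3_DOWN)
        pts = compose_stress_stretch(pair, np.array([0.0, L3_LOAD.c3, 2 * L3_LOAD.c3]))
        assert pts[1, 1] == pytest.approx(3.6948, abs=5e-5)

    def test_singleton_grid_matches_both_eval_ops(self):
        pair = ParametricCyclePair(L3_LOAD, L3_DOWN)
        pts = compose_stress_stretch(pair, [2.5])
        assert pts.shape == (1, 2)
        assert pts[0, 0] == eval_stretch(L3_DOWN, 2.5)
        assert pts[0, 1] == eval_stress(L3_LOAD, 2.5)

    @pytest.mark.parametrize("grid", [[], [3.0, 1.0], [1.0, 1.0]])
    def test_bad_grids_rejected(self, grid):
        pair = ParametricCyclePair(L3_LOAD, L3_DOWN)
        with pytest.raises(InvalidArgumentError):
            compose_stress_stretch(pair, grid)


def test_cycle_pair_validation():
    with pytest.raises(InvalidArgumentError):
        ParametricCyclePair(L3_LOAD, L3_DOWN, cycle_index=0)
    with pytest.raises(InvalidArgumentError):
        ParametricCyclePair(L3_LOAD, L3_DOWN, direction="sideways")
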