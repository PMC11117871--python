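"""Least-squares estimation: R^2, logistic and quadratic fits, per-cycle fits."""

import numpy as np
import pytest
from conftest import (
    brute_force_r_squared,
    recover_stress_row,
    recover_stretch_row,
    recovery_grid,
    rel_err,
)
from hypothesis import given
from hypothesis import strategies as st

import stressfit as sf
from stressfit import (
    DegenerateDataError,
    InvalidArgumentError,
    LogisticStressModel,
    QuadraticStretchModel,
    fit_cycle,
    fit_logistic_stress,
    fit_quadratic_stretch,
    r_squared,
    segment_cycles,
    to_stress_stretch,
)


class TestRSquared:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 5.0])
        assert r_squared(y, y) == 1.0

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0)) == 0.0

    def test_hand_computed_example(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_constant_observed_rejected(self):
        with pytest.raises(DegenerateDataError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 12))
            y = rng.normal(size=n)
            yhat = y + rng.normal(scale=0.3, size=n)
            assert r_squared(y, yhat) == pytest.approx(
                brute_force_r_squared(y, yhat), abs=1e-12
            )

    @given(scale=st.floats(0.01, 100), shift=st.floats(-50, 50))
    def test_invariant_under_affine_rescaling_of_both_series(self, scale, shift):
        y = np.array([0.1, 1.4, 2.2, 3.9, 2.5])
        yhat = np.array([0.2, 1.2, 2.5, 3.6, 2.6])
        base = r_squared(y, yhat)
        assert r_squared(scale * y + shift, scale * yhat + shift) == pytest.approx(base)


class TestLogisticRecovery:
    def test_reference_loading_row_round_trip(self):
        truth = LogisticStressModel(0.1133, 7.163, 1.4699, 3.2392)
        t = np.linspace(0, 6.5, 200)
        fit = fit_logistic_stress(t, truth.predict(t))
        assert rel_err(fit.model.c1, 7.163) <= 1e-3
        assert fit.r_squared >= 1 - 1e-9

    def test_all_reference_rows_recovered(self, stress_rows):
        """Noiseless round trip over every published stress coefficient row."""
        for _, row in stress_rows.iterrows():
            truth, fit = recover_stress_row(row)
            m = fit.model
            c2_tol = 0.10 if abs(truth.c2) > 50 else 1e-3
            assert rel_err(m.c0, truth.c0) <= 1e-3, row.to_dict()
            assert rel_err(m.c1, truth.c1) <= 1e-3, row.to_dict()
            assert rel_err(m.c2, truth.c2) <= c2_tol, row.to_dict()
            assert rel_err(m.c3, truth.c3) <= 1e-3, row.to_dict()
            assert fit.r_squared >= 1 - 1e-9

    def test_sharp_sigmoid_offset_and_amplitude(self):
        """Near-step regime (C2 ~ 240): C0/C1 tight, C2 within 10%."""
        truth = LogisticStressModel(0.0356, 6.3102, 242.6306, 0.0292)
        t = recovery_grid(truth.c3, 400)
        fit = fit_logistic_stress(t, truth.predict(t))
        assert rel_err(fit.model.c0, truth.c0) <= 1e-2
        assert rel_err(fit.model.c1, truth.c1) <= 1e-2
        assert rel_err(fit.model.c2, truth.c2) <= 0.10

    def test_converged_fit_scores_unity_on_own_predictions(self):
        truth = LogisticStressModel(0.2, 5.0, 2.0, 1.5)
        t = np.linspace(0, 3, 80)
        fit = fit_logistic_stress(t, truth.predict(t))
        assert r_squared(fit.model.predict(t), fit.model.predict(t)) == 1.0

    def test_amplitude_estimate_unbiased_under_noise(self):
        """Mean C1 over seeded noisy replicates within 3 standard errors of truth."""
        truth = LogisticStressModel(0.1133, 7.163, 1.4699, 3.2392)
        t = np.linspace(0, 2 * truth.c3, 200)
        clean = truth.predict(t)
        sd = 0.005 * truth.c1
        rng = np.random.default_rng(2024)
        estimates = []
        for _ in range(200):
            fit = fit_logistic_stress(t, clean + rng.normal(0, sd, t.size))
            estimates.append(fit.model.c1)
        estimates = np.asarray(estimates)
        stderr = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - truth.c1) <= 3 * stderr

    def test_constant_stress_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_logistic_stress(np.linspace(0, 1, 20), np.full(20, 3.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_logistic_stress([0, 1, 2, 3], [0, 1, 2, 3])

    def test_canonical_output_has_positive_amplitude(self):
        """A falling segment is encoded with C1 > 0 and C2 < 0."""
        truth = LogisticStressModel(0.0, 5.0, -2.0, 1.5)
        t = np.linspace(0, 3, 100)
        fit = fit_logistic_stress(t, truth.predict(t))
        assert fit.model.c1 > 0
        assert fit.model.c2 < 0


class TestQuadraticFit:
    def test_all_reference_rows_exact(self, stretch_rows):
        """OLS is exact on noiseless quadratic data, every published row."""
        for _, row in stretch_rows.iterrows():
            truth, fit = recover_stretch_row(row)
            assert abs(fit.model.d2 - truth.d2) <= 1e-9
            assert abs(fit.model.d1 - truth.d1) <= 1e-9
            assert abs(fit.model.d0 - truth.d0) <= 1e-9

    def test_constant_stretch(self):
        fit = fit_quadratic_stretch(np.linspace(0, 1, 10), np.ones(10))
        assert fit.model.d2 == pytest.approx(0.0, abs=1e-12)
        assert fit.model.d1 == pytest.approx(0.0, abs=1e-12)
        assert fit.model.d0 == pytest.approx(1.0, rel=1e-12)
        assert fit.r_squared == 1.0

    def test_exact_linear_case(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_quadratic_stretch(t, t)
        assert fit.model.d2 == pytest.approx(0.0, abs=1e-12)
        assert fit.model.d1 == pytest.approx(1.0, rel=1e-12)
        assert fit.model.d0 == pytest.approx(0.0, abs=1e-12)

    def test_direction_labels_follow_d1_sign(self):
        t = np.linspace(0, 1, 20)
        assert fit_quadratic_stretch(t, 1 - 0.3 * t).direction_label == "down"
        assert fit_quadratic_stretch(t, 0.7 + 0.3 * t).direction_label == "up"

    def test_degenerate_time_axis_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_quadratic_stretch(np.zeros(6), np.linspace(0, 1, 6))

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_quadratic_stretch([0, 1, 2], [0, 1, 2])


class TestFitCycle:
    def test_round_trip_on_generated_segment(self, noiseless_cyclic_record):
        trace = to_stress_stretch(noiseless_cyclic_record)
        seg = segment_cycles(trace)[0]
        result = fit_cycle(seg)
        truth = noiseless_cyclic_record.ground_truth[0]
        t_local = np.linspace(0, seg.time_s[-1] - seg.time_s[0], 50)
        np.testing.assert_allclose(
            result.pair.stress.predict(t_local), truth.stress.predict(t_local), atol=1e-6
        )
        np.testing.assert_allclose(
            result.pair.stretch.predict(t_local), truth.stretch.predict(t_local), atol=1e-6
        )

    def test_unload_segment_labelled_up_with_positive_d1(self, noiseless_cyclic_record):
        trace = to_stress_stretch(noiseless_cyclic_record)
        unload = [s for s in segment_cycles(trace) if s.direction == "unload"][0]
        result = fit_cycle(unload)
        assert result.stretch.direction_label == "up"
        assert result.stretch.model.d1 >= 0

    def test_time_rezeroed_per_segment(self, noiseless_cyclic_record):
        trace = to_stress_stretch(noiseless_cyclic_record)
        seg = segment_cycles(trace)[2]  # second loading segment, t_start > 0
        result = fit_cycle(seg)
        assert result.time_origin_s == pytest.approx(seg.time_s[0])
        # fitted midpoint is expressed on the local clock, not the global one
        assert 0 < result.pair.stress.c3 < seg.time_s[-1] - seg.time_s[0]

    def test_stretch_mode_skips_quadratic(self, fracture_record):
        trace = to_stress_stretch(fracture_record)
        seg = segment_cycles(trace)[0]
        result = fit_cycle(seg, mode="stretch")
        assert result.stretch is None and result.pair is None
        assert result.stress.mode == "stretch"
        assert result.stress.r_squared >= 1 - 1e-9

    def test_tiny_segment_rejected(self):
        from stressfit.segmentation import CycleSegment

        seg = CycleSegment(
            cycle_index=1,
            direction="load",
            start_index=0,
            end_index=2,
            time_s=np.array([0.0, 1.0, 2.0]),
            stress_mpa=np.array([0.0, 1.0, 2.0]),
            stretch=np.array([1.0, 0.9, 0.8]),
        )
        with pytest.raises(InvalidArgumentError):
            fit_cycle(seg)


def test_stretch_domain_fit_recovers_stretch_parameterized_row():
    """Load-to-fracture style: logistic fitted with stretch as the abscissa."""
    truth = LogisticStressModel(-4.3779, 33.41, 9.1167, 0.7886)
    lam = np.linspace(1.0, 0.55, 300)[::-1]
    fit = fit_logistic_stress(lam, truth.predict(lam), mode="stretch")
    assert rel_err(fit.model.c2, truth.c2) <= 1e-3
    assert rel_err(fit.model.c3, truth.c3) <= 1e-3
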