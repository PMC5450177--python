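"""Unit tests for the inverse action-potential fit and classification."""

import warnings

import numpy as np
import pytest

from ecginverse.ap_model import APParams, build_default_templates, template_integral
from ecginverse.feature_detection import detect_beats
from ecginverse.inverse_fitting import (
    LABEL_HEART_FAILURE,
    LABEL_ISCHEMIA,
    LABEL_NORMAL,
    ActionPotentialModel,
    FitConfig,
    FitInput,
    SingularDesignError,
    advisory_flags,
    classify,
    classify_table,
    fit_ap,
    regressors,
    solve_h,
    solve_k,
)
from ecginverse.synthetic_ecg import SimConfig, generate_from_ap

TEMPLATES = build_default_templates()
LEFT, RIGHT = TEMPLATES
PHI1 = template_integral(RIGHT, 1.0)
PHI2 = template_integral(LEFT, 1.0)


def _consistent_input(k, h_r, h_l, n=30, lat_lo=0.10, lat_hi=0.26):
    """Noise-free FitInput generated directly from the forward model."""
    lat = np.linspace(lat_lo, lat_hi, n)
    amp = h_r * RIGHT(k * lat) - h_l * LEFT(k * lat)
    delta = np.full(n, (h_r * PHI1 - h_l * PHI2) / k)
    return FitInput(t_amplitudes=amp, latencies=lat, deltas=delta)


class TestRegressors:
    def test_latency_zero_gives_zero(self):
        y1, y2 = regressors(TEMPLATES, np.array([0.0]), k=1.0)
        assert y1[0] == 0.0
        assert y2[0] == 0.0

    def test_grid_points_exact_at_unit_k(self):
        tau = RIGHT.grid[10:20]
        y1, y2 = regressors(TEMPLATES, tau, k=1.0)
        assert np.array_equal(y1, RIGHT.values[10:20])
        assert np.array_equal(y2, LEFT.values[10:20])

    def test_support_halved_at_k2_with_warning(self):
        tau = np.array([0.1, RIGHT.duration / 2 + 0.01])
        with pytest.warns(UserWarning, match="beyond template support"):
            y1, _y2 = regressors(TEMPLATES, tau, k=2.0)
        assert y1[1] == 0.0
        assert y1[0] != 0.0

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            regressors(TEMPLATES, np.array([0.1]), k=0.0)


class TestSolveH:
    def test_exact_recovery(self):
        rng = np.random.default_rng(42)
        y1 = rng.random(50)
        y2 = rng.random(50)
        T = 0.9 * y1 - 0.8 * y2
        h_r, h_l = solve_h(T, y1, y2)
        assert h_r == pytest.approx(0.9, abs=1e-9)
        assert h_l == pytest.approx(0.8, abs=1e-9)

    def test_constant_regressor_singular(self):
        rng = np.random.default_rng(0)
        y1 = rng.random(20)
        with pytest.raises(SingularDesignError):
            solve_h(rng.random(20), y1, np.zeros(20))

    def test_collinear_regressors_singular(self):
        rng = np.random.default_rng(1)
        y1 = rng.random(20)
        with pytest.raises(SingularDesignError):
            solve_h(rng.random(20), y1, 2.0 * y1)

    def test_oracle_equivalence_100_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            y1 = rng.standard_normal(n)
            y2 = rng.standard_normal(n)
            T = rng.standard_normal(n)
            h_r, h_l = solve_h(T, y1, y2)
            design = np.column_stack([y1, -y2, np.ones(n)])
            coeffs, *_ = np.linalg.lstsq(design, T, rcond=None)
            assert h_r == pytest.approx(coeffs[0], abs=1e-9)
            assert h_l == pytest.approx(coeffs[1], abs=1e-9)

    def test_too_short(self):
        with pytest.raises(ValueError):
            solve_h(np.array([1.0]), np.array([1.0]), np.array([2.0]))


class TestSolveK:
    def test_exact_inverse_slope(self):
        u = 0.9 * PHI1 - 0.8 * PHI2
        deltas = np.full(10, u / 1.3)
        assert solve_k(deltas, 0.9, 0.8, PHI1, PHI2) == pytest.approx(1.3)

    def test_noisy_estimate_near_truth(self):
        rng = np.random.default_rng(3)
        u = 0.9 * PHI1 - 0.8 * PHI2
        deltas = u / 1.3 + 0.01 * abs(u) * rng.standard_normal(100)
        k = solve_k(deltas, 0.9, 0.8, PHI1, PHI2)
        assert k == pytest.approx(1.3, rel=0.05)

    def test_balanced_case_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            solve_k(np.ones(5), 1.0, PHI1 / PHI2, PHI1, PHI2)

    def test_zero_mean_delta_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            solve_k(np.zeros(5), 0.9, 0.8, PHI1, PHI2)


class TestFitAp:
    @pytest.mark.parametrize("k,h_r,h_l", [
        (1.0, 1.0, 1.0),
        (0.7, 0.9, 0.93),
        (1.4, 0.8, 1.0),
    ])
    def test_recovery_from_consistent_features(self, k, h_r, h_l):
        result = fit_ap(_consistent_input(k, h_r, h_l), TEMPLATES)
        assert result.converged
        assert result.k == pytest.approx(k, rel=1e-3)
        assert result.h_r == pytest.approx(h_r, rel=1e-3)
        assert result.h_l == pytest.approx(h_l, rel=1e-3)

    def test_end_to_end_normal(self):
        config = SimConfig(seed=11)
        signal, _ = generate_from_ap(APParams(1.0, 1.0, 1.0), TEMPLATES, config)
        outcome = detect_beats(signal, config.fs)
        result = fit_ap(outcome.beats, TEMPLATES)
        assert result.k == pytest.approx(1.0, rel=0.02)
        assert result.h_r == pytest.approx(1.0, rel=0.02)
        assert result.h_l == pytest.approx(1.0, rel=0.02)
        assert classify(result.params) == LABEL_NORMAL

    def test_end_to_end_ischemia_decision_region(self):
        # an ischemia-like setting must land below the 0.9 threshold
        config = SimConfig(seed=11)
        signal, _ = generate_from_ap(APParams(0.7, 0.9, 0.93), TEMPLATES, config)
        outcome = detect_beats(signal, config.fs)
        result = fit_ap(outcome.beats, TEMPLATES)
        assert result.k < 0.9
        assert classify(result.params) == LABEL_ISCHEMIA

    def test_single_beat_rejected(self):
        with pytest.raises(ValueError):
            FitInput(np.array([0.2]), np.array([0.2]), np.array([0.05]))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            FitInput(np.zeros(3), np.zeros(3), np.zeros(2))

    def test_zero_deltas_rejected(self):
        data = FitInput(np.array([0.1, 0.2]), np.array([0.15, 0.2]),
                        np.array([0.0, 0.0]))
        with pytest.raises(ValueError, match="zero"):
            fit_ap(data, TEMPLATES)

    def test_result_reports_history_and_residual(self):
        result = fit_ap(_consistent_input(1.1, 0.9, 0.8), TEMPLATES)
        assert result.rounds_used == len(result.history) >= 1
        assert result.residual_norm < 1e-6


class TestFitInputFromBeats:
    def test_support_rows_expanded(self):
        config = SimConfig(seed=11)
        signal, _ = generate_from_ap(APParams(1.0, 1.0, 1.0), TEMPLATES, config)
        outcome = detect_beats(signal, config.fs)
        complete = [b for b in outcome.beats if b.complete]
        data = FitInput.from_beats(complete)
        assert data.n > len(complete)  # per-sample rows, not per-beat scalars
        scalar = FitInput.from_beats(complete, use_support=False)
        assert scalar.n == len(complete)

    def test_needs_two_complete_beats(self):
        from ecginverse.feature_detection import BeatFeatures

        beats = [BeatFeatures(r_time=1.0, r_amplitude=1.0)]
        with pytest.raises(ValueError, match="at least 2"):
            FitInput.from_beats(beats)


class TestClassify:
    def test_reference_exemplars(self):
        assert classify(APParams(0.71, 0.97, 0.95)) == LABEL_ISCHEMIA
        assert classify(APParams(1.79, 0.81, 0.83)) == LABEL_HEART_FAILURE
        assert classify(APParams(1.01, 0.98, 0.99)) == LABEL_NORMAL

    def test_boundaries_are_normal(self):
        assert classify(APParams(0.9, 1.0, 1.0)) == LABEL_NORMAL
        assert classify(APParams(1.2, 1.0, 1.0)) == LABEL_NORMAL

    def test_monotone_in_k(self):
        order = {LABEL_ISCHEMIA: 0, LABEL_NORMAL: 1, LABEL_HEART_FAILURE: 2}
        ks = np.linspace(0.3, 2.5, 45)
        labels = [order[classify(APParams(k, 1.0, 1.0))] for k in ks]
        assert all(b >= a for a, b in zip(labels, labels[1:]))

    def test_advisory_flags(self):
        assert advisory_flags(APParams(1.0, 0.90, 1.0)) == ["low_h_r"]
        assert advisory_flags(APParams(1.0, 1.0, 0.90)) == ["low_h_l"]
        assert advisory_flags(APParams(1.0, 1.0, 1.0)) == []


class TestClassifyTable:
    def test_bundled_pathology_table_accuracies(self):
        from ecginverse.datasets import load_pathology_fits

        report = classify_table(load_pathology_fits())
        by_label = report.set_index("clinical_label")["accuracy_pct"]
        assert by_label["myocardial_ischemia"] == pytest.approx(93.3)
        assert by_label["heart_failure"] == pytest.approx(86.7)
        assert by_label["normal"] == pytest.approx(100.0)

    def test_tuple_rows(self):
        rows = [
            (0.7, 1.0, 1.0, LABEL_ISCHEMIA),
            (1.0, 1.0, 1.0, LABEL_NORMAL),
            (1.5, 1.0, 1.0, LABEL_NORMAL),
        ]
        report = classify_table(rows)
        by_label = dict(zip(report["clinical_label"], report["accuracy_pct"]))
        assert by_label[LABEL_ISCHEMIA] == 100.0
        assert by_label[LABEL_NORMAL] == 50.0

    def test_empty_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            classify_table(pd.DataFrame(columns=["k", "h_r", "h_l", "clinical_label"]))


class TestActionPotentialModel:
    def test_fit_array_input(self):
        data = _consistent_input(1.0, 1.0, 1.0)
        X = np.column_stack([data.t_amplitudes, data.latencies, data.deltas])
        model = ActionPotentialModel().fit(X)
        assert model.k_ == pytest.approx(1.0, rel=1e-3)
        assert model.label_ == LABEL_NORMAL
        assert model.converged_

    def test_predict_returns_label(self):
        data = _consistent_input(0.7, 0.9, 0.93)
        X = np.column_stack([data.t_amplitudes, data.latencies, data.deltas])
        labels = ActionPotentialModel().predict(X)
        assert list(labels) == [LABEL_ISCHEMIA]

    def test_sklearn_params(self):
        model = ActionPotentialModel(k_low=0.85)
        assert model.get_params()["k_low"] == 0.85
        model.set_params(k_high=1.3)
        assert model.k_high == 1.3

    def test_bad_array_shape(self):
        with pytest.raises(ValueError, match=r"\(n, 3\)"):
            ActionPotentialModel().fit(np.zeros((4, 2)))
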