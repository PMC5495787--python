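import numpy as np
import pytest

from hrpfsasa.calibration import (
    CalibrationModel,
    CalibrationPoint,
    evaluate_predictions,
    fit_calibration,
    jackknife,
    predict_sasa,
    PredictionResult,
)
from hrpfsasa.gxg import gxg_reference


def points_from(xs, ys, protein="myo"):
    return [
        CalibrationPoint("A", i + 1, "TRP", x, y, protein_id=protein)
        for i, (x, y) in enumerate(zip(xs, ys))
    ]


class TestFitCalibration:
    def test_collinear_points_exact(self):
        pts = points_from([0.1, 0.2, 0.3, 0.4], [0.25, 0.45, 0.65, 0.85])
        model = fit_calibration(pts, "npf")
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(0.05)
        assert model.pearson_r == pytest.approx(1.0)

    def test_anticorrelated_line(self):
        pts = points_from([0.1, 0.2, 0.3], [0.9, 0.6, 0.3])
        model = fit_calibration(pts, "ratio")
        assert model.pearson_r == pytest.approx(-1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(11)
        xs = rng.uniform(0.05, 1.0, size=6)
        ys = np.abs(0.9 * xs + 0.1 + rng.normal(0, 0.05, size=6))
        model = fit_calibration(points_from(xs, ys), "npf")
        design = np.column_stack([np.ones(6), xs])
        beta = np.linalg.solve(design.T @ design, design.T @ ys)
        assert model.intercept == pytest.approx(beta[0], abs=1e-10)
        assert model.slope == pytest.approx(beta[1], abs=1e-10)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_calibration(points_from([0.2, 0.2, 0.2], [0.1, 0.2, 0.3]), "npf")

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration(points_from([0.1, 0.2], [0.1, 0.2]), "npf")

    def test_training_proteins_recorded(self):
        pts = points_from([0.1, 0.2], [0.1, 0.2], "myo") + points_from(
            [0.3, 0.4], [0.3, 0.4], "lys"
        )
        model = fit_calibration(pts, "npf")
        assert model.training_proteins == frozenset({"myo", "lys"})

    def test_json_roundtrip(self):
        model = fit_calibration(points_from([0.1, 0.2, 0.5], [0.2, 0.3, 0.6]), "npf")
        again = CalibrationModel.from_json(model.to_json())
        assert again == model

    def test_coefficient_recovery_within_three_se(self):
        """Across seeded noisy datasets from a known linear law, the fitted
        slope lies within 3 SE of truth in >= 95% of replicates."""
        from scipy import stats

        rng = np.random.default_rng(991)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            xs = rng.uniform(0.05, 1.0, size=12)
            ys = np.abs(0.8 * xs + 0.05 + rng.normal(0, 0.06, size=12))
            fit = stats.linregress(xs, ys)
            hits += abs(fit.slope - 0.8) <= 3 * fit.stderr
        assert hits / n_rep >= 0.95


class TestPredict:
    def test_prediction_at_training_mean(self):
        xs = [0.1, 0.25, 0.4, 0.55]
        ys = [0.22, 0.38, 0.41, 0.66]
        model = fit_calibration(points_from(xs, ys), "npf")
        pred = predict_sasa(model, float(np.mean(xs)), ("A", 1, "TRP"))
        assert pred.fractional_sasa == pytest.approx(np.mean(ys))

    def test_arithmetic(self):
        model = CalibrationModel("npf", 2.0, 0.1, 1.0, 5)
        pred = predict_sasa(model, 0.2, ("A", 1, "TRP"))
        assert pred.fractional_sasa == pytest.approx(0.5)
        assert pred.absolute_sasa == pytest.approx(0.5 * gxg_reference("TRP"))

    def test_negative_prediction_clipped(self):
        model = CalibrationModel("npf", 2.0, -0.5, 1.0, 5)
        with pytest.warns(UserWarning, match="clipped"):
            pred = predict_sasa(model, 0.1, ("A", 1, "TRP"))
        assert pred.fractional_sasa == 0.0

    def test_glycine_unsupported(self):
        model = CalibrationModel("npf", 1.0, 0.0, 1.0, 5)
        with pytest.raises(ValueError):
            predict_sasa(model, 0.5, ("A", 1, "GLY"))


class TestJackknife:
    def test_exact_line_all_models_coincide(self):
        pts = points_from([0.1, 0.2, 0.3, 0.4, 0.5],
                          [0.15, 0.25, 0.35, 0.45, 0.55])
        full = fit_calibration(pts, "npf")
        summary = jackknife(pts, "npf")
        assert len(summary.models) == 5
        for m in summary.models:
            assert m.slope == pytest.approx(full.slope, abs=1e-12)
            assert m.intercept == pytest.approx(full.intercept, abs=1e-12)
        assert summary.slope_range[0] == pytest.approx(summary.slope_range[1])

    def test_count_matches_points(self):
        pts = points_from([0.1, 0.3, 0.2, 0.5], [0.2, 0.4, 0.1, 0.6])
        assert len(jackknife(pts, "npf").models) == 4

    def test_loo_predictions_match_brute_force(self):
        rng = np.random.default_rng(5)
        xs = rng.uniform(0.0, 1.0, size=8)
        ys = np.abs(xs + rng.normal(0, 0.1, size=8))
        pts = points_from(xs, ys)
        summary = jackknife(pts, "npf")
        for i, point in enumerate(pts):
            refit = fit_calibration(pts[:i] + pts[i + 1:], "npf")
            expected = refit.slope * point.x + refit.intercept
            assert summary.loo_predictions[i] == pytest.approx(expected, abs=1e-12)

    def test_needs_four_points(self):
        with pytest.raises(ValueError):
            jackknife(points_from([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]), "npf")


def predictions_from(pred, ref):
    return [
        PredictionResult("A", i + 1, "TRP", 0.0, p, reference_sasa=r)
        for i, (p, r) in enumerate(zip(pred, ref))
    ]


class TestEvaluatePredictions:
    def test_perfect_predictions(self):
        out = evaluate_predictions(predictions_from([10, 20, 30], [10, 20, 30]))
        assert out["rmsd"] == 0.0
        assert out["r_squared"] == pytest.approx(1.0)

    def test_constant_offset_rmsd_equals_offset(self):
        out = evaluate_predictions(predictions_from([15, 25, 35], [10, 20, 30]))
        assert out["rmsd"] == pytest.approx(5.0)

    def test_offset_detectable_by_identity_r2_not_pearson(self):
        out = evaluate_predictions(predictions_from([15, 25, 35], [10, 20, 30]))
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["r_squared"] < 1.0

    def test_hand_computed_five_pairs(self):
        pred = [12.0, 18.0, 33.0, 44.0, 52.0]
        ref = [10.0, 20.0, 30.0, 40.0, 50.0]
        out = evaluate_predictions(predictions_from(pred, ref))
        sq = [(p - r) ** 2 for p, r in zip(pred, ref)]
        assert out["rmsd"] == pytest.approx(np.sqrt(np.mean(sq)))
        ss_tot = sum((r - 30.0) ** 2 for r in ref)
        assert out["r_squared"] == pytest.approx(1 - sum(sq) / ss_tot)
        assert out["n"] == 5

    def test_missing_references_rejected(self):
        preds = [PredictionResult("A", 1, "TRP", 0.1, 10.0)]
        with pytest.raises(ValueError):
            evaluate_predictions(preds)

    def test_redundant_training_data_changes_little(self):
        """Duplicating one protein's points barely moves predictions for an
        unseen protein when both proteins obey the same law."""
        rng = np.random.default_rng(17)
        xs1 = rng.uniform(0.1, 1.0, size=15)
        ys1 = np.abs(0.9 * xs1 + 0.05 + rng.normal(0, 0.04, size=15))
        xs2 = rng.uniform(0.1, 1.0, size=15)
        ys2 = np.abs(0.9 * xs2 + 0.05 + rng.normal(0, 0.04, size=15))
        single = fit_calibration(points_from(xs1, ys1, "myo"), "npf")
        dual = fit_calibration(
            points_from(xs1, ys1, "myo") + points_from(xs2, ys2, "lys"), "npf"
        )
        x_test = np.linspace(0.1, 1.0, 20)
        p_single = single.slope * x_test + single.intercept
        p_dual = dual.slope * x_test + dual.intercept
        assert np.max(np.abs(p_single - p_dual)) < 0.05
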