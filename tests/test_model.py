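"""Scale-coefficient fitting, bias estimation, prediction, scoring and the
packaged reference calibration's internal consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import seraquant as sq
from seraquant.model import (
    ModelError,
    REFERENCE_DELTA,
    _round_half_up,
    fit_shared_composite_value,
    implied_composite_values,
)


class TestScaleCoefficients:
    def test_proportional_data_exact(self):
        panels = [
            sq.ConcentrationPanel("a", {"B1": 2.0}),
            sq.ConcentrationPanel("b", {"B1": 4.0}),
        ]
        c = sq.fit_scale_coefficients([1.0, 2.0], panels)
        assert c["B1"] == pytest.approx(2.0, abs=1e-15)

    def test_equal_k_gives_mean(self):
        panels = [
            sq.ConcentrationPanel("a", {"B1": 1.0}),
            sq.ConcentrationPanel("b", {"B1": 3.0}),
        ]
        assert sq.fit_scale_coefficients([1.0, 1.0], panels)["B1"] == pytest.approx(2.0)

    def test_matches_scalar_minimisation_oracle(self):
        rng = np.random.default_rng(5)
        K = rng.uniform(0.5, 2.0, 6)
        b = rng.uniform(10, 50, 6)
        panels = [sq.ConcentrationPanel(f"s{i}", {"B1": v}) for i, v in enumerate(b)]
        c = sq.fit_scale_coefficients(K, panels)["B1"]
        f = lambda x: float(np.sum((x * K - b) ** 2))
        oracle = minimize_scalar(f, bounds=(0, 200), method="bounded",
                                 options={"xatol": 1e-10}).x
        assert c == pytest.approx(oracle, abs=1e-6)
        assert f(c) <= f(oracle) + 1e-10
        # and beats any perturbation of itself (true quadratic minimum)
        assert f(c) <= min(f(c + 1e-7), f(c - 1e-7)) + 1e-10

    def test_all_zero_k_rejected(self):
        with pytest.raises(ModelError):
            sq.fit_scale_coefficients([0.0, 0.0], [
                sq.ConcentrationPanel("a", {"B1": 1.0}),
                sq.ConcentrationPanel("b", {"B1": 2.0}),
            ])


class TestBias:
    def test_recovers_published_delta(self):
        truth = np.array([131.0, 59.0, 4.2, 0.7, 1100.2])
        pred = truth / (1 - 0.054)
        assert sq.estimate_bias(pred, truth) == pytest.approx(0.054, abs=1e-12)

    def test_zero_for_perfect_predictions(self):
        t = np.array([1.0, 2.0, 3.0])
        assert sq.estimate_bias(t, t) == pytest.approx(0.0, abs=1e-15)

    def test_matches_grid_scan_oracle(self):
        rng = np.random.default_rng(11)
        truth = rng.uniform(1, 100, 20)
        pred = truth * rng.uniform(1.02, 1.08, 20)
        delta = sq.estimate_bias(pred, truth)
        fs = np.arange(0.5, 1.5, 1e-6)
        r = pred / truth
        obj = np.sum((fs[:, None] * r[None, :] - 1.0) ** 2, axis=1)
        f_star = fs[np.argmin(obj)]
        assert 1 - delta == pytest.approx(f_star, abs=2e-6)

    def test_empty_rejected(self):
        with pytest.raises(ModelError):
            sq.estimate_bias([], [])


class TestPredictAndScore:
    def test_reference_prediction_b1(self):
        """Shared K fitted to the published truth reproduces B1 = 131.0."""
        model = sq.reference_model()
        truth = sq.reference_validation().set_index("analyte")["test_true"]
        k_hat = fit_shared_composite_value(truth)
        b1 = model.coefficients["B1"] * k_hat * (1 - model.bias)
        assert b1 == pytest.approx(131.0, abs=0.1)

    def test_predictions_linear_in_k(self, calibrated):
        import warnings

        model, _, _ = calibrated
        feats = {f: 1.0 for f in model.composite.feature_ids()}
        feats2 = {f: 2.0 * v for f, v in feats.items()}
        k1 = sq.evaluate_composite(model.composite, feats)
        k2 = sq.evaluate_composite(model.composite, feats2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # far outside calibration range
            p1 = sq.predict_panel(model, feats)
            p2 = sq.predict_panel(model, feats2)
        for a in p1.values:
            assert p2.values[a] == pytest.approx(p1.values[a] * k2 / k1, rel=1e-9)

    def test_out_of_range_prediction_warns(self):
        model = sq.reference_model()
        # features pushing K far above the calibration range
        with pytest.warns(UserWarning, match="calibration range"):
            sq.predict_panel(
                model, {"H20": 10.0, "H49": 10.0, "S2": 1.0, "S42": 1.0, "S49": 1.0}
            )

    @pytest.mark.parametrize(
        "true,found,expected",
        [(131.00, 130.96, 0.03), (59.00, 58.95, 0.08), (193.80, 193.68, 0.06)],
    )
    def test_published_delta_pct_rows(self, true, found, expected):
        pred = sq.ConcentrationPanel("t", {"B1": found})
        truth = sq.ConcentrationPanel("t", {"B1": true})
        rep = sq.score_predictions(pred, truth)
        assert rep.table["delta_pct"].iloc[0] == expected

    def test_perfect_prediction_scores_zero(self):
        p = sq.ConcentrationPanel("t", {"B1": 5.0, "B2": 1.0})
        rep = sq.score_predictions(p, p)
        assert rep.max_delta_pct == 0.0

    def test_rounding_half_away_from_zero(self):
        assert _round_half_up(0.125) == 0.13
        assert _round_half_up(0.0749999) == 0.07


class TestSerialisation:
    def test_reference_model_round_trip(self, tmp_path):
        model = sq.reference_model()
        path = tmp_path / "model.json"
        sq.save_model(model, path)
        loaded = sq.load_model(path)
        assert loaded.coefficients == model.coefficients
        assert len(loaded.coefficients) == 38
        assert loaded.bias == model.bias
        assert loaded.composite.terms == model.composite.terms
        assert np.array_equal(loaded.composite.weights, model.composite.weights)
        assert loaded.composite.scale == model.composite.scale
        assert [a.id for a in loaded.panel.analytes] == [a.id for a in model.panel.analytes]

    def test_fitted_model_round_trip_bit_exact(self, calibrated, tmp_path):
        model, _, _ = calibrated
        path = tmp_path / "m.json"
        sq.save_model(model, path)
        loaded = sq.load_model(path)
        assert loaded.coefficients == model.coefficients
        assert loaded.bias == model.bias
        assert [
            (b.index, b.center, b.window_low, b.window_high) for b in loaded.bands
        ] == [(b.index, b.center, b.window_low, b.window_high) for b in model.bands]

    def test_zero_bias_round_trips(self, tmp_path):
        model = sq.reference_model()
        model.bias = 0.0
        sq.save_model(model, tmp_path / "m.json")
        assert sq.load_model(tmp_path / "m.json").bias == 0.0

    def test_missing_coefficient_rejected(self, tmp_path):
        model = sq.reference_model()
        import json

        path = tmp_path / "m.json"
        sq.save_model(model, path)
        d = json.loads(path.read_text())
        del d["coefficients"]["B38"]
        path.write_text(json.dumps(d))
        with pytest.raises(ModelError, match="B38"):
            sq.load_model(path)

    def test_corrupt_file_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ModelError):
            sq.load_model(p)


class TestReferenceConsistency:
    def test_implied_k_agrees_across_analytes(self):
        """One shared K generated all 38 published found values: the implied
        per-analyte K_i spread is dominated by 2-decimal table rounding."""
        ki = implied_composite_values("test_found")
        cv = float(ki.std(ddof=1) / ki.mean())
        assert len(ki) == 38
        assert cv < 0.005

    def test_single_k_reproduces_precise_truth_rows(self):
        """For analytes printed with >= 4 units, one fitted K predicts the
        true concentration to better than 0.1% relative error."""
        coefs = sq.reference_coefficients()
        truth = sq.reference_validation().set_index("analyte")["test_true"]
        k = fit_shared_composite_value(truth, min_true=4.0)
        sel = truth[truth >= 4.0]
        pred = np.array([coefs[a] * (1 - REFERENCE_DELTA) * k for a in sel.index])
        rel = np.abs(pred - sel.to_numpy()) / sel.to_numpy()
        assert rel.max() < 0.001
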