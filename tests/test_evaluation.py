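import math

import numpy as np
import pandas as pd
import pytest

import predaot as p
from predaot.cascade import CascadeModel
from predaot.chem import compute_ecfp4
from predaot.evaluation import compare_predictors, evaluate_cascade, per_category_rmse


class TestPerCategoryRmse:
    def test_zero_residuals(self):
        truth = np.array([3.0, 100.0, 4000.0])
        cats = np.array(["1", "3", "5"])
        out = per_category_rmse(truth, truth, cats)
        assert out == {"1": 0.0, "3": 0.0, "5": 0.0}

    def test_single_compound_residual(self):
        out = per_category_rmse([200.0], [100.0], ["3"])
        assert out["3"] == 100.0

    def test_two_residuals_hand_computed(self):
        # residuals 3 and 4 in one category -> sqrt((9+16)/2) = sqrt(12.5)
        out = per_category_rmse([13.0, 24.0], [10.0, 20.0], ["2", "2"])
        assert math.isclose(out["2"], math.sqrt(12.5), rel_tol=1e-12)

    def test_empty_categories_omitted(self):
        out = per_category_rmse([10.0], [12.0], ["2"])
        assert set(out) == {"2"}

    def test_four_row_worked_example(self):
        pred = np.array([4.0, 150.0, 500.0, 2500.0])
        truth = np.array([2.0, 100.0, 400.0, 3000.0])
        cats = np.array(["1", "3", "4", "5"])
        out = per_category_rmse(pred, truth, cats)
        assert out == {"1": 2.0, "3": 50.0, "4": 100.0, "5": 500.0}

    def test_pooled_equals_weighted_grouped_mse(self):
        rng = np.random.default_rng(0)
        truth = 10 ** rng.uniform(-1, 4, 500)
        pred = truth * 10 ** rng.normal(0, 0.3, 500)
        from predaot.labeling import ghs_categories
        cats = ghs_categories(truth)
        rmse = per_category_rmse(pred, truth, cats)
        counts = {c: int(np.sum(cats == c)) for c in rmse}
        weighted = sum(counts[c] * rmse[c] ** 2 for c in rmse) / 500
        pooled = float(np.mean((pred - truth) ** 2))
        assert math.isclose(weighted, pooled, rel_tol=1e-9)


def _oracle_model(records, n_bits=256):
    """A cascade stub that predicts every record's true values exactly."""
    score_by_fp, log_by_fp = {}, {}
    for r in records:
        key = compute_ecfp4(r.smiles_canonical, n_bits).astype(np.float64).tobytes()
        score_by_fp[key] = 1.0 if r.ld50_mg_per_kg <= 300 else 0.0
        log_by_fp[key] = r.log_ld50

    class Cls:
        def predict_proba(self, X):
            s = np.array([score_by_fp[row.tobytes()] for row in X])
            return np.column_stack([1 - s, s])

    class Reg:
        def predict(self, X):
            return np.array([log_by_fp[row.tobytes()] for row in X])

    return CascadeModel(species="mouse", classifier=Cls(), toxic_regressor=Reg(),
                        nontoxic_regressor=Reg(), n_bits=n_bits)


@pytest.fixture(scope="module")
def oracle_setup():
    records = p.generate_fixture(p.FixtureSpec(n_compounds=130, noise_sd=0.3, seed=31, n_bits=256))
    # distinct molecules can share a bit *set* (e.g. unbranched chains of
    # length >= 5 have identical circular environments); keep one per
    # fingerprint so the lookup oracle is well defined
    seen, unique = set(), []
    for r in records:
        key = compute_ecfp4(r.smiles_canonical, 256).tobytes()
        if key not in seen:
            seen.add(key)
            unique.append(r)
    return _oracle_model(unique), unique


class TestEvaluateCascade:
    def test_perfect_oracle_scores_perfectly(self, oracle_setup):
        model, records = oracle_setup
        report = evaluate_cascade(model, records)
        cm = report.classifier_metrics
        assert cm.acc == 1.0 and cm.auroc == 1.0 and cm.mcc == 1.0
        for regimes in report.regressor_metrics.values():
            for m in regimes.values():
                if m.n:
                    assert m.rmse == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in report.per_category_rmse_mg_per_kg.values())
        assert report.correlations == pytest.approx((1.0, 1.0))

    def test_train_test_overlap_is_hard_error(self, trained_cascade):
        model, train, _ = trained_cascade
        with pytest.raises(ValueError, match="overlap"):
            evaluate_cascade(model, train[:20])

    def test_category_counts_sum_to_test_size(self, trained_cascade):
        model, _, test = trained_cascade
        report = evaluate_cascade(model, test)
        assert sum(report.per_category_counts.values()) == report.n_test == len(test)
        assert report.binary_counts["toxic"] + report.binary_counts["less_or_non_toxic"] == len(test)

    def test_report_serializes_and_prints(self, trained_cascade):
        import json
        model, _, test = trained_cascade
        report = evaluate_cascade(model, test)
        d = json.loads(json.dumps(report.to_dict()))
        assert d["species"] == "mouse"
        text = report.to_text()
        assert "Per-GHS-category RMSE" in text and "AUROC" in text


class TestComparePredictors:
    def test_external_equal_to_own_gives_identical_rows(self, oracle_setup):
        model, records = oracle_setup
        report = evaluate_cascade(model, records)
        ext = pd.DataFrame({"id": [str(i) for i in report.ids],
                            "prediction": 10.0 ** report.pred_log})
        table = compare_predictors(report, ext, name="clone", mg_per_kg_scale=True)
        corr = table[table.scope == "correlation"].set_index("predictor")
        assert corr.loc["predaot", "pearson_r"] == pytest.approx(corr.loc["clone", "pearson_r"])
        rmse_rows = table[table.scope.str.contains("rmse")]
        for scope, grp in rmse_rows.groupby("scope"):
            vals = grp["rmse"].to_numpy()
            assert vals[0] == pytest.approx(vals[-1])

    def test_monotone_scale_suppresses_rmse(self, oracle_setup):
        model, records = oracle_setup
        report = evaluate_cascade(model, records)
        # external predictor on an arbitrary monotone scale (not mg/kg)
        ext = pd.DataFrame({"id": [str(i) for i in report.ids],
                            "prediction": np.exp(report.pred_log)})
        table = compare_predictors(report, ext, mg_per_kg_scale=False)
        assert not table.scope.str.contains("rmse").any()
        ext_row = table[table.predictor == "external"].iloc[0]
        assert ext_row["spearman_r"] == pytest.approx(1.0)

    def test_mismatched_ids_excluded_with_warning(self, oracle_setup, caplog):
        model, records = oracle_setup
        report = evaluate_cascade(model, records)
        ext = pd.DataFrame({"id": [str(i) for i in report.ids[:50]] + ["ghost1", "ghost2"],
                            "prediction": list(10.0 ** report.pred_log[:50]) + [1.0, 2.0]})
        with caplog.at_level("WARNING"):
            table = compare_predictors(report, ext, mg_per_kg_scale=False)
        assert any("excluded" in m for m in caplog.messages)
        assert len(table) == 2

    def test_correlations_delegate_to_learners_functions(self, oracle_setup):
        model, records = oracle_setup
        report = evaluate_cascade(model, records[:3])
        ext = pd.DataFrame({"id": [str(i) for i in report.ids],
                            "prediction": [1.0, 5.0, 2.0]})
        table = compare_predictors(report, ext)
        expected = p.rank_correlations(np.array([1.0, 5.0, 2.0]), report.truth_log)
        ext_row = table[table.predictor == "external"].iloc[0]
        assert ext_row["pearson_r"] == pytest.approx(expected[0])
        assert ext_row["spearman_r"] == pytest.approx(expected[1])
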