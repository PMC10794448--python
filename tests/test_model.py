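"""Cross-validation protocol, feature handling, metrics and post-hoc indices."""

import numpy as np
import pandas as pd
import pytest

from plaquetrend.errors import ConfigError, DataError
from plaquetrend.model import (
    ExperimentConfig,
    evaluate,
    make_folds,
    metrics_table,
    one_hot,
    posthoc_indices,
    run_experiment,
    select_k_best,
    shap_report,
    standardize,
    train_regressor,
)


def _groups(n=40, pos_frac=0.4, seed=0):
    rng = np.random.default_rng(seed)
    groups = np.array([f"PB{i:03d}" for i in range(n)])
    signs = (rng.random(n) < pos_frac).astype(int)
    return groups, signs


class TestFolds:
    def test_counts_and_coverage(self):
        groups, signs = _groups()
        cfg = ExperimentConfig(seed=1)
        folds = make_folds(groups, signs, cfg)
        assert len(folds) == 100  # 5 folds x 20 repeats
        appearances = {g: 0 for g in groups}
        for f in folds:
            for g in f.test_groups:
                appearances[g] += 1
        assert set(appearances.values()) == {20}

    def test_partition_within_repeat(self):
        groups, signs = _groups()
        folds = make_folds(groups, signs, ExperimentConfig(seed=2, n_repeats=1))
        seen = []
        for f in folds:
            assert not set(f.train_groups) & set(f.test_groups)
            seen.extend(f.test_groups)
        assert sorted(seen) == sorted(groups)

    def test_stratification_within_one(self):
        groups, signs = _groups()
        lookup = dict(zip(groups, signs))
        cfg = ExperimentConfig(seed=3)
        for f in make_folds(groups, signs, cfg):
            pos = sum(lookup[g] for g in f.test_groups)
            expected = signs.sum() / cfg.n_folds
            assert abs(pos - expected) <= 1.0

    def test_deterministic(self):
        groups, signs = _groups()
        a = make_folds(groups, signs, ExperimentConfig(seed=7))
        b = make_folds(groups, signs, ExperimentConfig(seed=7))
        assert a == b

    def test_too_few_groups(self):
        with pytest.raises(ConfigError):
            make_folds(["a", "b"], [0, 1], ExperimentConfig(seed=0))


class TestStandardize:
    def test_population_std(self):
        t, a, _ = standardize(np.array([[1.0], [2.0], [3.0]]), np.array([[2.0]]))
        np.testing.assert_allclose(t[:, 0], [-1.224744871, 0.0, 1.224744871], rtol=1e-8)
        assert a[0, 0] == 0.0  # test row equal to the train mean

    def test_zero_variance_guard(self):
        t, a, _ = standardize(np.full((4, 1), 3.0), np.array([[5.0]]))
        assert np.all(t == 0.0) and np.all(a == 0.0)

    def test_passthrough_columns_untouched(self):
        X = np.array([[1.0, 1.0], [3.0, 0.0]])
        t, _, _ = standardize(X, X, passthrough=[False, True])
        np.testing.assert_allclose(t[:, 1], X[:, 1])
        assert t[:, 0].mean() == pytest.approx(0.0)

    def test_train_only_parameters(self):
        # negative leakage control: refitting on train+test changes parameters
        rng = np.random.default_rng(0)
        tr, te = rng.normal(size=(50, 3)), rng.normal(loc=2.0, size=(20, 3))
        _, _, (mean_tr, _) = standardize(tr, te)
        _, _, (mean_all, _) = standardize(np.vstack([tr, te]), te)
        assert not np.allclose(mean_tr, mean_all)


class TestSelection:
    def test_label_copy_always_selected(self):
        rng = np.random.default_rng(1)
        y = (rng.random(300) < 0.5).astype(int)
        X = np.column_stack([rng.normal(size=(300, 6)), y.astype(float)])
        sel = select_k_best(X, y, 3, seed=0)
        assert 6 in sel

    def test_k_equals_all(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 5))
        y = (rng.random(50) < 0.5).astype(int)
        assert list(select_k_best(X, y, 5)) == [0, 1, 2, 3, 4]

    def test_invalid_k(self):
        with pytest.raises(ConfigError):
            select_k_best(np.zeros((10, 3)), np.zeros(10, int), 0)

    def test_planted_informative_features_recovered(self):
        # 5 informative + 50 noise features: >=4/5 recovered in >=95% of runs
        hits = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            n = 2000
            informative = rng.normal(size=(n, 5))
            logits = informative.sum(axis=1)
            y = (logits + 0.5 * rng.normal(size=n) > 0).astype(int)
            X = np.column_stack([informative, rng.normal(size=(n, 50))])
            sel = select_k_best(X, y, 8, seed=seed)
            if np.isin(np.arange(5), sel).sum() >= 4:
                hits += 1
        assert hits >= int(0.95 * runs)


class TestRegressor:
    CFG = ExperimentConfig(seed=0)

    def test_near_interpolation_on_distinct_rows(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50) * 5
        model = train_regressor(X, y, self.CFG, seed=0)
        assert np.mean(np.abs(model.predict(X) - y)) < 0.1

    def test_constant_target(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        model = train_regressor(X, np.full(30, 2.5), self.CFG, seed=0)
        np.testing.assert_allclose(model.predict(X), 2.5, atol=1e-5)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 6))
        y = rng.normal(size=80)
        p1 = train_regressor(X, y, self.CFG, seed=9).predict(X)
        p2 = train_regressor(X, y, self.CFG, seed=9).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            train_regressor(np.zeros((0, 3)), np.zeros(0), self.CFG, seed=0)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([-2.0, -1.0, 1.0, 3.0])
        m = evaluate(y, y)
        assert m["MAE"] == 0 and m["MSE"] == 0
        assert m["ACC"] == 1 and m["MCC"] == 1
        assert m["F1neg"] == m["F1pos"] == m["F1a"] == 1

    def test_hand_confusion_matrix(self):
        # TP=2, FP=1, FN=1, TN=3 -> ACC=5/7, MCC=5/12
        y_true = np.array([1, 1, 1, -1, -1, -1, -1], float)
        y_pred = np.array([1, 1, -1, 1, -1, -1, -1], float)
        m = evaluate(y_pred, y_true)
        assert m["ACC"] == pytest.approx(5 / 7)
        assert m["MCC"] == pytest.approx(5 / 12)

    def test_single_class_truth_guard(self):
        m = evaluate(np.array([1.0, -1.0]), np.array([-1.0, -2.0]))
        assert m["MCC"] == 0.0
        assert m["ACC"] == 0.5

    def test_degenerate_r_guard(self):
        m = evaluate(np.full(5, 1.0), np.arange(5, dtype=float))
        assert m["r"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            evaluate([], [])


def _toy_dataset(n_pullbacks=12, rois_per_pb=6, seed=0):
    """ROI-level dataset with signal: dpav driven by one feature."""
    rng = np.random.default_rng(seed)
    rows, meta = [], []
    for p in range(n_pullbacks):
        pb_id = f"PB{p:02d}"
        pb_dpav = 0.0
        for r in range(rois_per_pb):
            driver = rng.normal()
            dpav = 4.0 * driver + rng.normal() * 0.5
            pb_dpav += dpav
            rows.append(
                {"f0": driver, "f1": rng.normal(), "f2": rng.normal(),
                 "artery": rng.choice(["LAD", "LCx", "RCA"])}
            )
            meta.append(
                {"pullback_id": pb_id, "patient_id": f"P{p // 2:02d}",
                 "dpav": dpav, "length_mm": 1.0 + r * 0.5, "pullback_dpav": 0.0}
            )
        for k in range(rois_per_pb):
            meta[-1 - k]["pullback_dpav"] = pb_dpav
    return pd.DataFrame(rows), pd.DataFrame(meta)


class TestExperiment:
    CFG = ExperimentConfig(seed=5, n_folds=3, n_repeats=4, n_estimators=64, max_depth=4)

    def test_group_integrity_and_signal_recovery(self):
        feats, meta = _toy_dataset()
        result = run_experiment(feats, meta, self.CFG)
        assert result.n_models == 12
        pullbacks = meta["pullback_id"].to_numpy()
        for m in result.models:
            test_pbs = set(pullbacks[m.test_index])
            train_pbs = set(pullbacks) - test_pbs
            assert not test_pbs & train_pbs
        mean_mcc = np.mean([m.metrics["MCC"] for m in result.models])
        assert mean_mcc > 0.8  # strong planted signal

    def test_posthoc_ccr_ccl(self):
        feats, meta = _toy_dataset()
        result = run_experiment(feats, meta, self.CFG)
        roi_df, pb_df = posthoc_indices(result, meta)
        assert len(roi_df) == len(meta)
        assert roi_df["ccr"].between(0, 1).all()
        assert pb_df["ccl_mean"].between(0, 1).all()
        assert (pb_df["n_test_models"] == self.CFG.n_repeats).all()

    def test_ccl_length_weighting(self):
        # one pullback, ROIs of 1 mm and 3 mm, only the long one correct
        meta = pd.DataFrame(
            {"pullback_id": ["p", "p"], "length_mm": [1.0, 3.0]}
        )
        from plaquetrend.model import ModelRecord, ExperimentResult

        rec = ModelRecord(
            repeat_id=0, fold_id=0, test_index=np.array([0, 1]),
            y_true=np.array([1.0, 1.0]), y_pred=np.array([-1.0, 2.0]),
            metrics={}, selected=np.array([]), mean_abs_shap=None,
        )
        result = ExperimentResult(
            config=ExperimentConfig(seed=0, n_repeats=1), feature_columns=[], models=[rec]
        )
        roi_df, pb_df = posthoc_indices(result, meta)
        assert pb_df["ccl_mean"].iloc[0] == pytest.approx(0.75)
        assert list(roi_df["ccr"]) == [0.0, 1.0]

    def test_shap_report_weighting(self):
        feats, meta = _toy_dataset()
        cfg = ExperimentConfig(seed=6, n_folds=3, n_repeats=2, n_estimators=32,
                               max_depth=3, k_select=2)
        result = run_experiment(feats, meta, cfg)
        report = shap_report(result)
        never = report[report["selection_count"] == 0]
        assert (never["weighted_shap"] == 0).all()
        top = report.iloc[0]
        assert top["feature"] == "f0"  # the planted driver dominates
        assert top["selection_count"] == result.n_models

    def test_metrics_table_layout(self):
        feats, meta = _toy_dataset()
        result = run_experiment(feats, meta, self.CFG)
        table = metrics_table(result)
        assert list(table.columns) == ["metric", "mean", "std", "min", "max"]
        assert (table["min"] <= table["mean"]).all() and (table["mean"] <= table["max"]).all()

    def test_one_hot_exempt_from_standardization(self):
        feats, meta = _toy_dataset()
        X = one_hot(feats)
        onehot_cols = [c for c in X.columns if c.startswith("artery_")]
        assert onehot_cols and set(np.unique(X[onehot_cols])) <= {0.0, 1.0}
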