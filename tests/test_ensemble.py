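"""Splitting, cross-validation, RFE, tuning, and the 5x5 ensemble."""

import numpy as np
import pandas as pd
import pytest

from delpath.ensemble import (
    DeletionEnsembleClassifier,
    cross_validate,
    make_learner,
    make_split,
    protein_class,
    protein_labels_from_table,
    rfe_select,
    tune_hyperparams,
)
from delpath.simulate import simulate_feature_table


@pytest.fixture(scope="module")
def separable_table():
    return simulate_feature_table(
        n_rows=600, n_features=15, n_informative=5, effect=2.5, seed=21
    )


@pytest.fixture(scope="module")
def null_table():
    return simulate_feature_table(
        n_rows=600, n_features=15, n_informative=0, effect=0.0, seed=22
    )


def _plan(table, seed=0):
    return make_split(protein_labels_from_table(table), seed=seed)


class TestProteinClass:
    def test_majority_and_tie(self):
        assert protein_class(["benign", "benign", "pathogenic"]) == "benign"
        assert protein_class(["benign", "pathogenic"]) == "pathogenic"  # tie


class TestMakeSplit:
    def test_disjoint_and_deterministic(self, separable_table):
        plan1 = _plan(separable_table, seed=5)
        plan2 = _plan(separable_table, seed=5)
        assert not (plan1.train_proteins & plan1.test_proteins)
        assert plan1.train_proteins == plan2.train_proteins
        assert plan1.cv_folds == plan2.cv_folds

    def test_folds_partition_training_proteins(self, separable_table):
        plan = _plan(separable_table)
        union = set().union(*plan.cv_folds)
        assert union == set(plan.train_proteins)
        for i, a in enumerate(plan.cv_folds):
            for b in plan.cv_folds[i + 1 :]:
                assert not (a & b)

    def test_stratification_preserves_class_fraction(self, separable_table):
        labels = separable_table.data["label"]
        overall = (labels == "pathogenic").mean()
        plan = _plan(separable_table, seed=3)
        for side in (plan.train_proteins, plan.test_proteins):
            ids = [v for v in labels.index if v.rsplit(":", 1)[0] in side]
            frac = (labels.loc[ids] == "pathogenic").mean()
            assert abs(frac - overall) <= 0.05

    def test_test_size_near_requested_fraction(self, separable_table):
        plan = _plan(separable_table)
        n_test = len(plan.test_proteins)
        assert abs(n_test - 0.2 * 600) <= 10

    def test_too_few_proteins_to_stratify(self):
        with pytest.raises(ValueError, match="too few"):
            make_split({"P1": "pathogenic", "P2": "benign", "P3": "benign"})


class TestCrossValidate:
    def test_separable_data_near_perfect(self, separable_table):
        cv = cross_validate("lightgbm", separable_table, _plan(separable_table))
        assert cv.mean_report.accuracy >= 0.95
        assert cv.mean_auc >= 0.99

    def test_label_permutation_null_mcc(self, null_table):
        cv = cross_validate("lightgbm", null_table, _plan(null_table))
        assert abs(cv.mean_report.MCC) < 0.15

    def test_fold_counts_conserve_totals(self, separable_table):
        plan = _plan(separable_table)
        cv = cross_validate("lightgbm", separable_table, plan)
        train_rows = sum(
            1 for v in separable_table.data.index
            if v.rsplit(":", 1)[0] in plan.train_proteins
        )
        fold_total = sum(r.counts.total for r in cv.fold_reports)
        assert fold_total == train_rows
        assert cv.mean_counts.total == pytest.approx(fold_total / len(cv.fold_reports))

    @pytest.mark.parametrize("spec", ["logistic", "rf", "svm"])
    def test_baseline_learners_run(self, separable_table, spec):
        cv = cross_validate(spec, separable_table, _plan(separable_table))
        assert cv.mean_auc > 0.9  # strongly separable data


class TestRFE:
    def test_planted_signal_recovery(self, separable_table):
        result = rfe_select(
            "lightgbm", separable_table, _plan(separable_table), sizes=[5, 10, 15]
        )
        informative = {f"inf_{i:02d}" for i in range(5)}
        assert result.size <= 20
        recall = len(informative & set(result.features)) / 5
        assert recall >= 0.8

    def test_zero_tolerance_takes_argmax(self, separable_table):
        result = rfe_select(
            "lightgbm", separable_table, _plan(separable_table),
            sizes=[5, 10, 15], tolerance=0.0,
        )
        best = max(result.size_scores.values())
        assert result.size_scores[result.size] == best

    def test_oversized_requests_truncated(self, separable_table):
        result = rfe_select(
            "lightgbm", separable_table, _plan(separable_table), sizes=[10, 500]
        )
        assert max(result.size_scores) == 15  # table only has 15 features

    def test_deterministic(self, separable_table):
        a = rfe_select("lightgbm", separable_table, _plan(separable_table), sizes=[5, 10])
        b = rfe_select("lightgbm", separable_table, _plan(separable_table), sizes=[5, 10])
        assert a.features == b.features and a.size_scores == b.size_scores


class TestTuning:
    def test_single_trial_returns_that_trial(self, separable_table):
        result = tune_hyperparams(
            "lightgbm", separable_table, _plan(separable_table), n_trials=1, seed=9
        )
        assert len(result.trials) == 1
        assert result.best_params == result.trials[0]["params"]

    def test_incumbent_auc_non_decreasing(self, separable_table):
        result = tune_hyperparams(
            "lightgbm", separable_table, _plan(separable_table), n_trials=5, seed=9
        )
        best = [t["best_auc"] for t in result.trials]
        assert best == sorted(best)

    def test_tuning_gain_marginal_on_separable_data(self, separable_table):
        plan = _plan(separable_table)
        default_auc = cross_validate("lightgbm", separable_table, plan).mean_auc
        tuned = tune_hyperparams(
            "lightgbm", separable_table, plan, n_trials=5, seed=9
        )
        assert abs(tuned.best_auc - default_auc) < 0.01


@pytest.fixture(scope="module")
def fitted(separable_table):
    X = separable_table.data.drop(columns="label")
    est = DeletionEnsembleClassifier(
        n_splits=5, n_folds=5, B=200, random_state=1,
        learner_params={"n_estimators": 50},
    )
    est.fit(X, separable_table.data["label"])
    return est, X


class TestEnsemble:
    def test_bundle_has_25_models_sharing_features(self, fitted):
        est, X = fitted
        assert len(est.models_) == 25
        assert est.feature_names_ == list(X.columns)

    def test_retrain_reproduces_predictions(self, fitted, separable_table):
        est, X = fitted
        probe = X.iloc[:20]
        est2 = DeletionEnsembleClassifier(
            n_splits=5, n_folds=5, B=200, random_state=1,
            learner_params={"n_estimators": 50},
        )
        est2.fit(X, separable_table.data["label"])
        np.testing.assert_array_equal(
            est.prob_matrix(probe), est2.prob_matrix(probe)
        )

    def test_predict_proba_layout_and_threshold(self, fitted):
        est, X = fitted
        proba = est.predict_proba(X.iloc[:10])
        assert proba.shape == (10, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        calls = est.predict(X.iloc[:10])
        expected = np.where(proba[:, 1] > 0.5, "pathogenic", "benign")
        np.testing.assert_array_equal(calls, expected)

    def test_missing_feature_errors_by_name(self, fitted):
        est, X = fitted
        with pytest.raises(ValueError, match="inf_00"):
            est.predict(X.drop(columns=["inf_00"]).iloc[:5])

    def test_save_load_round_trip(self, fitted, tmp_path):
        est, X = fitted
        est.save(tmp_path / "bundle")
        assert (tmp_path / "bundle" / "manifest.json").exists()
        loaded = DeletionEnsembleClassifier.load(tmp_path / "bundle")
        np.testing.assert_array_equal(
            est.prob_matrix(X.iloc[:10]), loaded.prob_matrix(X.iloc[:10])
        )

    def test_tristate_predictions_carry_25_probs(self, fitted):
        est, X = fitted
        preds = est.predict_tristate(X.iloc[:5], B=200)
        assert all(len(p.probs) == 25 for p in preds)
        for p in preds:
            assert p.mean_prob == pytest.approx(np.mean(p.probs))


class TestMinMaxScalingForNonTreeLearners:
    def test_pipeline_wrapping(self):
        from sklearn.pipeline import Pipeline

        assert isinstance(make_learner("logistic"), Pipeline)
        assert isinstance(make_learner("svm"), Pipeline)
        assert not isinstance(make_learner("lightgbm"), Pipeline)
        assert not isinstance(make_learner("rf"), Pipeline)
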