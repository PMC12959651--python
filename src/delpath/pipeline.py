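"""End-to-end training and blind-test evaluation.

Chains the stages in leakage-safe order on a feature table:

1. hold out a protein-disjoint blind-test partition;
2. fit the redundancy filter on training rows, replay on the rest;
3. rank features by recursive elimination and pick the smallest
   well-performing size by cross-validated AUC;
4. random-search hyperparameters by cross-validated AUC;
5. train the split/fold ensemble on the training partition;
6. issue binary and three-state calls on the blind test and evaluate.

Every learnt component (filter drop list, feature subset, hyperparameters,
fold models) sees training-partition rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from delpath.ensemble import (
    CVResult,
    DeletionEnsembleClassifier,
    RFEResult,
    SplitPlan,
    TuningResult,
    _rows_for_proteins,
    make_split,
    protein_labels_from_table,
)
from delpath.features import FeatureTable
from delpath.filtering import SpearmanRedundancyFilter, filter_table
from delpath.metrics import MetricsReport, evaluate_tristate
from delpath.tristate import TriStatePrediction


@dataclass
class PipelineResult:
    """Everything one end-to-end run produces."""

    blind_split: SplitPlan
    filter: SpearmanRedundancyFilter
    rfe: RFEResult
    tuning: TuningResult | None
    model: DeletionEnsembleClassifier
    predictions: list[TriStatePrediction]
    binary_report: MetricsReport
    tristate_report: MetricsReport
    test_index: list[str] = field(default_factory=list)


def run_pipeline(
    table: FeatureTable,
    learner: str = "lightgbm",
    test_frac: float = 0.2,
    n_splits: int = 5,
    n_folds: int = 5,
    rfe_sizes=None,
    rfe_tolerance: float = 0.005,
    n_trials: int = 100,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
) -> PipelineResult:
    """Run the full pipeline and evaluate on the held-out blind test."""
    protein_labels = protein_labels_from_table(table)
    blind = make_split(
        protein_labels, test_frac=test_frac, n_folds=n_folds, seed=seed, split_id=-1
    )
    train_rows = _rows_for_proteins(table, blind.train_proteins)
    test_rows = _rows_for_proteins(table, blind.test_proteins)

    # filter: fit on training rows only, replay everywhere
    train_table = FeatureTable(
        data=table.data.loc[train_rows],
        categories=table.categories,
        kinds=table.kinds,
        segments=None,
        excluded=[],
    )
    filtered_train, filt = filter_table(train_table)

    # feature refinement + hyperparameter search, cross-validated inside
    # the training partition (the blind split's folds partition it)
    from delpath.ensemble import rfe_select, tune_hyperparams

    rfe = rfe_select(
        learner,
        filtered_train,
        blind,
        sizes=rfe_sizes,
        tolerance=rfe_tolerance,
        random_state=seed,
    )
    tuning = None
    params = None
    if n_trials > 0:
        tuning = tune_hyperparams(
            learner,
            filtered_train,
            blind,
            n_trials=n_trials,
            seed=seed,
            feature_names=rfe.features,
        )
        params = tuning.best_params

    model = DeletionEnsembleClassifier(
        learner=learner,
        learner_params=params,
        n_splits=n_splits,
        n_folds=n_folds,
        test_frac=test_frac,
        alpha=alpha,
        B=B,
        random_state=seed,
    )
    X_train = table.data.loc[train_rows, rfe.features]
    model.fit(X_train, table.data.loc[train_rows, "label"])

    X_test = table.data.loc[test_rows, rfe.features]
    labels = list(table.data.loc[test_rows, "label"])
    preds = model.predict_tristate(X_test)
    mean_probs = [p.mean_prob for p in preds]
    binary_calls = ["pathogenic" if p > 0.5 else "benign" for p in mean_probs]
    tri_calls = [p.call for p in preds]

    binary_report = evaluate_tristate(labels, binary_calls, scores=mean_probs)
    tristate_report = evaluate_tristate(labels, tri_calls, scores=mean_probs)
    return PipelineResult(
        blind_split=blind,
        filter=filt,
        rfe=rfe,
        tuning=tuning,
        model=model,
        predictions=preds,
        binary_report=binary_report,
        tristate_report=tristate_report,
        test_index=list(test_rows),
    )
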