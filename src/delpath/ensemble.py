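"""Protein-disjoint training: splits, cross-validation, feature refinement,
hyperparameter search, and the 5×5 split/fold ensemble.

Evaluation honesty rests on protein-disjoint partitioning: a protein's
variants share sequence context, so variants of one protein must never
appear on both sides of a train/test boundary.  Splits are stratified on a
protein-level class (the majority label over the protein's variants, ties
resolved to pathogenic) and cross-validation folds are protein-disjoint as
well.

The headline estimator is :class:`DeletionEnsembleClassifier`: it draws
``n_splits`` independent train–test partitions, trains one model per
cross-validation fold of each partition (25 models for the default 5×5),
and predicts with the mean probability.  The per-model probability spread
feeds the bootstrap three-state classification in
:mod:`delpath.tristate`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterSampler
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from delpath.features import FeatureTable
from delpath.metrics import ConfusionCounts, MetricsReport, auc, confusion, metrics
from delpath.tristate import TriStatePrediction, tristate_calls

POSITIVE = "pathogenic"

# LightGBM autogenerates "Column_i" names for array input, which trips
# sklearn's name check on every array predict; the check is vacuous here
# because all fits and predicts go through the same column order.
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names", category=UserWarning
)


# ---------------------------------------------------------------------------
# learners


def make_learner(spec: str, params: Mapping | None = None, random_state: int = 0):
    """Instantiate a binary classifier by name.

    ``lightgbm`` is the production learner; ``logistic`` (balanced class
    weights), ``rf`` (100 trees) and ``svm`` (linear kernel, probability
    estimates) are framework-comparison baselines.  Non-tree learners get
    MinMax feature scaling in a pipeline.
    """
    params = dict(params or {})
    if spec == "lightgbm":
        from lightgbm import LGBMClassifier

        defaults = dict(
            n_estimators=100, random_state=random_state, n_jobs=1,
            verbose=-1, deterministic=True, force_row_wise=True,
        )
        defaults.update(params)
        return LGBMClassifier(**defaults)
    if spec == "logistic":
        return Pipeline(
            [
                ("scale", MinMaxScaler()),
                ("clf", LogisticRegression(
                    class_weight="balanced", max_iter=2000,
                    random_state=random_state, **params,
                )),
            ]
        )
    if spec == "rf":
        defaults = dict(n_estimators=100, random_state=random_state, n_jobs=1)
        defaults.update(params)
        return RandomForestClassifier(**defaults)
    if spec == "svm":
        return Pipeline(
            [
                ("scale", MinMaxScaler()),
                ("clf", SVC(kernel="linear", probability=True,
                            random_state=random_state, **params)),
            ]
        )
    raise ValueError(f"unknown learner spec {spec!r}")


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitPlan:
    """One protein-disjoint train/test partition with CV fold groups."""

    split_id: int
    train_proteins: frozenset[str]
    test_proteins: frozenset[str]
    cv_folds: list[frozenset[str]]
    seed: int

    def __post_init__(self) -> None:
        if self.train_proteins & self.test_proteins:
            raise ValueError("train and test protein sets overlap")
        covered: set[str] = set()
        for fold in self.cv_folds:
            if fold & covered:
                raise ValueError("CV fold protein groups overlap")
            covered |= fold
        if covered != set(self.train_proteins):
            raise ValueError("CV folds must partition the training proteins")


def protein_class(labels: Sequence[str]) -> str:
    """Majority label of a protein's variants; ties go to pathogenic."""
    n_path = sum(lab == POSITIVE for lab in labels)
    return POSITIVE if n_path >= len(labels) - n_path else "benign"


def _variant_protein(variant_id: str) -> str:
    return variant_id.rsplit(":", 1)[0]


def make_split(
    protein_labels: Mapping[str, str],
    test_frac: float = 0.2,
    n_folds: int = 5,
    seed: int = 0,
    split_id: int = 0,
) -> SplitPlan:
    """Stratified protein-disjoint train/test split with CV folds.

    *protein_labels* maps protein id → protein-level class.  Proteins are
    shuffled within each class and a ``test_frac`` share of each class goes
    to the test side, so variant-level class proportions stay close to the
    overall proportions.  The training proteins of each class are dealt
    round-robin into ``n_folds`` protein-disjoint fold groups.
    """
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    by_class: dict[str, list[str]] = {}
    for pid, cls in sorted(protein_labels.items()):
        by_class.setdefault(cls, []).append(pid)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(by_class):
        members = by_class[cls]
        if len(members) < max(2, n_folds):
            raise ValueError(
                f"class {cls!r} has only {len(members)} proteins; "
                "too few to stratify"
            )
        order = list(rng.permutation(members))
        n_test = max(1, round(test_frac * len(order)))
        test.extend(order[:n_test])
        train.extend(order[n_test:])
    # deal training proteins of each class round-robin into folds
    folds: list[set[str]] = [set() for _ in range(n_folds)]
    train_set = set(train)
    cursor = 0
    for cls in sorted(by_class):
        for pid in by_class[cls]:
            if pid in train_set:
                folds[cursor % n_folds].add(pid)
                cursor += 1
    return SplitPlan(
        split_id=split_id,
        train_proteins=frozenset(train),
        test_proteins=frozenset(test),
        cv_folds=[frozenset(f) for f in folds],
        seed=seed,
    )


def protein_labels_from_table(table: FeatureTable) -> dict[str, str]:
    """Protein-level class map from a feature table's variant ids/labels."""
    per_protein: dict[str, list[str]] = {}
    for vid, label in table.data["label"].items():
        per_protein.setdefault(_variant_protein(vid), []).append(label)
    return {pid: protein_class(labs) for pid, labs in per_protein.items()}


def _rows_for_proteins(table: FeatureTable, proteins: frozenset[str] | set[str]) -> pd.Index:
    mask = [(_variant_protein(vid) in proteins) for vid in table.data.index]
    return table.data.index[mask]


def split_table(table: FeatureTable, plan: SplitPlan) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(train, test) row subsets of a table under a split plan."""
    return (
        table.data.loc[_rows_for_proteins(table, plan.train_proteins)],
        table.data.loc[_rows_for_proteins(table, plan.test_proteins)],
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    """Per-fold metric reports plus the fold-averaged confusion summary."""

    fold_reports: list[MetricsReport]
    mean_counts: ConfusionCounts
    mean_report: MetricsReport
    mean_auc: float


def _xy(df: pd.DataFrame, feature_names: Sequence[str] | None = None):
    features = [c for c in df.columns if c != "label"]
    if feature_names is not None:
        features = list(feature_names)
    X = df[features].to_numpy(dtype=float)
    y = (df["label"] == POSITIVE).astype(int).to_numpy()
    return X, y


def cross_validate(
    learner_spec,
    table: FeatureTable,
    plan: SplitPlan,
    feature_names: Sequence[str] | None = None,
    random_state: int = 0,
) -> CVResult:
    """5-fold protein-disjoint cross-validation on a split's training side.

    *learner_spec* is a learner name (see :func:`make_learner`) or an
    unfitted estimator to clone.  Reports per-fold metrics and the
    fold-averaged (fractional) confusion counts.
    """
    train_df = table.data.loc[_rows_for_proteins(table, plan.train_proteins)]
    reports: list[MetricsReport] = []
    aucs: list[float] = []
    for fold_proteins in plan.cv_folds:
        val_idx = [vid for vid in train_df.index if _variant_protein(vid) in fold_proteins]
        fit_idx = [vid for vid in train_df.index if vid not in set(val_idx)]
        fit_df, val_df = train_df.loc[fit_idx], train_df.loc[val_idx]
        for name, df in (("training", fit_df), ("validation", val_df)):
            if df["label"].nunique() < 2:
                raise ValueError(f"a CV fold has a single class in its {name} part")
        model = (
            make_learner(learner_spec, random_state=random_state)
            if isinstance(learner_spec, str)
            else clone(learner_spec)
        )
        X_fit, y_fit = _xy(fit_df, feature_names)
        X_val, y_val = _xy(val_df, feature_names)
        model.fit(X_fit, y_fit)
        prob = model.predict_proba(X_val)[:, 1]
        calls = [POSITIVE if p > 0.5 else "benign" for p in prob]
        labels = list(val_df["label"])
        fold_auc = auc(labels, prob)
        reports.append(
            metrics(confusion(labels, calls), auc_value=fold_auc, normalise=False)
        )
        aucs.append(fold_auc)
    mean_counts = ConfusionCounts(
        TP=float(np.mean([r.counts.TP for r in reports])),
        TN=float(np.mean([r.counts.TN for r in reports])),
        FP=float(np.mean([r.counts.FP for r in reports])),
        FN=float(np.mean([r.counts.FN for r in reports])),
    )
    mean_auc = float(np.mean(aucs))
    return CVResult(reports, mean_counts, metrics(mean_counts, auc_value=mean_auc), mean_auc)


# ---------------------------------------------------------------------------
# recursive feature elimination


@dataclass
class RFEResult:
    """Outcome of RFE + size selection."""

    features: list[str]
    size: int
    ranking: list[str]
    size_scores: dict[int, float]


def rfe_select(
    learner_spec,
    table: FeatureTable,
    plan: SplitPlan,
    sizes: Sequence[int] | None = None,
    tolerance: float = 0.005,
    random_state: int = 0,
) -> RFEResult:
    """Rank features by recursive elimination and pick the smallest good size.

    Features are ranked with RFE on the split's training data; each
    candidate size (top 10 … top 190 by default, step 10) is scored by mean
    CV AUC, and the smallest size within *tolerance* of the best score is
    chosen — small feature sets are preferred when they perform as well as
    large ones.  Sizes beyond the available feature count are truncated.
    """
    feature_names = [c for c in table.data.columns if c != "label"]
    n_features = len(feature_names)
    if sizes is None:
        sizes = range(10, 191, 10)
    sizes = sorted({min(s, n_features) for s in sizes if s > 0})
    train_df = table.data.loc[_rows_for_proteins(table, plan.train_proteins)]
    X, y = _xy(train_df, feature_names)

    base = (
        make_learner(learner_spec, random_state=random_state)
        if isinstance(learner_spec, str)
        else clone(learner_spec)
    )
    rfe = RFE(base, n_features_to_select=1, step=1)
    rfe.fit(X, y)
    order = np.argsort(rfe.ranking_)  # rank 1 = retained last = most important
    ranking = [feature_names[i] for i in order]

    size_scores: dict[int, float] = {}
    for size in sizes:
        subset = ranking[:size]
        cv = cross_validate(
            learner_spec, table, plan, feature_names=subset, random_state=random_state
        )
        size_scores[size] = cv.mean_auc
    best = max(size_scores.values())
    chosen = min(s for s, score in size_scores.items() if score >= best - tolerance)
    return RFEResult(ranking[:chosen], chosen, ranking, size_scores)


# ---------------------------------------------------------------------------
# hyperparameter search

#: search space over the gradient-boosting hyperparameters that matter:
#: learning rate, boosting type, tree complexity, L1/L2 regularisation,
#: bagging, child constraints, split gain, and feature subsampling.
LIGHTGBM_SEARCH_SPACE = {
    "learning_rate": scipy_stats.loguniform(0.01, 0.3),
    "boosting_type": ["gbdt", "dart"],
    "num_leaves": scipy_stats.randint(8, 128),
    "reg_alpha": scipy_stats.loguniform(1e-8, 10.0),
    "reg_lambda": scipy_stats.loguniform(1e-8, 10.0),
    "subsample": scipy_stats.uniform(0.5, 0.5),       # bagging fraction
    "subsample_freq": scipy_stats.randint(0, 8),      # bagging frequency
    "min_child_weight": scipy_stats.loguniform(1e-3, 10.0),
    "min_split_gain": scipy_stats.uniform(0.0, 1.0),
    "colsample_bytree": scipy_stats.uniform(0.5, 0.5),  # feature fraction
    "min_child_samples": scipy_stats.randint(5, 51),
}


@dataclass
class TuningResult:
    """Best parameters and the per-trial log (with the running best AUC)."""

    best_params: dict
    best_auc: float
    trials: list[dict] = field(default_factory=list)


def tune_hyperparams(
    learner_spec: str,
    table: FeatureTable,
    plan: SplitPlan,
    n_trials: int = 100,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    search_space: Mapping | None = None,
) -> TuningResult:
    """Seeded random search maximising mean CV AUC.

    Samples *n_trials* parameter sets from the search space and evaluates
    each with protein-disjoint cross-validation on the plan's training
    side.  The trial log records the incumbent best after every trial.
    """
    space = dict(search_space or LIGHTGBM_SEARCH_SPACE)
    sampler = ParameterSampler(space, n_iter=n_trials, random_state=seed)
    best_params: dict = {}
    best_auc = -np.inf
    trials: list[dict] = []
    for i, params in enumerate(sampler):
        learner = make_learner(learner_spec, params=params, random_state=seed)
        cv = cross_validate(
            learner, table, plan, feature_names=feature_names, random_state=seed
        )
        if cv.mean_auc > best_auc:
            best_auc, best_params = cv.mean_auc, dict(params)
        trials.append(
            {"trial": i, "params": dict(params), "auc": cv.mean_auc, "best_auc": best_auc}
        )
    return TuningResult(best_params, best_auc, trials)


# ---------------------------------------------------------------------------
# the 5x5 ensemble estimator


class DeletionEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Split/fold ensemble for deletion pathogenicity with VUS abstention.

    ``fit`` draws ``n_splits`` protein-disjoint stratified train–test
    partitions of the data (seeded ``random_state + split``), partitions
    each training side into ``n_folds`` protein-disjoint folds, and trains
    one base learner per (split, fold) — 25 models for the default 5×5.
    Prediction averages the per-model pathogenic probabilities; the spread
    across models drives the bootstrap VUS test.

    Parameters
    ----------
    learner:
        Base learner name (``lightgbm``, ``logistic``, ``rf``, ``svm``).
    learner_params:
        Extra keyword parameters for the base learner (e.g. tuned
        gradient-boosting hyperparameters).
    n_splits, n_folds:
        Ensemble geometry; the model count is their product.
    test_frac:
        Protein share held out of each split (those variants never reach
        that split's fold models).
    alpha:
        Significance level of the two-sided bootstrap test; ``p >= alpha``
        yields a VUS call.  ``alpha=1.0`` disables abstention.
    B:
        Bootstrap resamples per variant.
    random_state:
        Seed for splits, fold assignment and learners.

    Attributes
    ----------
    models_ : dict[(int, int), estimator]
        Fitted fold models keyed by (split, fold).
    feature_names_ : list[str]
        Feature order shared by all models.
    splits_ : list[SplitPlan]
        The protein partitions used.
    classes_ : ndarray
        ``["benign", "pathogenic"]``.
    """

    def __init__(
        self,
        learner: str = "lightgbm",
        learner_params: Mapping | None = None,
        n_splits: int = 5,
        n_folds: int = 5,
        test_frac: float = 0.2,
        alpha: float = 0.05,
        B: int = 1000,
        random_state: int = 0,
    ):
        self.learner = learner
        self.learner_params = learner_params
        self.n_splits = n_splits
        self.n_folds = n_folds
        self.test_frac = test_frac
        self.alpha = alpha
        self.B = B
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y: Sequence[str] | None = None, groups: Sequence[str] | None = None):
        """Train the split/fold ensemble.

        *X* is a feature DataFrame (no label column) indexed by variant id;
        *y* the pathogenic/benign labels; *groups* the protein id of each
        row (defaults to the prefix of the variant id before the final
        colon, the canonical ``protein:start-end`` form).
        """
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame of features")
        if y is None:
            raise ValueError("y (pathogenic/benign labels) is required")
        y = np.asarray(
            [POSITIVE if lab in (POSITIVE, 1, True) else "benign" for lab in y],
            dtype=object,
        )
        if groups is None:
            groups = [_variant_protein(str(vid)) for vid in X.index]
        groups = np.asarray(groups, dtype=object)

        per_protein: dict[str, list[str]] = {}
        for g, lab in zip(groups, y):
            per_protein.setdefault(g, []).append(lab)
        protein_labels = {pid: protein_class(labs) for pid, labs in per_protein.items()}

        self.feature_names_ = list(X.columns)
        self.classes_ = np.array(["benign", POSITIVE], dtype=object)
        self.splits_ = []
        self.models_ = {}
        Xa = X.to_numpy(dtype=float)
        y01 = (y == POSITIVE).astype(int)

        for split in range(self.n_splits):
            plan = make_split(
                protein_labels,
                test_frac=self.test_frac,
                n_folds=self.n_folds,
                seed=int(self.random_state) + split,
                split_id=split,
            )
            self.splits_.append(plan)
            train_mask = np.array([g in plan.train_proteins for g in groups])
            for fold, fold_proteins in enumerate(plan.cv_folds):
                fold_mask = np.array([g in fold_proteins for g in groups])
                fit_mask = train_mask & ~fold_mask
                if y01[fit_mask].min(initial=1) == y01[fit_mask].max(initial=0):
                    raise ValueError(
                        f"split {split} fold {fold}: training portion has one class"
                    )
                model = make_learner(
                    self.learner,
                    params=self.learner_params,
                    random_state=int(self.random_state) + split * self.n_folds + fold,
                )
                model.fit(Xa[fit_mask], y01[fit_mask])
                self.models_[(split, fold)] = model
        return self

    # -- prediction -------------------------------------------------------

    def _check_features(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "models_")
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names_ if c not in X.columns]
            if missing:
                raise ValueError(f"missing feature column(s): {missing}")
            return X[self.feature_names_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names_):
            raise ValueError(
                f"expected {len(self.feature_names_)} features, got {X.shape[1]}"
            )
        return X

    def prob_matrix(self, X) -> np.ndarray:
        """Per-model pathogenic probabilities, shape (n_rows, n_models)."""
        Xa = self._check_features(X)
        cols = [
            self.models_[(s, f)].predict_proba(Xa)[:, 1]
            for s in range(self.n_splits)
            for f in range(self.n_folds)
        ]
        return np.column_stack(cols)

    def predict_proba(self, X) -> np.ndarray:
        """Mean ensemble probabilities, sklearn layout (benign, pathogenic)."""
        p = self.prob_matrix(X).mean(axis=1)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        """Binary calls: pathogenic iff mean probability > 0.5."""
        p = self.predict_proba(X)[:, 1]
        return np.where(p > 0.5, POSITIVE, "benign").astype(object)

    def predict_tristate(
        self,
        X,
        variant_ids: Sequence[str] | None = None,
        alpha: float | None = None,
        B: int | None = None,
        seed: int | None = None,
    ) -> list[TriStatePrediction]:
        """Three-state calls with bootstrap VUS abstention."""
        matrix = self.prob_matrix(X)
        if variant_ids is None:
            variant_ids = (
                [str(v) for v in X.index]
                if isinstance(X, pd.DataFrame)
                else [str(i) for i in range(matrix.shape[0])]
            )
        return tristate_calls(
            matrix,
            variant_ids,
            alpha=self.alpha if alpha is None else alpha,
            B=self.B if B is None else B,
            seed=self.random_state if seed is None else seed,
        )

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist as a directory: one model file per (split, fold) + manifest."""
        check_is_fitted(self, "models_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for (s, f), model in self.models_.items():
            joblib.dump(model, directory / f"model_s{s}_f{f}.joblib")
        manifest = {
            "learner": self.learner,
            "learner_params": dict(self.learner_params or {}),
            "n_splits": self.n_splits,
            "n_folds": self.n_folds,
            "test_frac": self.test_frac,
            "alpha": self.alpha,
            "B": self.B,
            "random_state": self.random_state,
            "feature_names": self.feature_names_,
            "splits": [
                {
                    "split_id": p.split_id,
                    "seed": p.seed,
                    "train_proteins": sorted(p.train_proteins),
                    "test_proteins": sorted(p.test_proteins),
                    "cv_folds": [sorted(f) for f in p.cv_folds],
                }
                for p in self.splits_
            ],
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "DeletionEnsembleClassifier":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        est = cls(
            learner=manifest["learner"],
            learner_params=manifest["learner_params"] or None,
            n_splits=manifest["n_splits"],
            n_folds=manifest["n_folds"],
            test_frac=manifest["test_frac"],
            alpha=manifest["alpha"],
            B=manifest["B"],
            random_state=manifest["random_state"],
        )
        est.feature_names_ = list(manifest["feature_names"])
        est.classes_ = np.array(["benign", POSITIVE], dtype=object)
        est.splits_ = [
            SplitPlan(
                split_id=p["split_id"],
                train_proteins=frozenset(p["train_proteins"]),
                test_proteins=frozenset(p["test_proteins"]),
                cv_folds=[frozenset(f) for f in p["cv_folds"]],
                seed=p["seed"],
            )
            for p in manifest["splits"]
        ]
        est.models_ = {}
        for s in range(est.n_splits):
            for f in range(est.n_folds):
                est.models_[(s, f)] = joblib.load(directory / f"model_s{s}_f{f}.joblib")
        return est


def train_ensemble(
    table: FeatureTable,
    feature_names: Sequence[str] | None = None,
    **params,
) -> DeletionEnsembleClassifier:
    """Fit a :class:`DeletionEnsembleClassifier` on a feature table."""
    features = feature_names or [c for c in table.data.columns if c != "label"]
    est = DeletionEnsembleClassifier(**params)
    est.fit(table.data[list(features)], table.data["label"])
    return est
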