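"""Three-stage feature-redundancy filter.

The cascade removes, in order:

1. unstable binary features — minority class of 5 or fewer samples;
2. numeric features with exactly zero variance;
3. redundant numeric features — for any pair with absolute Spearman
   correlation above 0.8, the later column in the deterministic registry
   order is dropped.

The filter is fit on training data only and replayed as a fixed drop list
on evaluation data.  Fixed-width sequence segments are never part of the
tabular input and therefore bypass the cascade by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from delpath.features import FeatureTable


@dataclass
class FilterReport:
    """Bookkeeping for one cascade run; counts reconcile with n_in/n_out."""

    dropped_rare_binary: list[str] = field(default_factory=list)
    dropped_zero_variance: list[str] = field(default_factory=list)
    dropped_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    n_in: int = 0
    n_out: int = 0

    @property
    def n_dropped(self) -> int:
        return (
            len(self.dropped_rare_binary)
            + len(self.dropped_zero_variance)
            + len(self.dropped_correlated)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_in": self.n_in,
                "n_out": self.n_out,
                "dropped_rare_binary": self.dropped_rare_binary,
                "dropped_zero_variance": self.dropped_zero_variance,
                "dropped_correlated": [
                    {"dropped": d, "kept": k, "rho": r}
                    for d, k, r in self.dropped_correlated
                ],
            },
            indent=2,
        )


def drop_rare_binary(
    df: pd.DataFrame, binary_columns: Sequence[str], min_minority: int = 6
) -> tuple[pd.DataFrame, list[str]]:
    """Drop binary columns whose minority class has < *min_minority* samples.

    With the default of 6, a column with 5 or fewer samples in its rarer
    state is removed; an all-constant binary column has minority count 0 and
    is always removed.
    """
    dropped = []
    for col in binary_columns:
        if col not in df.columns:
            continue
        ones = int((df[col] != 0).sum())
        minority = min(ones, len(df) - ones)
        if minority < min_minority:
            dropped.append(col)
    return df.drop(columns=dropped), dropped


def drop_zero_variance(
    df: pd.DataFrame, numeric_columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Drop numeric columns that are exactly constant.

    The rule is strict equality — a column varying by any amount is kept;
    near-constant columns are left for the correlation stage.
    """
    cols = [c for c in (numeric_columns if numeric_columns is not None else df.columns)
            if c in df.columns]
    dropped = [c for c in cols if (df[c] == df[c].iloc[0]).all()]
    return df.drop(columns=dropped), dropped


def drop_correlated(
    df: pd.DataFrame,
    numeric_columns: Sequence[str] | None = None,
    threshold: float = 0.8,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Greedy Spearman-redundancy removal in column order.

    Columns are scanned left to right; a column whose absolute Spearman
    correlation with any already-kept column exceeds *threshold* is dropped,
    recorded as (dropped, kept, rho) against the first offending kept
    column.  Spearman uses average ranks for ties.  The surviving set
    contains no pair above the threshold.
    """
    cols = [c for c in (numeric_columns if numeric_columns is not None else df.columns)
            if c in df.columns]
    if len(cols) < 2:
        return df, []
    ranks = df[cols].rank(method="average").to_numpy()
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)  # Pearson on ranks == Spearman
    kept: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j in range(len(cols)):
        offender = next(
            (i for i in kept if abs(corr[i, j]) > threshold), None
        )
        if offender is None:
            kept.append(j)
        else:
            dropped.append((cols[j], cols[offender], float(corr[offender, j])))
    return df.drop(columns=[d for d, _, _ in dropped]), dropped


class SpearmanRedundancyFilter(BaseEstimator, TransformerMixin):
    """Fit the three-stage cascade on training features, replay anywhere.

    Parameters
    ----------
    min_minority:
        Minimum minority-class size for a binary feature to survive
        (default 6, i.e. features with ≤5 minority samples are dropped).
    threshold:
        Absolute Spearman correlation above which the later feature of a
        pair is dropped.
    binary_columns:
        Names of binary feature columns.  When None, columns whose values
        are a subset of {0, 1} are treated as binary.
    order:
        Deterministic column order for the correlation scan.  When None the
        input column order is used (pass a registry order for the canonical
        category-then-name behaviour).

    Attributes
    ----------
    keep_columns_:
        Columns surviving the cascade, in scan order.
    report_:
        :class:`FilterReport` with itemised drops.
    """

    def __init__(
        self,
        min_minority: int = 6,
        threshold: float = 0.8,
        binary_columns: Sequence[str] | None = None,
        order: Sequence[str] | None = None,
    ):
        self.min_minority = min_minority
        self.threshold = threshold
        self.binary_columns = binary_columns
        self.order = order

    def _resolve_binary(self, X: pd.DataFrame) -> list[str]:
        if self.binary_columns is not None:
            return [c for c in self.binary_columns if c in X.columns]
        return [
            c for c in X.columns if set(pd.unique(X[c])) <= {0, 1, 0.0, 1.0}
        ]

    def fit(self, X: pd.DataFrame, y=None) -> "SpearmanRedundancyFilter":
        if self.order is not None:
            cols = [c for c in self.order if c in X.columns]
        else:
            cols = list(X.columns)
        X = X[cols]
        binary = self._resolve_binary(X)
        numeric = [c for c in cols if c not in binary]

        report = FilterReport(n_in=len(cols))
        X1, report.dropped_rare_binary = drop_rare_binary(X, binary, self.min_minority)
        X2, report.dropped_zero_variance = drop_zero_variance(
            X1, [c for c in numeric if c in X1.columns]
        )
        X3, report.dropped_correlated = drop_correlated(
            X2, [c for c in numeric if c in X2.columns], self.threshold
        )
        report.n_out = X3.shape[1]
        self.keep_columns_ = list(X3.columns)
        self.report_ = report
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.keep_columns_ if c not in X.columns]
        if missing:
            raise ValueError(f"input lacks fitted feature columns: {missing}")
        return X[self.keep_columns_]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.keep_columns_, dtype=object)


def filter_table(
    table: FeatureTable,
    min_minority: int = 6,
    threshold: float = 0.8,
) -> tuple[FeatureTable, SpearmanRedundancyFilter]:
    """Apply the cascade to a :class:`~delpath.features.FeatureTable`.

    Uses the table's registry for binary identification and the canonical
    category-then-name scan order.  Returns the filtered table and the
    fitted filter (reusable on evaluation tables).
    """
    features = table.data[table.registry_order()]
    filt = SpearmanRedundancyFilter(
        min_minority=min_minority,
        threshold=threshold,
        binary_columns=table.binary_columns(),
        order=table.registry_order(),
    )
    filtered = filt.fit(features).transform(features)
    filtered = filtered.copy()
    filtered["label"] = table.data["label"]
    out = FeatureTable(
        data=filtered,
        categories={c: table.categories[c] for c in filt.keep_columns_},
        kinds={c: table.kinds[c] for c in filt.keep_columns_},
        segments=table.segments,
        excluded=list(table.excluded),
    )
    return out, filt
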