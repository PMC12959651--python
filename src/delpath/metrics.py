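"""Performance evaluation for binary and three-state variant classification.

The suite computes PPV, NPV, sensitivity, specificity, accuracy, the
Matthews correlation coefficient (MCC), the overall performance measure

    OPM = (PPV + NPV) · (Sens + Spec) · (Acc + (1 + MCC)/2) / 8,

and a rank-based AUC.  Confusion counts are real-valued because
fold-averaged and class-normalised counts are fractional.  Pathogenic is
the positive class.  VUS calls enter only the missing count; all ratio
metrics are computed on the classified subset.

Class normalisation scales the benign row (TN, FP) so both class totals
equal the pathogenic total.  Every ratio metric is invariant to which row
is scaled, so the direction affects displayed counts only.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    """Real-valued confusion counts plus a missing (VUS) count."""

    TP: float
    TN: float
    FP: float
    FN: float
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_missing < 0:
            raise ValueError("n_missing must be non-negative")

    @property
    def total(self) -> float:
        """Number of classified (non-VUS) cases."""
        return self.TP + self.TN + self.FP + self.FN

    @property
    def positives(self) -> float:
        return self.TP + self.FN

    @property
    def negatives(self) -> float:
        return self.TN + self.FP


@dataclass
class MetricsReport:
    """All ratio metrics with raw and class-normalised confusion counts."""

    counts: ConfusionCounts
    PPV: float
    NPV: float
    sensitivity: float
    specificity: float
    accuracy: float
    MCC: float
    OPM: float
    AUC: float | None = None
    normalised_counts: ConfusionCounts | None = None
    normalised: "MetricsReport | None" = None
    missing_fraction: float = 0.0

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Display values, rounded half-even as printed in reports."""
        out = {
            "PPV": round(self.PPV, ndigits),
            "NPV": round(self.NPV, ndigits),
            "sensitivity": round(self.sensitivity, ndigits),
            "specificity": round(self.specificity, ndigits),
            "accuracy": round(self.accuracy, ndigits),
            "MCC": round(self.MCC, ndigits),
            "OPM": round(self.OPM, ndigits),
        }
        if self.AUC is not None:
            out["AUC"] = round(self.AUC, ndigits)
        return out

    def to_json(self) -> str:
        payload = {
            "counts": vars(self.counts),
            "metrics": {
                "PPV": self.PPV,
                "NPV": self.NPV,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy,
                "MCC": self.MCC,
                "OPM": self.OPM,
                "AUC": self.AUC,
            },
            "missing_fraction": self.missing_fraction,
        }
        if self.normalised_counts is not None:
            payload["normalised_counts"] = vars(self.normalised_counts)
        if self.normalised is not None:
            payload["normalised_metrics"] = self.normalised.rounded(6)
        return json.dumps(payload, indent=2)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def confusion(labels: Sequence[str], calls: Sequence[str]) -> ConfusionCounts:
    """Tally confusion counts; VUS calls count only as missing.

    *labels* must be ``pathogenic``/``benign``; *calls* may additionally be
    ``VUS``.
    """
    if len(labels) != len(calls):
        raise ValueError("labels and calls differ in length")
    tp = tn = fp = fn = missing = 0
    for label, call in zip(labels, calls):
        if label not in ("pathogenic", "benign"):
            raise ValueError(f"unlabeled case {label!r} cannot be scored")
        if call == "VUS":
            missing += 1
        elif call == "pathogenic":
            tp += label == "pathogenic"
            fp += label == "benign"
        elif call == "benign":
            tn += label == "benign"
            fn += label == "pathogenic"
        else:
            raise ValueError(f"unknown call {call!r}")
    return ConfusionCounts(tp, tn, fp, fn, missing)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    den = math.sqrt((tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / den


def metrics(
    counts: ConfusionCounts,
    auc_value: float | None = None,
    normalise: bool = True,
    n_total: float | None = None,
) -> MetricsReport:
    """Full metric report from confusion counts.

    ``n_total`` (classified + missing) sets the missing fraction; it
    defaults to ``counts.total + counts.n_missing``.
    """
    if counts.total == 0:
        raise ValueError("no classified cases; metrics undefined")
    ppv = _safe_ratio(counts.TP, counts.TP + counts.FP, "PPV")
    npv = _safe_ratio(counts.TN, counts.TN + counts.FN, "NPV")
    sens = _safe_ratio(counts.TP, counts.positives, "sensitivity")
    spec = _safe_ratio(counts.TN, counts.negatives, "specificity")
    acc = (counts.TP + counts.TN) / counts.total
    m = mcc(counts)
    opm = (ppv + npv) * (sens + spec) * (acc + (1 + m) / 2) / 8
    total = n_total if n_total is not None else counts.total + counts.n_missing
    report = MetricsReport(
        counts=counts,
        PPV=ppv,
        NPV=npv,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        MCC=m,
        OPM=opm,
        AUC=auc_value,
        missing_fraction=counts.n_missing / total if total else 0.0,
    )
    if normalise and counts.positives > 0 and counts.negatives > 0:
        report.normalised_counts = normalise_counts(counts)
        report.normalised = metrics(report.normalised_counts, normalise=False)
    return report


def normalise_counts(counts: ConfusionCounts) -> ConfusionCounts:
    """Scale the benign row so both class totals equal the pathogenic total.

    All derived ratio metrics are identical whichever row is scaled; the
    benign row is used so that displayed counts match the convention of
    scaling the minority class up to the pathogenic total.
    """
    if counts.positives == 0 or counts.negatives == 0:
        raise ValueError("both class totals must be positive to normalise")
    scale = counts.positives / counts.negatives
    return ConfusionCounts(
        TP=counts.TP,
        TN=counts.TN * scale,
        FP=counts.FP * scale,
        FN=counts.FN,
        n_missing=counts.n_missing,
    )


def auc(labels: Sequence[str], scores: Sequence[float]) -> float:
    """Rank-based (Mann–Whitney) AUC with tied scores averaged.

    Pathogenic is the positive class; both classes must be present.
    """
    y = np.asarray([1 if lab == "pathogenic" else 0 for lab in labels])
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(s)  # average ranks for ties
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def evaluate_tristate(
    labels: Sequence[str],
    calls: Sequence[str],
    scores: Sequence[float] | None = None,
) -> MetricsReport:
    """Metric report for three-state calls.

    Ratio metrics are computed on the classified subset; the missing
    fraction is relative to all cases.  When *scores* are given, AUC is
    computed over all labelled cases (it is threshold-independent and does
    not abstain).
    """
    counts = confusion(labels, calls)
    if counts.total == 0:
        raise ValueError("all calls are VUS; metrics undefined")
    auc_value = auc(labels, scores) if scores is not None else None
    return metrics(counts, auc_value=auc_value, n_total=len(labels))
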