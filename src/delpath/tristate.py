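"""Bootstrap three-state classification: pathogenic / benign / VUS.

Each variant receives 25 probabilities, one per independently trained
model (5 cross-validation folds × 5 train–test splits).  The mean
probability is tested against the no-evidence value 0.5 by bootstrap
resampling of the 25 probabilities (1,000 iterations by default): the
p-value doubles the smaller inclusive tail of the resampled means around
0.5, capped at 1.  Variants whose mean is not significantly different from
0.5 (p ≥ alpha) are variants of uncertain significance (VUS); the rest are
pathogenic when the mean exceeds 0.5 and benign otherwise.

Setting ``alpha`` to 1.0 disables uncertainty entirely: every variant gets
the binary call from its mean probability.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class TriStatePrediction:
    """Ensemble prediction for one variant.

    Invariants: ``mean_prob`` is the mean of ``probs``; for ``alpha`` < 1,
    ``call == "VUS"`` iff ``p_value >= alpha``; a non-VUS call is
    pathogenic iff ``mean_prob > 0.5`` and benign when ``mean_prob <= 0.5``.
    """

    variant_id: str
    probs: tuple[float, ...]
    mean_prob: float
    p_value: float
    call: str
    alpha: float


def binary_call(prob: float) -> str:
    """Pathogenic above 0.5, benign at or below 0.5."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"probability {prob} outside [0, 1]")
    return "pathogenic" if prob > 0.5 else "benign"


def bootstrap_pvalue(
    probs: Sequence[float],
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-sided bootstrap p-value for mean(probs) != 0.5.

    Draws *B* resamples of the probabilities with replacement, computes each
    resample mean m*, and doubles the smaller of the inclusive tail counts
    #{m* >= 0.5} and #{m* <= 0.5}, divided by B and capped at 1.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or probs.size == 0:
        raise ValueError("probs must be a non-empty 1-D sequence")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # the empirical distribution is a multiset: sorting makes the p-value
    # exactly invariant to the order of the input probabilities
    probs = np.sort(probs)
    idx = rng.integers(0, probs.size, size=(B, probs.size))
    means = probs[idx].mean(axis=1)
    upper = int(np.count_nonzero(means >= 0.5))
    lower = int(np.count_nonzero(means <= 0.5))
    return min(1.0, 2.0 * min(upper, lower) / B)


def _variant_seed(global_seed: int, variant_id: str) -> int:
    """Stable per-variant RNG seed, independent of batch order."""
    return (int(global_seed) ^ zlib.crc32(variant_id.encode())) % (2**31 - 1)


def classify(
    variant_id: str,
    probs: Sequence[float],
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
) -> TriStatePrediction:
    """Three-state call for one variant from its per-model probabilities.

    The bootstrap RNG is seeded from the global seed and a hash of the
    variant id, so results do not depend on batch composition or order.
    With ``alpha >= 1`` the significance test is skipped (no uncertainty)
    and the call is the plain binary one.
    """
    probs = tuple(float(p) for p in probs)
    mean_prob = float(np.mean(probs))
    rng = np.random.default_rng(_variant_seed(seed, variant_id))
    p_value = bootstrap_pvalue(probs, B=B, seed=rng)
    if alpha < 1.0 and p_value >= alpha:
        call = "VUS"
    else:
        call = binary_call(mean_prob)
    return TriStatePrediction(variant_id, probs, mean_prob, p_value, call, alpha)


def tristate_calls(
    prob_matrix: np.ndarray,
    variant_ids: Sequence[str],
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
) -> list[TriStatePrediction]:
    """Vectorised three-state calls for a batch.

    *prob_matrix* has one row per variant and one column per ensemble
    model (25 for the standard 5×5 ensemble).
    """
    prob_matrix = np.asarray(prob_matrix, dtype=float)
    if prob_matrix.ndim != 2 or prob_matrix.shape[0] != len(variant_ids):
        raise ValueError("prob_matrix must be (n_variants, n_models)")
    return [
        classify(vid, prob_matrix[i], alpha=alpha, B=B, seed=seed)
        for i, vid in enumerate(variant_ids)
    ]
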