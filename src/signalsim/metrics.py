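"""Tie-corrected Kendall's coefficient of concordance.

The accuracy of a run is summarized as the concordance W among m = 21
judges -- the true display-effort record plus the 20 receiver estimate
vectors -- ranking the n = 20 signalers. The tie-corrected form is required
because receivers that never managed to observe (e.g. for lack of food)
rank every signaler identically at zero; ordinary rank correlations are
undefined at zero variance, while W with mid-ranks and the tie correction
accommodates such judges.

With rank sums :math:`R_i` over judges, :math:`S = \\sum_i (R_i - \\bar R)^2`,
and per-judge tie penalty :math:`T_j = \\sum (t^3 - t)` over tie groups of
size t,

.. math:: W = \\frac{12 S}{m^2 (n^3 - n) - m \\sum_j T_j} \\in [0, 1].
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata


def rank_with_ties(scores: np.ndarray) -> np.ndarray:
    """Mid-ranks of a score vector (rank 1 = smallest; ties share the mean).

    The ranks of n scores always sum to ``n (n + 1) / 2``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size < 1:
        raise ValueError("scores must be a non-empty 1-D vector")
    return rankdata(scores, method="average")


def tie_penalty(scores: np.ndarray) -> float:
    """``sum(t**3 - t)`` over the tie groups of one judge's scores."""
    _, counts = np.unique(np.asarray(scores, dtype=float), return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def kendalls_w(table: np.ndarray) -> float:
    """Tie-corrected Kendall's W for an m-judges x n-objects score matrix.

    Returns 1 exactly when all judges produce the same ranking (identical
    tie patterns included) and 0 for perfectly balanced disagreement. When
    every judge ties every object (zero denominator, no ranking information
    at all) the statistic is defined as 0 and a warning is emitted, so that
    large simulation sweeps never crash on degenerate runs.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-D (judges x objects)")
    m, n = table.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 judges and 2 objects")
    ranks = np.apply_along_axis(rankdata, 1, table)
    R = ranks.sum(axis=0)
    S = float(np.sum((R - R.mean()) ** 2))
    T = sum(tie_penalty(row) for row in table)
    denom = m * m * (n**3 - n) - m * T
    if denom <= 0:
        warnings.warn(
            "all judges fully tied on all objects; Kendall's W undefined, returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    w = 12.0 * S / denom
    # guard against roundoff just outside [0, 1]
    return float(min(max(w, 0.0), 1.0))


def run_concordance(result) -> float:
    """Kendall's W over a run's 21-judge rating table (truth + receivers)."""
    return kendalls_w(result.rating_table())


def mean_truth_correlation(result) -> float:
    """Secondary diagnostic: mean Spearman correlation of receivers vs truth.

    Zero-variance receiver columns contribute 0 (no information) rather than
    NaN. This is not the headline statistic; it ignores inter-receiver
    agreement and fails to use tie information the way W does.
    """
    from scipy.stats import spearmanr

    truth = np.asarray(result.true_efforts, dtype=float)
    rhos = []
    for est in np.asarray(result.estimates, dtype=float):
        if np.ptp(est) == 0 or np.ptp(truth) == 0:
            rhos.append(0.0)
        else:
            rhos.append(float(spearmanr(truth, est).statistic))
    return float(np.mean(rhos)) if rhos else 0.0
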