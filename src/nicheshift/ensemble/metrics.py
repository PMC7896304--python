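"""Discrimination metrics: rank-based AUC and the max(sens+spec) threshold."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def evaluate_auc(scores, labels) -> float:
    """Area under the ROC curve, rank-based with ties counted half.

    Equivalent to the Mann-Whitney U statistic normalized by the number of
    positive-negative pairs.  Raises ``ValueError`` on single-class input,
    where the AUC is undefined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def select_threshold(scores, labels) -> float:
    """Score cutoff maximizing sensitivity + specificity (Youden-type).

    Candidates are the observed scores; a point is predicted positive when
    its score is >= the threshold.  Ties in the objective are broken by the
    lower threshold, favouring sensitivity.  Raises on single-class input.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold undefined: both classes must be present")
    cand = np.unique(scores)  # ascending
    # for each candidate t: sens = P(score >= t | pos), spec = P(score < t | neg).
    # The objective is kept in exact integer arithmetic
    # (sens_count * n_neg + spec_count * n_pos) so that mathematically tied
    # candidates really tie and the lower threshold wins.
    pos_sorted = np.sort(scores[labels == 1])
    neg_sorted = np.sort(scores[labels == 0])
    sens_count = n_pos - np.searchsorted(pos_sorted, cand, side="left")
    spec_count = np.searchsorted(neg_sorted, cand, side="left")
    obj = sens_count * n_neg + spec_count * n_pos
    best = int(np.argmax(obj))  # argmax returns the first (lowest) maximizer
    return float(cand[best])
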