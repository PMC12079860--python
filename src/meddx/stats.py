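"""Rank-based AUC and the paired DeLong test for correlated ROC curves.

The AUC is computed from the Mann-Whitney rank formulation (midranks for
ties); the DeLong test uses the structural-components estimator of the
covariance of two AUCs measured on the same samples.
"""
from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["rank_auc", "delong_test"]


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1, False, True}:
        raise ValueError("labels must be binary 0/1")
    return y.astype(bool)


def rank_auc(scores, labels) -> float:
    """AUC via the rank (Mann-Whitney) formulation with midranks.

    ``labels`` are 0/1 with 1 = case; higher scores indicate case.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _structural_components(scores: np.ndarray, y: np.ndarray):
    """Per-sample placement values V10 (cases) and V01 (controls)."""
    cases = scores[y]
    controls = scores[~y]
    m, n = len(cases), len(controls)
    # midrank placements: fraction of the other class each sample beats
    order = np.concatenate([cases, controls])
    ranks_all = sps.rankdata(order)
    ranks_cases = sps.rankdata(cases)
    ranks_controls = sps.rankdata(controls)
    v10 = (ranks_all[:m] - ranks_cases) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_controls) / m
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Two-sided paired DeLong test for equal AUC.

    Returns ``(auc_a, auc_b, p_value)``.  Both score vectors must be on
    the same samples in the same order.  Identical (or perfectly rank-
    correlated) score vectors give p = 1.
    """
    y = _as_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("paired scores must share the label vector's shape")
    v10a, v01a = _structural_components(a, y)
    v10b, v01b = _structural_components(b, y)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 1e-15:
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return auc_a, auc_b, float(min(p, 1.0))
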