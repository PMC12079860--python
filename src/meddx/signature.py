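"""Per-DMR ROC thresholds and cumulative DNA methylation scores.

For each DMR, an ROC-optimal threshold (Youden's J maximizer by
default) is learned on training labels.  Each sample then scores 1 per
DMR whose orientation-adjusted comparison is satisfied (above the
threshold for hypermethylated DMRs, below for hypomethylated), and the
cumulative count over the signature is the sample's DNA methylation
score.  Fitting and applying are separate calls, so thresholds learned
on a training cohort carry to held-out samples unchanged.
"""
from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .stats import rank_auc

log = logging.getLogger(__name__)

__all__ = [
    "fit_dmr_thresholds",
    "score_samples",
    "compare_scores",
    "FOLD_CAP",
]

#: Cap reported in place of an infinite fold change (control mean 0).
FOLD_CAP = 1e6

THRESHOLD_COLUMNS = ["dmr_id", "threshold", "orientation", "auc"]


def _youden_threshold(
    case_vals: np.ndarray, control_vals: np.ndarray, orientation: str
) -> tuple[float, float]:
    """Maximize J = sensitivity + specificity - 1 over candidate cuts.

    Candidates are midpoints between consecutive distinct values plus
    guards outside the range; ties in J break toward the larger
    threshold.
    """
    values = np.unique(np.concatenate([case_vals, control_vals]))
    mids = (values[:-1] + values[1:]) / 2.0
    candidates = np.concatenate([[values[0] - 1.0], mids, [values[-1] + 1.0]])
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:
        if orientation == "hyper":
            sens = float(np.mean(case_vals > t))
            spec = float(np.mean(control_vals <= t))
        else:
            sens = float(np.mean(case_vals < t))
            spec = float(np.mean(control_vals >= t))
        j = sens + spec - 1.0
        if j >= best_j:  # >= so ties break toward the larger threshold
            best_j, best_t = j, float(t)
    return best_t, best_j


def fit_dmr_thresholds(
    dmr_scores: pd.DataFrame,
    labels: pd.Series,
    directions: Mapping[str, str] | pd.Series | None = None,
    criterion: str = "youden",
) -> pd.DataFrame:
    """Learn a per-DMR positivity threshold from training labels.

    Parameters
    ----------
    dmr_scores
        DMRs x samples RPM score matrix.
    labels
        Binary series indexed by sample (1 = case).
    directions
        DMR direction (``hyper``/``hypo``) per DMR id; defaults to
        hyper.  The orientation of the binary call follows it.
    criterion
        ``youden`` (default) or ``closest01`` (closest to the (0, 1)
        ROC corner).

    Returns a frame with columns ``dmr_id, threshold, orientation, auc``
    (training AUC, orientation-adjusted).  Constant-score DMRs are
    dropped with a warning.
    """
    labels = labels.reindex(dmr_scores.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    y = labels.astype(int).to_numpy()
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need >= 2 samples per label")
    rows = []
    for dmr_id, vals in dmr_scores.iterrows():
        v = vals.to_numpy(dtype=float)
        if np.ptp(v) == 0:
            log.warning("DMR %s has constant scores; threshold undefined, dropped", dmr_id)
            continue
        orient = "hyper"
        if directions is not None:
            orient = dict(directions).get(dmr_id, "hyper")
        case_vals, control_vals = v[y == 1], v[y == 0]
        if criterion == "youden":
            t, _ = _youden_threshold(case_vals, control_vals, orient)
        elif criterion == "closest01":
            t = _closest01_threshold(case_vals, control_vals, orient)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        oriented = v if orient == "hyper" else -v
        rows.append((dmr_id, t, orient, rank_auc(oriented, y)))
    return pd.DataFrame(rows, columns=THRESHOLD_COLUMNS)


def _closest01_threshold(
    case_vals: np.ndarray, control_vals: np.ndarray, orientation: str
) -> float:
    values = np.unique(np.concatenate([case_vals, control_vals]))
    mids = (values[:-1] + values[1:]) / 2.0
    candidates = np.concatenate([[values[0] - 1.0], mids, [values[-1] + 1.0]])
    best_d, best_t = np.inf, candidates[0]
    for t in candidates:
        if orientation == "hyper":
            sens = float(np.mean(case_vals > t))
            spec = float(np.mean(control_vals <= t))
        else:
            sens = float(np.mean(case_vals < t))
            spec = float(np.mean(control_vals >= t))
        d = np.hypot(1.0 - sens, 1.0 - spec)
        if d <= best_d:
            best_d, best_t = d, float(t)
    return best_t


def score_samples(
    dmr_scores: pd.DataFrame, thresholds: pd.DataFrame
) -> pd.DataFrame:
    """Cumulative DNA methylation score per sample.

    score = number of signature DMRs whose call is positive for the
    sample (strictly above the threshold for hyper orientation, strictly
    below for hypo).  A DMR absent from ``dmr_scores`` contributes 0 and
    is logged.  Returns ``sample, score, n_dmrs``.
    """
    n_dmrs = len(thresholds)
    score = pd.Series(0, index=dmr_scores.columns, dtype=int)
    for t in thresholds.itertuples(index=False):
        if t.dmr_id not in dmr_scores.index:
            log.warning("DMR %s missing from the score matrix; contributes 0", t.dmr_id)
            continue
        v = dmr_scores.loc[t.dmr_id]
        positive = v > t.threshold if t.orientation == "hyper" else v < t.threshold
        score += positive.astype(int)
    return pd.DataFrame(
        {"sample": score.index, "score": score.to_numpy(), "n_dmrs": n_dmrs}
    )


def compare_scores(
    scores: pd.DataFrame, labels: pd.Series, q_threshold: float = 0.01
) -> pd.DataFrame:
    """Two-group comparison of signature score vectors.

    ``scores`` is signatures x samples.  Per signature: two-sided
    Mann-Whitney U of case vs control scores and the case/control fold
    change of means; Benjamini-Hochberg across signatures; significance
    flag at q < ``q_threshold``.  Infinite fold changes (control mean 0)
    are capped at :data:`FOLD_CAP` and flagged; all-zero signatures have
    undefined fold change (NaN, flagged).
    """
    labels = labels.reindex(scores.columns)
    y = labels.astype(int).to_numpy()
    if y.sum() < 3 or (1 - y).sum() < 3:
        raise ValueError("need >= 3 samples per group")
    rows = []
    for sig_id, vals in scores.iterrows():
        v = vals.to_numpy(dtype=float)
        case_vals, control_vals = v[y == 1], v[y == 0]
        if np.ptp(v) == 0:
            p = 1.0
        else:
            p = float(sps.mannwhitneyu(case_vals, control_vals, alternative="two-sided").pvalue)
        mc, mo = case_vals.mean(), control_vals.mean()
        capped = False
        if mo == 0 and mc == 0:
            fold = np.nan
            capped = True
        elif mo == 0:
            fold = FOLD_CAP
            capped = True
        else:
            fold = mc / mo
        rows.append((sig_id, fold, capped, p))
    out = pd.DataFrame(rows, columns=["signature", "fold_change", "fold_capped", "p"])
    out["q"] = multipletests(out.p, method="fdr_bh")[1]
    out["significant"] = out.q < q_threshold
    return out
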