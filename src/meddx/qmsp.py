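"""qMSP quantification and percentile-based positivity calling.

Marker methylation is quantified from quantification cycles (Ct) by the
comparative Ct method against the unmethylated ACTB reference:
``2**-(ct_target - ct_reference)``.  A sample is positive for a marker
when its relative level strictly exceeds the control group's 95th
percentile for that marker.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "relative_methylation",
    "levels_matrix",
    "percentile_threshold",
    "call_positivity",
    "detection_fractions",
    "compare_marker_groups",
    "REFERENCE_MARKER",
    "DEFAULT_PERCENTILE",
]

REFERENCE_MARKER = "ACTB"
DEFAULT_PERCENTILE = 95.0
#: Exact Mann-Whitney enumeration when both groups are at most this
#: size and tie-free; the normal approximation with tie correction
#: otherwise.
EXACT_MWU_MAX_N = 25


def relative_methylation(ct_target, ct_reference):
    """Relative methylation level ``2**-(ct_target - ct_reference)``.

    An undetermined (NaN) target Ct — no amplification — maps to level
    0, matching the qMSP semantics of absent methylation.
    """
    ct_t = np.asarray(ct_target, dtype=float)
    ct_r = np.asarray(ct_reference, dtype=float)
    if np.isnan(ct_r).any():
        raise ValueError("reference Ct must be determined")
    undet = np.isnan(ct_t)
    level = np.where(undet, 0.0, np.power(2.0, -(np.where(undet, 0.0, ct_t) - ct_r)))
    if np.isscalar(ct_target) or np.ndim(ct_target) == 0:
        return float(level)
    return level


def levels_matrix(qmsp: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Pivot a long-format qMSP table to a markers x samples level matrix.

    Expects columns ``sample, group, marker, ct_target, ct_reference``.
    Returns the matrix and the per-sample group labels.
    """
    df = qmsp.copy()
    df["level"] = relative_methylation(
        df.ct_target.to_numpy(), df.ct_reference.to_numpy()
    )
    mat = df.pivot_table(index="marker", columns="sample", values="level")
    groups = df.drop_duplicates("sample").set_index("sample")["group"]
    return mat, groups.reindex(mat.columns)


def percentile_threshold(control_values, q: float = DEFAULT_PERCENTILE) -> float:
    """Empirical q-th percentile of control levels (linear interpolation
    between order statistics).  Requires >= 5 control values."""
    v = np.asarray(control_values, dtype=float)
    if len(v) < 5:
        raise ValueError(f"need >= 5 control values, got {len(v)}")
    return float(np.percentile(v, q, method="linear"))


def call_positivity(
    levels: pd.DataFrame, thresholds: pd.Series
) -> pd.DataFrame:
    """Binary positivity per marker and sample: 1 iff level strictly
    exceeds the marker's threshold."""
    missing = set(levels.index) - set(thresholds.index)
    if missing:
        raise ValueError(f"thresholds missing for markers: {sorted(missing)}")
    return levels.gt(thresholds.reindex(levels.index), axis=0).astype(int)


def fit_thresholds(
    levels: pd.DataFrame,
    groups: pd.Series,
    control_group: str,
    q: float = DEFAULT_PERCENTILE,
) -> pd.Series:
    """Per-marker percentile threshold from the control group only."""
    controls = levels.loc[:, groups == control_group]
    if controls.shape[1] < 5:
        raise ValueError(
            f"need >= 5 samples in control group {control_group!r}"
        )
    return controls.apply(lambda row: percentile_threshold(row.to_numpy(), q), axis=1)


def detection_fractions(
    positivity: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Per-marker fraction of positive samples in each group."""
    groups = groups.reindex(positivity.columns)
    out = {}
    for g in groups.unique():
        cols = positivity.columns[groups == g]
        out[g] = positivity[cols].mean(axis=1)
    return pd.DataFrame(out)


def compare_marker_groups(
    levels: pd.DataFrame, groups: pd.Series, case_group: str, control_group: str
) -> pd.Series:
    """Two-sided Mann-Whitney U per marker, case vs control levels.

    The exact null distribution is enumerated when both groups have at
    most 25 tie-free samples; otherwise the normal approximation with
    tie correction is used.  All-tied data gives p = 1.
    """
    groups = groups.reindex(levels.columns)
    out = {}
    for marker, row in levels.iterrows():
        a = row[groups.to_numpy() == case_group].to_numpy(dtype=float)
        b = row[groups.to_numpy() == control_group].to_numpy(dtype=float)
        if len(a) < 3 or len(b) < 3:
            raise ValueError(f"need >= 3 per group for marker {marker}")
        combined = np.concatenate([a, b])
        if np.ptp(combined) == 0:
            out[marker] = 1.0
            continue
        ties = len(np.unique(combined)) < len(combined)
        method = (
            "exact"
            if (not ties and max(len(a), len(b)) <= EXACT_MWU_MAX_N)
            else "asymptotic"
        )
        out[marker] = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    return pd.Series(out, name="p")
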