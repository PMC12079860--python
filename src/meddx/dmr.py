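"""Differentially methylated region calling.

Per-site two-group comparison: counts are pooled within each group and a
2x2 chi-square (site reads vs all other reads, case vs control) without
continuity correction is computed — the coverage normalization a 2x2
test admits; RPM means give the direction and fold change.  Significance
is Bonferroni-corrected over the testable sites.  Runs of neighbouring
significant sites with the same direction and inter-site gaps at most
``max_gap`` are binned into DMRs, which then must clear site-count, size
and fold-change thresholds.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import SiteCountMatrix

__all__ = [
    "per_site_test",
    "call_dmrs",
    "annotate_dmrs",
    "class_tally",
    "remove_sex_chromosomes",
    "DEFAULT_ALPHA",
    "DEFAULT_MAX_GAP",
    "DEFAULT_MIN_SITES",
    "DEFAULT_MIN_SIZE",
    "DEFAULT_MIN_FOLD",
    "SEX_CHROMOSOMES",
]

DEFAULT_ALPHA = 0.05
DEFAULT_MAX_GAP = 1_000
DEFAULT_MIN_SITES = 4
DEFAULT_MIN_SIZE = 100
DEFAULT_MIN_FOLD = 2.0
SEX_CHROMOSOMES = ("chrX", "chrY", "X", "Y")

DMR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_sites",
    "fold_change",
    "direction",
    "min_p_corrected",
]


def per_site_test(case: SiteCountMatrix, control: SiteCountMatrix) -> pd.DataFrame:
    """Chi-square test of pooled group counts at every LpnPI site.

    Returns one row per site with columns ``chrom, pos, case_pooled,
    control_pooled, case_rpm, control_rpm, chi2, p, direction``.  A site
    with zero pooled reads in both groups gets p = 1 and no direction.
    """
    if case.site_index.labels() != control.site_index.labels():
        raise ValueError("case and control matrices must share the site index")
    if case.n_samples < 1 or control.n_samples < 1:
        raise ValueError("need at least one sample per group")
    x1 = case.counts.sum(axis=1).to_numpy(dtype=float)
    x2 = control.counts.sum(axis=1).to_numpy(dtype=float)
    n1 = float(case.library_size.sum())
    n2 = float(control.library_size.sum())
    # 2x2 table per site: [[x1, n1-x1], [x2, n2-x2]], chi-square without
    # continuity correction, df = 1
    total = n1 + n2
    colsum = x1 + x2
    with np.errstate(divide="ignore", invalid="ignore"):
        e11 = n1 * colsum / total
        e12 = n1 * (total - colsum) / total
        e21 = n2 * colsum / total
        e22 = n2 * (total - colsum) / total
        chi2 = (
            (x1 - e11) ** 2 / e11
            + ((n1 - x1) - e12) ** 2 / e12
            + (x2 - e21) ** 2 / e21
            + ((n2 - x2) - e22) ** 2 / e22
        )
    zero = colsum == 0
    chi2 = np.where(zero, 0.0, chi2)
    p = sps.chi2.sf(chi2, df=1)
    p = np.where(zero, 1.0, p)

    case_rpm = case.rpm().mean(axis=1).to_numpy(dtype=float)
    control_rpm = control.rpm().mean(axis=1).to_numpy(dtype=float)
    direction = np.where(
        case_rpm > control_rpm, "hyper", np.where(case_rpm < control_rpm, "hypo", "")
    )
    sites = case.sites_frame()
    return pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "case_pooled": x1,
            "control_pooled": x2,
            "case_rpm": case_rpm,
            "control_rpm": control_rpm,
            "chi2": chi2,
            "p": p,
            "direction": direction,
        }
    )


def call_dmrs(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    n_tests: int | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
    min_sites: int = DEFAULT_MIN_SITES,
    min_size: int = DEFAULT_MIN_SIZE,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> pd.DataFrame:
    """Bin Bonferroni-significant neighbouring sites into DMRs.

    A site is significant iff ``p < alpha / n_tests`` (``n_tests``
    defaults to the number of testable sites, i.e. nonzero pooled
    coverage).  Runs of significant sites with the same direction and
    consecutive gaps <= ``max_gap`` form one DMR spanning from the first
    site to 2 bp past the last (covering its CpG).  DMRs failing
    ``min_sites``, ``min_size`` or ``min_fold`` (on max(fc, 1/fc)) are
    discarded.  Output is coordinate-sorted.
    """
    if results.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    testable = (results.case_pooled + results.control_pooled) > 0
    if n_tests is None:
        n_tests = int(testable.sum())
    if n_tests < 1:
        return pd.DataFrame(columns=DMR_COLUMNS)
    threshold = alpha / n_tests
    sig = results[(results.p < threshold) & (results.direction != "")]
    rows = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        run: list[pd.Series] = []
        for _, site in sub.iterrows():
            if run and (
                site.pos - run[-1].pos > max_gap or site.direction != run[-1].direction
            ):
                rows.append(_close_run(chrom, run, n_tests))
                run = []
            run.append(site)
        if run:
            rows.append(_close_run(chrom, run, n_tests))
    dmrs = pd.DataFrame(rows, columns=DMR_COLUMNS)
    if dmrs.empty:
        return dmrs
    fold_ok = np.maximum(dmrs.fold_change, 1.0 / dmrs.fold_change) >= min_fold
    keep = (
        (dmrs.n_sites >= min_sites)
        & ((dmrs.end - dmrs.start) >= min_size)
        & fold_ok
    )
    return dmrs[keep].sort_values(["chrom", "start"]).reset_index(drop=True)


def _close_run(chrom: str, run: list[pd.Series], n_tests: int) -> dict:
    case_sum = sum(s.case_rpm for s in run)
    control_sum = sum(s.control_rpm for s in run)
    if control_sum > 0:
        fold = case_sum / control_sum
    else:
        fold = np.inf
    return {
        "chrom": chrom,
        "start": int(run[0].pos),
        "end": int(run[-1].pos) + 2,
        "n_sites": len(run),
        "fold_change": fold,
        "direction": run[0].direction,
        "min_p_corrected": min(1.0, min(s.p for s in run) * n_tests),
    }


def annotate_dmrs(dmrs: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Label each DMR with every region class it overlaps by >= 1 bp.

    A DMR overlapping no region is ``intergenic``.  Classes are stored
    as a comma-joined string in a ``classes`` column (each class counted
    once per DMR).
    """
    out = dmrs.copy()
    classes = []
    for d in out.itertuples(index=False):
        sub = regions[regions.chrom == d.chrom]
        hit = sub[(sub.start < d.end) & (sub.end > d.start)]
        cls = sorted(set(hit.cls))
        classes.append(",".join(cls) if cls else "intergenic")
    out["classes"] = classes
    return out


def class_tally(annotated: pd.DataFrame) -> dict[str, int]:
    """Per-class DMR counts (a DMR contributes once to each class it
    overlaps), mirroring per-class DMR tallies in discovery reports."""
    tally: dict[str, int] = {}
    for entry in annotated.get("classes", pd.Series(dtype=str)):
        for cls in str(entry).split(","):
            tally[cls] = tally.get(cls, 0) + 1
    return tally


def remove_sex_chromosomes(
    table: pd.DataFrame, sex_chroms: tuple[str, ...] = SEX_CHROMOSOMES
) -> pd.DataFrame:
    """Drop rows on sex chromosomes (avoids sex-linked methylation
    differences confounding group comparisons)."""
    if "chrom" not in table.columns:
        raise ValueError("table must have a 'chrom' column")
    return table[~table.chrom.isin(sex_chroms)].reset_index(drop=True)
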