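"""End-to-end driver: tissue discovery -> marker selection -> blood evaluation.

``run_discovery`` simulates (or accepts) a two-group tissue cohort,
calls DMRs, learns per-DMR ROC thresholds and selects the top-k markers
by training AUC.  ``run_blood_evaluation`` simulates cfDNA cohorts as
tumor/background mixtures at a given tumor fraction, carries the
tissue-trained thresholds over unchanged, and fits/evaluates the
DMM-only, ASAP-only and combined classifiers on a training cohort
before applying the frozen operating points to a validation cohort.
Validation labels are read only inside the final evaluation call.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dmr as dmr_mod
from . import synthetic
from .containers import GenomeAnnotation, LpnPISiteIndex, SiteCountMatrix
from .diagnostics import ClassifierResult, asap_score, evaluate, fit_combined
from .regions import define_regions, score_regions
from .signature import fit_dmr_thresholds, score_samples

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "DiscoveryResult",
    "run_discovery",
    "run_blood_evaluation",
    "dilution_curve",
    "concat_samples",
]


@dataclass
class PipelineConfig:
    """All tunable knobs of the synthetic end-to-end study."""

    # genome
    n_chroms: int = 2
    chrom_length: int = 500_000
    gene_density: float = 20.0
    island_density: float = 5.0
    # tissue simulation
    n_per_group: int = 10
    mean_depth: float = 50.0
    dispersion: float = 0.05
    n_planted: int = 8
    sites_per_dmr: int = 8
    fold_change: float = 4.0
    # DMR calling
    alpha: float = dmr_mod.DEFAULT_ALPHA
    max_gap: int = dmr_mod.DEFAULT_MAX_GAP
    min_sites: int = dmr_mod.DEFAULT_MIN_SITES
    min_size: int = dmr_mod.DEFAULT_MIN_SIZE
    min_fold: float = dmr_mod.DEFAULT_MIN_FOLD
    # marker selection / evaluation
    top_k: int = 5
    fixed_specificity: float = 0.857
    tumor_fraction: float = 0.02
    n_cfdna_per_group: int = 30
    seed: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class DiscoveryResult:
    annotation: GenomeAnnotation
    site_index: LpnPISiteIndex
    planted: list
    tissue: dict[str, SiteCountMatrix]
    site_results: pd.DataFrame
    dmrs: pd.DataFrame  # annotated, with dmr_id
    dmr_scores: pd.DataFrame
    thresholds: pd.DataFrame  # ranked by training AUC, descending
    selected: list[str] = field(default_factory=list)


def concat_samples(a: SiteCountMatrix, b: SiteCountMatrix) -> SiteCountMatrix:
    """Column-concatenate two matrices on the same site index."""
    if a.site_index.labels() != b.site_index.labels():
        raise ValueError("matrices must share the site index")
    frac = None
    if a.cpg_read_fraction is not None and b.cpg_read_fraction is not None:
        frac = pd.concat([a.cpg_read_fraction, b.cpg_read_fraction])
    return SiteCountMatrix(
        site_index=a.site_index,
        counts=pd.concat([a.counts, b.counts], axis=1),
        library_size=pd.concat([a.library_size, b.library_size]),
        cpg_read_fraction=frac,
    )


def _dmr_region_frame(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Called DMRs as a scoreable region set (region_id = dmr_id)."""
    return pd.DataFrame(
        {
            "region_id": dmrs["dmr_id"],
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "cls": "dmr",
        }
    )


def run_discovery(config: PipelineConfig) -> DiscoveryResult:
    """Tissue-phase discovery on a simulated two-group cohort.

    Generates the toy genome, plants ground-truth DMRs, simulates
    tumor/control tissue counts, calls DMRs (sex chromosomes removed),
    annotates them, scores them per sample, learns per-DMR thresholds
    and ranks DMRs by training AUC, selecting the top-k markers.
    Deterministic for a fixed config seed.
    """
    log.info("discovery: generating genome (seed=%d)", config.seed)
    annotation, site_index = synthetic.generate_genome(
        n_chroms=config.n_chroms,
        chrom_length=config.chrom_length,
        gene_density=config.gene_density,
        island_density=config.island_density,
        seed=config.seed,
    )
    planted = (
        synthetic.choose_planted_dmrs(
            site_index,
            n_dmrs=config.n_planted,
            sites_per_dmr=config.sites_per_dmr,
            fold_change=config.fold_change,
            seed=config.seed + 1,
        )
        if config.n_planted > 0
        else []
    )
    design = synthetic.SimulationDesign(
        n_per_group=config.n_per_group,
        planted_dmrs=planted,
        mean_depth=config.mean_depth,
        dispersion=config.dispersion,
        seed=config.seed + 2,
    )
    tissue = synthetic.simulate_site_counts(annotation, site_index, design)
    case_label, control_label = design.group_labels
    log.info(
        "discovery: %d sites, %d+%d samples",
        site_index.n_sites,
        tissue[case_label].n_samples,
        tissue[control_label].n_samples,
    )
    results = dmr_mod.per_site_test(tissue[case_label], tissue[control_label])
    results = dmr_mod.remove_sex_chromosomes(results)
    dmrs = dmr_mod.call_dmrs(
        results,
        alpha=config.alpha,
        max_gap=config.max_gap,
        min_sites=config.min_sites,
        min_size=config.min_size,
        min_fold=config.min_fold,
    )
    log.info("discovery: %d DMRs called", len(dmrs))
    regions = define_regions(annotation)
    dmrs = dmr_mod.annotate_dmrs(dmrs, regions)
    dmrs["dmr_id"] = [
        f"{d.chrom}:{d.start}-{d.end}" for d in dmrs.itertuples(index=False)
    ]
    if dmrs.empty:
        return DiscoveryResult(
            annotation, site_index, planted, tissue, results, dmrs,
            pd.DataFrame(), pd.DataFrame(), [],
        )
    combined = concat_samples(tissue[case_label], tissue[control_label])
    dmr_scores = score_regions(combined, _dmr_region_frame(dmrs))
    labels = pd.Series(
        [1] * tissue[case_label].n_samples + [0] * tissue[control_label].n_samples,
        index=combined.samples,
    )
    directions = dict(zip(dmrs["dmr_id"], dmrs["direction"]))
    thresholds = fit_dmr_thresholds(dmr_scores, labels, directions)
    thresholds = thresholds.sort_values("auc", ascending=False).reset_index(drop=True)
    k = config.top_k
    if k > len(thresholds):
        log.warning(
            "top_k=%d exceeds the %d available DMRs; returning all", k, len(thresholds)
        )
        k = len(thresholds)
    selected = thresholds.dmr_id.head(k).tolist()
    log.info("discovery: selected top-%d markers: %s", k, selected)
    return DiscoveryResult(
        annotation, site_index, planted, tissue, results, dmrs,
        dmr_scores, thresholds, selected,
    )


def _cfdna_cohort(
    discovery: DiscoveryResult,
    tumor_fraction: float,
    n_per_group: int,
    dispersion: float,
    seed: int,
    prefix: str,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate one cfDNA cohort and return (DMM score frame, labels).

    The HCC group is a tumor/background mixture at ``tumor_fraction``;
    controls are pure background.  Per-sample cumulative DMM scores use
    the tissue-trained thresholds restricted to the selected markers.
    Also returns each sample's best-marker RPM in column ``best_dmm``.
    """
    case_label, control_label = ("tumor", "control")
    tumor_profile = synthetic.mean_profile(discovery.tissue[case_label])
    background = synthetic.mean_profile(discovery.tissue[control_label])
    hcc = synthetic.simulate_cfdna_counts(
        discovery.site_index, tumor_profile, background, tumor_fraction,
        n_samples=n_per_group, dispersion=dispersion, seed=seed,
        sample_prefix=f"{prefix}_hcc",
    )
    ctrl = synthetic.simulate_cfdna_counts(
        discovery.site_index, tumor_profile, background, 0.0,
        n_samples=n_per_group, dispersion=dispersion, seed=seed + 1,
        sample_prefix=f"{prefix}_ctrl",
    )
    combined = concat_samples(hcc, ctrl)
    sel = discovery.thresholds[discovery.thresholds.dmr_id.isin(discovery.selected)]
    sel_dmrs = discovery.dmrs[discovery.dmrs.dmr_id.isin(discovery.selected)]
    scores_matrix = score_regions(combined, _dmr_region_frame(sel_dmrs))
    cumulative = score_samples(scores_matrix, sel).set_index("sample")["score"]
    best = discovery.selected[0]
    features = pd.DataFrame(
        {
            "dmm_score": cumulative,
            "best_dmm": scores_matrix.loc[best],
        }
    )
    labels = pd.Series(
        [1] * n_per_group + [0] * n_per_group, index=combined.samples
    )
    return features, labels


def _clinical_features(labels: pd.Series, seed: int) -> pd.Series:
    """ASAP scores for a cohort aligned to the cfDNA sample labels."""
    n_case = int(labels.sum())
    n_ctrl = int((1 - labels).sum())
    cohort = synthetic.simulate_cohort(
        {"HCC": n_case, "cirrhosis": n_ctrl}, seed=seed
    )
    z = asap_score(cohort.age, cohort.sex, cohort.afp, cohort.pivka)
    idx = list(labels.index[labels == 1]) + list(labels.index[labels == 0])
    return pd.Series(np.asarray(z), index=idx).reindex(labels.index)


MODEL_FEATURES = {
    "dmm_only": ["dmm_score"],
    "asap_only": ["asap"],
    "asap_plus_dmm": ["asap", "dmm_score"],
    "asap_plus_best_dmm": ["asap", "best_dmm"],
}


def run_blood_evaluation(
    config: PipelineConfig,
    discovery: DiscoveryResult,
    tumor_fraction: float | None = None,
) -> dict[str, dict[str, ClassifierResult]]:
    """Blood-phase evaluation at one cfDNA tumor fraction.

    Simulates independent training and validation cfDNA cohorts plus
    matched clinical covariates, fits the four classifiers on training
    data, and applies the frozen models and operating thresholds to the
    validation cohort.  Returns
    ``{model: {'train': ClassifierResult, 'validation': ...}}``.
    """
    if not discovery.selected:
        raise ValueError("discovery selected no markers")
    tf = config.tumor_fraction if tumor_fraction is None else tumor_fraction
    n = config.n_cfdna_per_group
    if n < 1:
        raise ValueError("empty cfDNA cohort")
    feats_tr, y_tr = _cfdna_cohort(
        discovery, tf, n, config.dispersion, config.seed + 100, "train"
    )
    feats_va, y_va = _cfdna_cohort(
        discovery, tf, n, config.dispersion, config.seed + 200, "val"
    )
    feats_tr["asap"] = _clinical_features(y_tr, config.seed + 300)
    feats_va["asap"] = _clinical_features(y_va, config.seed + 400)

    out: dict[str, dict[str, ClassifierResult]] = {}
    for model, cols in MODEL_FEATURES.items():
        fit = fit_combined(feats_tr[cols], y_tr, method="enter")
        s_tr = fit.decision_scores(feats_tr)
        train_res = evaluate(
            s_tr, y_tr, fixed_specificity=config.fixed_specificity, aic=fit.aic
        )
        s_va = fit.decision_scores(feats_va)
        val_res = evaluate(s_va, y_va, threshold=train_res.threshold)
        out[model] = {"train": train_res, "validation": val_res}
        log.info(
            "%s: train AUC %.3f, validation AUC %.3f",
            model, train_res.auc, val_res.auc,
        )
    return out


def dilution_curve(
    config: PipelineConfig,
    discovery: DiscoveryResult,
    fractions: Sequence[float] = (1.0, 0.25, 0.05, 0.0),
    n_per_group: int | None = None,
) -> dict[float, float]:
    """Cumulative-DMM-score AUC as a function of cfDNA tumor fraction.

    The computational twin of the study's blood phase: tissue-trained
    thresholds applied to cfDNA mixtures lose separation as the tumor
    fraction drops, reaching chance (AUC 0.5) at fraction 0.
    """
    from .stats import rank_auc

    n = n_per_group or config.n_cfdna_per_group
    out = {}
    for i, tf in enumerate(fractions):
        feats, labels = _cfdna_cohort(
            discovery, tf, n, config.dispersion, config.seed + 1000 + 7 * i, f"tf{i}"
        )
        out[float(tf)] = rank_auc(feats["dmm_score"].to_numpy(), labels.to_numpy())
    return out
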