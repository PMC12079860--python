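"""Synthetic cohorts with the statistical structure MeD-seq analysis assumes.

This module generates every input the downstream stages consume: a toy
genome with gene models, CpG islands and LpnPI site positions; per-site
negative-binomial read counts for two-group tissue designs with planted
hyper/hypomethylated regions; cfDNA counts as a tumor/background mixture
with a tunable tumor fraction; qMSP Ct tables; and clinical cohorts with
group-dependent AFP/PIVKA-II distributions.  All randomness flows from
explicit seeds — there is no hidden global RNG state.

The defaults define the simulated study conditions: mean depth 50 reads
per site, NB dispersion 0.05 (mild bulk-sequencing overdispersion),
cfDNA tumor fraction 0.02 reflecting the 1-3% hepatocyte contribution
to plasma cfDNA in the literature on liquid biopsy of the liver.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import GenomeAnnotation, LpnPISiteIndex, SiteCountMatrix
from .reads import ReadRecord

__all__ = [
    "PlantedDmr",
    "SimulationDesign",
    "generate_genome",
    "simulate_site_counts",
    "simulate_cfdna_counts",
    "emit_fragments",
    "choose_planted_dmrs",
    "mean_profile",
    "simulate_qmsp",
    "simulate_cohort",
    "FRAGMENT_LENGTH",
    "FRAGMENT_SITE_OFFSET",
]

#: LpnPI digestion produces 32 bp fragments around the methylated CpG.
FRAGMENT_LENGTH = 32
#: Offset of the CpG's C within the emitted fragment: 15 bp from the 5'
#: end, 16 bp from the 3' end — inside the 13-17 bp filter window.
FRAGMENT_SITE_OFFSET = 15

# Site spacing: mean gap between CpG/LpnPI sites outside (background)
# and inside CpG islands, in bp.
_BG_SITE_SPACING = 100.0
_ISLAND_SITE_SPACING = 20.0
_MIN_GENE_LEN, _MAX_GENE_LEN = 3_000, 10_000
_MIN_ISLAND_LEN, _MAX_ISLAND_LEN = 300, 1_500


@dataclass(frozen=True)
class PlantedDmr:
    """A ground-truth differentially methylated region to plant."""

    chrom: str
    start: int
    end: int
    direction: str = "hyper"  # hyper | hypo, relative to the case group
    fold_change: float = 4.0

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be 'hyper' or 'hypo'")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.end <= self.start:
            raise ValueError("empty planted region")


@dataclass
class SimulationDesign:
    """Two-group site-count simulation parameters."""

    n_per_group: int = 10
    group_labels: tuple[str, str] = ("tumor", "control")
    planted_dmrs: list[PlantedDmr] = field(default_factory=list)
    mean_depth: float = 50.0
    dispersion: float = 0.05
    tumor_fraction: float = 0.02
    background_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float, size: tuple
) -> np.ndarray:
    """Negative binomial with mean ``mean`` and Var = m + dispersion*m^2
    (Poisson in the dispersion -> 0 limit)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_genome(
    n_chroms: int = 1,
    chrom_length: int = 1_000_000,
    gene_density: float = 20.0,
    island_density: float = 5.0,
    seed: int = 0,
) -> tuple[GenomeAnnotation, LpnPISiteIndex]:
    """Generate a toy genome annotation plus its LpnPI site index.

    Densities are per Mb.  Gene counts per chromosome are Poisson around
    ``gene_density * length / 1e6``; islands likewise, placed without
    overlap.  LpnPI sites are point CpG positions with exponential
    spacing, denser inside islands.  Deterministic for a fixed seed.
    """
    if gene_density <= 0 or island_density <= 0:
        raise ValueError("densities must be > 0 (no gene/island placeable)")
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10 kb")
    if n_chroms < 1:
        raise ValueError("need at least one chromosome")
    if chrom_length < _MIN_GENE_LEN + 4_000:
        raise ValueError("chromosome too short to host any gene")
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": int(chrom_length) for i in range(n_chroms)}

    gene_rows, island_rows, positions = [], [], {}
    gid = 0
    for chrom, size in chroms.items():
        n_genes = rng.poisson(gene_density * size / 1e6)
        for _ in range(n_genes):
            glen = int(rng.integers(_MIN_GENE_LEN, min(_MAX_GENE_LEN, size - 4_000)))
            lo = int(rng.integers(2_000, size - glen - 2_000))
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (lo, lo + glen) if strand == "+" else (lo + glen, lo)
            gene_rows.append((f"gene{gid}", chrom, strand, tss, tes))
            gid += 1

        n_islands = rng.poisson(island_density * size / 1e6)
        taken: list[tuple[int, int]] = []
        for _ in range(n_islands):
            for _attempt in range(50):
                ilen = int(rng.integers(_MIN_ISLAND_LEN, _MAX_ISLAND_LEN))
                start = int(rng.integers(0, size - ilen))
                if all(start >= e or start + ilen <= s for s, e in taken):
                    taken.append((start, start + ilen))
                    break
        taken.sort()
        island_rows.extend((chrom, s, e) for s, e in taken)

        # background sites: exponential spacing; extra density in islands
        gaps = rng.exponential(_BG_SITE_SPACING, int(2 * size / _BG_SITE_SPACING))
        bg = np.cumsum(np.maximum(2, gaps.astype(np.int64)))
        bg = bg[bg < size - FRAGMENT_LENGTH]
        extra = []
        for s, e in taken:
            g = rng.exponential(_ISLAND_SITE_SPACING, int(2 * (e - s) / _ISLAND_SITE_SPACING))
            p = s + np.cumsum(np.maximum(2, g.astype(np.int64)))
            extra.append(p[p < e])
        allpos = np.unique(
            np.concatenate([bg] + extra) if extra else bg
        )
        positions[chrom] = allpos[allpos >= FRAGMENT_LENGTH]

    annotation = GenomeAnnotation(
        chromosomes=chroms,
        genes=pd.DataFrame(
            gene_rows, columns=["gene_id", "chrom", "strand", "tss", "tes"]
        ),
        cpg_islands=pd.DataFrame(island_rows, columns=["chrom", "start", "end"]),
    )
    annotation.validate()
    return annotation, LpnPISiteIndex(positions)


def _region_mask(site_index: LpnPISiteIndex, chrom: str, start: int, end: int) -> np.ndarray:
    """Flat boolean mask (index order) for sites in [start, end)."""
    mask = np.zeros(site_index.n_sites, dtype=bool)
    off = 0
    for c, p in site_index.positions.items():
        if c == chrom:
            mask[off : off + len(p)] = (p >= start) & (p < end)
        off += len(p)
    return mask


def group_mean_vectors(
    annotation: GenomeAnnotation,
    site_index: LpnPISiteIndex,
    design: SimulationDesign,
) -> dict[str, np.ndarray]:
    """Per-site expected counts for case and control under the design."""
    case_label, control_label = design.group_labels
    base = np.full(site_index.n_sites, design.mean_depth, dtype=float)
    case_mean = base.copy() * (1.0 + design.background_shift)
    for dmr in design.planted_dmrs:
        if dmr.chrom not in annotation.chromosomes:
            raise ValueError(f"planted DMR on unknown chromosome {dmr.chrom}")
        mask = _region_mask(site_index, dmr.chrom, dmr.start, dmr.end)
        if not mask.any():
            warnings.warn(
                f"planted DMR {dmr.chrom}:{dmr.start}-{dmr.end} contains no "
                "LpnPI sites and cannot be planted",
                stacklevel=2,
            )
            continue
        if dmr.direction == "hyper":
            case_mean[mask] *= dmr.fold_change
        else:
            case_mean[mask] /= dmr.fold_change
    return {case_label: case_mean, control_label: base}


def simulate_site_counts(
    annotation: GenomeAnnotation,
    site_index: LpnPISiteIndex,
    design: SimulationDesign,
) -> dict[str, SiteCountMatrix]:
    """Simulate per-group site-count matrices under a two-group design."""
    rng = np.random.default_rng(design.seed)
    means = group_mean_vectors(annotation, site_index, design)
    labels = site_index.labels()
    out = {}
    for group, mean in means.items():
        n = design.n_per_group
        draw = _nb_sample(rng, mean[:, None], design.dispersion, (len(mean), n))
        cols = [f"{group}_{i}" for i in range(n)]
        counts = pd.DataFrame(draw, index=labels, columns=cols)
        out[group] = SiteCountMatrix(
            site_index=site_index,
            counts=counts,
            library_size=counts.sum(axis=0).astype(float),
            cpg_read_fraction=pd.Series(1.0, index=cols),
        )
    return out


def mean_profile(matrix: SiteCountMatrix) -> np.ndarray:
    """Per-site mean count across samples — a tissue methylation profile."""
    return matrix.counts.mean(axis=1).to_numpy(dtype=float)


def simulate_cfdna_counts(
    site_index: LpnPISiteIndex,
    tumor_profile: np.ndarray,
    background_profile: np.ndarray,
    tumor_fraction: float,
    n_samples: int = 10,
    dispersion: float = 0.05,
    seed: int = 0,
    sample_prefix: str = "cfdna",
) -> SiteCountMatrix:
    """cfDNA counts as a convex tumor/background mixture.

    The expected count at each site is
    ``tumor_fraction * tumor + (1 - tumor_fraction) * background``,
    then NB-sampled — the dilution that buries tumor methylation under
    non-tumor cfDNA at low fractions.
    """
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    tumor_profile = np.asarray(tumor_profile, dtype=float)
    background_profile = np.asarray(background_profile, dtype=float)
    if tumor_profile.shape != (site_index.n_sites,) or background_profile.shape != (
        site_index.n_sites,
    ):
        raise ValueError("profiles must match the site index length")
    rng = np.random.default_rng(seed)
    mean = tumor_fraction * tumor_profile + (1.0 - tumor_fraction) * background_profile
    draw = _nb_sample(rng, mean[:, None], dispersion, (len(mean), n_samples))
    cols = [f"{sample_prefix}_{i}" for i in range(n_samples)]
    counts = pd.DataFrame(draw, index=site_index.labels(), columns=cols)
    return SiteCountMatrix(
        site_index=site_index,
        counts=counts,
        library_size=counts.sum(axis=0).astype(float),
        cpg_read_fraction=pd.Series(1.0, index=cols),
    )


def choose_planted_dmrs(
    site_index: LpnPISiteIndex,
    n_dmrs: int,
    sites_per_dmr: int = 8,
    fold_change: float = 4.0,
    direction: str = "hyper",
    min_separation: int = 5_000,
    seed: int = 0,
) -> list[PlantedDmr]:
    """Pick ``n_dmrs`` non-adjacent runs of consecutive LpnPI sites as
    ground-truth regions, at least ``min_separation`` bp apart."""
    rng = np.random.default_rng(seed)
    chroms = [c for c in site_index.chroms if len(site_index.positions[c]) >= sites_per_dmr]
    if not chroms:
        raise ValueError("no chromosome has enough sites")
    out: list[PlantedDmr] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while len(out) < n_dmrs and attempts < 1000 * n_dmrs:
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        pos = site_index.positions[chrom]
        i = int(rng.integers(0, len(pos) - sites_per_dmr + 1))
        start, end = int(pos[i]), int(pos[i + sites_per_dmr - 1]) + 2
        if any(
            start < e + min_separation and end > s - min_separation
            for s, e in occupied[chrom]
        ):
            continue
        occupied[chrom].append((start, end))
        out.append(PlantedDmr(chrom, start, end, direction, fold_change))
    if len(out) < n_dmrs:
        raise ValueError("could not place the requested number of DMRs")
    return sorted(out, key=lambda d: (d.chrom, d.start))


def emit_fragments(
    matrix: SiteCountMatrix, sample_id: str, seed: int | None = None
) -> list[ReadRecord]:
    """Emit raw 32-bp fragment reads realising one sample's site counts.

    Each count at a site becomes one fragment whose CpG sits
    ``FRAGMENT_SITE_OFFSET`` bp from the 5' end; assigning the emitted
    reads back through the positional filter recovers the input counts
    exactly (the round-trip oracle for the read path).
    """
    counts = matrix.counts[sample_id]
    reads: list[ReadRecord] = []
    sites = matrix.sites_frame()
    for (chrom, pos), c in zip(
        zip(sites["chrom"], sites["pos"]), counts.to_numpy()
    ):
        start = int(pos) - FRAGMENT_SITE_OFFSET
        if start < 0:
            start = 0
        offset = int(pos) - start
        reads.extend(
            ReadRecord(chrom, start, FRAGMENT_LENGTH, (offset,))
            for _ in range(int(c))
        )
    if seed is not None:
        rng = np.random.default_rng(seed)
        reads = [reads[i] for i in rng.permutation(len(reads))]
    return reads


def simulate_qmsp(
    group_means: Mapping[str, Mapping[str, float]],
    sd: float = 0.5,
    n_per_group: int = 20,
    seed: int = 0,
    ref_ct_mean: float = 25.0,
    ref_ct_sd: float = 0.5,
) -> pd.DataFrame:
    """Simulate a long-format qMSP table.

    ``group_means[group][marker]`` is the expected delta-Ct (target
    minus ACTB reference); ``ct_target = ct_ref + dCt + N(0, sd)`` with
    a per-sample reference Ct drawn around ``ref_ct_mean``.  With sd=0
    every sample's relative methylation is exactly ``2**-dCt``.
    """
    if sd < 0 or ref_ct_sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, marker_means in group_means.items():
        for i in range(n_per_group):
            sample = f"{group}_{i}"
            ct_ref = ref_ct_mean + rng.normal(0.0, ref_ct_sd)
            for marker, dct in marker_means.items():
                ct_t = ct_ref + dct + rng.normal(0.0, sd)
                rows.append((sample, group, marker, ct_t, ct_ref))
    return pd.DataFrame(
        rows, columns=["sample", "group", "marker", "ct_target", "ct_reference"]
    )


# Default clinical cohort distributions (log10-normal parameters) for an
# HCC-vs-cirrhosis contrast: HCC has higher and more dispersed AFP and
# PIVKA-II.  Units: AFP ng/mL, PIVKA-II mAU/mL.
DEFAULT_AFP_PARAMS = {"HCC": (1.3, 0.8), "cirrhosis": (0.6, 0.5), "healthy": (0.4, 0.3)}
DEFAULT_PIVKA_PARAMS = {"HCC": (2.3, 0.8), "cirrhosis": (1.5, 0.4), "healthy": (1.3, 0.3)}


def simulate_cohort(
    n_per_group: Mapping[str, int],
    afp_params: Mapping[str, tuple[float, float]] | None = None,
    pivka_params: Mapping[str, tuple[float, float]] | None = None,
    age_range: tuple[int, int] = (45, 75),
    male_fraction: float = 0.7,
    early_stage_fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a clinical cohort table.

    AFP/PIVKA-II are drawn log10-normally per group and clipped to the
    assay detection limits; BCLC stage is assigned only to the HCC
    group (early = BCLC 0-A, late = BCLC B-D).
    """
    from .diagnostics import clip_to_detection_limits

    if not 0.0 <= male_fraction <= 1.0:
        raise ValueError("male_fraction must be in [0, 1]")
    afp_params = dict(DEFAULT_AFP_PARAMS) if afp_params is None else afp_params
    pivka_params = dict(DEFAULT_PIVKA_PARAMS) if pivka_params is None else pivka_params
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in n_per_group.items():
        am, asd = afp_params[group]
        pm, psd = pivka_params[group]
        for i in range(int(n)):
            age = int(rng.integers(age_range[0], age_range[1] + 1))
            sex = int(rng.random() < male_fraction)
            afp = 10.0 ** rng.normal(am, asd)
            pivka = 10.0 ** rng.normal(pm, psd)
            afp, pivka = clip_to_detection_limits(afp, pivka)
            if group == "HCC":
                stage = "early" if rng.random() < early_stage_fraction else "late"
                tumor_size = float(np.round(rng.uniform(1.0, 3.0 if stage == "early" else 8.0), 1))
            else:
                stage, tumor_size = "none", np.nan
            rows.append((f"{group}_{i}", group, age, sex, afp, pivka, stage, tumor_size))
    return pd.DataFrame(
        rows,
        columns=["sample", "group", "age", "sex", "afp", "pivka", "stage", "tumor_size"],
    )
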