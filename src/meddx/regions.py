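"""Region classes (TSS, gene body, CpG island) and RPM region scores.

A TSS region spans 1 kb before and 1 kb after the transcription start
site; a gene body runs from 1 kb after the TSS to the transcription end
site, strand-aware; CpG islands pass through from the annotation.  All
intervals are 0-based half-open and clipped to chromosome bounds.
Region scores are reads-per-million sums of site counts in the interval.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import GenomeAnnotation, SiteCountMatrix

log = logging.getLogger(__name__)

__all__ = ["define_regions", "score_regions", "REGION_CLASSES", "DEFAULT_TSS_FLANK"]

REGION_CLASSES = ("TSS", "gene_body", "cpg_island")
DEFAULT_TSS_FLANK = 1_000

REGION_COLUMNS = ["region_id", "chrom", "start", "end", "cls"]


def define_regions(
    annotation: GenomeAnnotation, tss_flank: int = DEFAULT_TSS_FLANK
) -> pd.DataFrame:
    """Build the TSS / gene-body / CpG-island region set.

    For a plus-strand gene with tss < tes: TSS window
    ``[tss - flank, tss + flank)`` and gene body ``[tss + flank, tes)``.
    On the minus strand the construction mirrors: TSS window
    ``[tss - flank, tss + flank)`` (symmetric, so identical in genomic
    coordinates) and gene body ``[tes, tss - flank)``.  Bodies shorter
    than 1 bp are omitted with a logged warning.  Overlapping genes give
    overlapping regions — no merging.
    """
    rows = []
    for _, g in annotation.genes.iterrows():
        size = annotation.chromosomes[g.chrom]
        tss_start = max(0, g.tss - tss_flank)
        tss_end = min(size, g.tss + tss_flank)
        rows.append((f"{g.gene_id}:TSS", g.chrom, tss_start, tss_end, "TSS"))
        if g.strand == "+":
            b_start, b_end = g.tss + tss_flank, g.tes
        else:
            b_start, b_end = g.tes, g.tss - tss_flank
        b_start, b_end = max(0, b_start), min(size, b_end)
        if b_end > b_start:
            rows.append((f"{g.gene_id}:body", g.chrom, b_start, b_end, "gene_body"))
        else:
            log.warning("gene %s shorter than the TSS flank; empty gene body omitted", g.gene_id)
    for i, isl in annotation.cpg_islands.iterrows():
        rows.append((f"cgi{i}", isl.chrom, int(isl.start), int(isl.end), "cpg_island"))
    out = pd.DataFrame(rows, columns=REGION_COLUMNS)
    out[["start", "end"]] = out[["start", "end"]].astype(np.int64)
    return out


def score_regions(matrix: SiteCountMatrix, regions: pd.DataFrame) -> pd.DataFrame:
    """RPM-normalized read-count score per region and sample.

    score(region, sample) = sum of counts at LpnPI sites with
    ``start <= pos < end``, times 1e6 / library_size.  A region with no
    sites scores 0 (and is flagged via the returned frame's ``n_sites``
    attribute, not an error).
    """
    if (regions.start >= regions.end).any():
        raise ValueError("region with start >= end")
    values = np.zeros((len(regions), matrix.n_samples))
    n_sites = np.zeros(len(regions), dtype=int)
    raw = matrix.counts.to_numpy()
    # flat row offsets of each chromosome block in the counts matrix
    offsets: dict[str, tuple[int, np.ndarray]] = {}
    off = 0
    for c, p in matrix.site_index.positions.items():
        offsets[c] = (off, p)
        off += len(p)
    for i, r in enumerate(regions.itertuples(index=False)):
        block = offsets.get(r.chrom)
        if block is None:
            continue
        off, pos = block
        lo = int(np.searchsorted(pos, r.start, side="left"))
        hi = int(np.searchsorted(pos, r.end, side="left"))
        n_sites[i] = hi - lo
        if hi > lo:
            values[i] = raw[off + lo : off + hi].sum(axis=0)
    lib = matrix.library_size.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rpm = values * 1e6 / lib[None, :]
    out = pd.DataFrame(rpm, index=regions.region_id.to_numpy(), columns=matrix.samples)
    out.attrs["n_sites"] = pd.Series(n_sites, index=out.index)
    if (n_sites == 0).any():
        log.info("%d regions contain no LpnPI sites (score 0)", int((n_sites == 0).sum()))
    return out
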