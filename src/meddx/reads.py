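"""MeD-seq fragment filtering, site assignment and sample QC.

LpnPI digestion of methylated CpGs yields short (32 bp) fragments with
the recognition CpG a fixed distance from the fragment ends.  Reads are
kept when an LpnPI site lies 13-17 bp (inclusive, configurable) from
either end, then each kept read is attributed to exactly one site of the
index.  Alignment itself is out of scope: reads carry their mapped
position, and a loader for externally produced per-site count tables is
available in :mod:`meddx.io`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import LpnPISiteIndex, SiteCountMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ReadRecord",
    "FilterStats",
    "QcResult",
    "filter_reads",
    "assign_reads",
    "qc_sample",
    "qc_matrix",
    "DEFAULT_MIN_OFFSET",
    "DEFAULT_MAX_OFFSET",
    "PAPER_QC_MIN_READS",
    "PAPER_QC_MIN_CPG_FRACTION",
    "TOY_QC_MIN_READS",
]

DEFAULT_MIN_OFFSET = 13
DEFAULT_MAX_OFFSET = 17

#: Sample QC thresholds at sequencing scale: a good library has over
#: 20 million reads and more than 20% of reads containing a CpG.
PAPER_QC_MIN_READS = 20_000_000
PAPER_QC_MIN_CPG_FRACTION = 0.20
#: Toy-scale default for simulated libraries (same CpG fraction rule).
TOY_QC_MIN_READS = 2_000


@dataclass(frozen=True)
class ReadRecord:
    """A mapped MeD-seq fragment.

    ``site_offsets`` are the 0-based distances, from the 5' end of the
    read, of every LpnPI site the read covers; the distance from the 3'
    end of an offset ``o`` is ``length - 1 - o``.
    """

    chrom: str
    start: int
    length: int
    site_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("read length must be positive")
        if any(o < 0 or o >= self.length for o in self.site_offsets):
            raise ValueError("site offset outside read")


@dataclass
class FilterStats:
    n_input: int = 0
    n_kept: int = 0

    @property
    def n_discarded(self) -> int:
        return self.n_input - self.n_kept


@dataclass
class QcResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    total_reads: float = 0.0
    cpg_read_fraction: float = 0.0


def _qualifying_offsets(
    read: ReadRecord, min_offset: int, max_offset: int
) -> list[int]:
    """5'-sorted offsets whose distance from either end is in window."""
    out = []
    for o in read.site_offsets:
        d3 = read.length - 1 - o
        if min_offset <= o <= max_offset or min_offset <= d3 <= max_offset:
            out.append(o)
    return sorted(out)


def filter_reads(
    reads: Iterable[ReadRecord],
    min_offset: int = DEFAULT_MIN_OFFSET,
    max_offset: int = DEFAULT_MAX_OFFSET,
) -> tuple[list[ReadRecord], FilterStats]:
    """Keep reads with an LpnPI site 13-17 bp from the 3' or 5' end.

    Both window bounds are inclusive.  Returns the kept reads (input
    order preserved) and kept/discarded statistics.
    """
    if min_offset > max_offset:
        raise ValueError("min_offset must be <= max_offset")
    stats = FilterStats()
    kept: list[ReadRecord] = []
    for read in reads:
        stats.n_input += 1
        if _qualifying_offsets(read, min_offset, max_offset):
            kept.append(read)
            stats.n_kept += 1
    return kept, stats


def assign_reads(
    reads: Sequence[ReadRecord],
    site_index: LpnPISiteIndex,
    sample_id: str = "sample",
    min_offset: int = DEFAULT_MIN_OFFSET,
    max_offset: int = DEFAULT_MAX_OFFSET,
) -> tuple[SiteCountMatrix, int]:
    """Attribute each kept read to exactly one LpnPI site.

    The site is the 5'-most offset satisfying the positional filter;
    reads whose qualifying site is absent from the index go to an
    ``unassigned`` bucket (returned as the second element) so that
    assigned + unassigned equals the number of input reads.

    ``cpg_read_fraction`` of the resulting one-sample matrix is the
    fraction of reads carrying any LpnPI site at all.
    """
    labels = site_index.labels()
    order = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros(len(labels), dtype=np.int64)
    unassigned = 0
    n_with_site = 0
    for read in reads:
        if read.site_offsets:
            n_with_site += 1
        offs = _qualifying_offsets(read, min_offset, max_offset)
        placed = False
        for o in offs:  # 5'-most qualifying site wins
            pos = read.start + o
            i = order.get(f"{read.chrom}:{pos}")
            if i is not None:
                counts[i] += 1
                placed = True
                break
        if not placed:
            unassigned += 1
    if unassigned:
        log.warning("%d/%d reads had no indexable qualifying site", unassigned, len(reads))
    n = len(reads)
    matrix = SiteCountMatrix(
        site_index=site_index,
        counts=pd.DataFrame({sample_id: counts}, index=labels),
        library_size=pd.Series({sample_id: float(n)}),
        cpg_read_fraction=pd.Series({sample_id: n_with_site / n if n else 0.0}),
    )
    return matrix, unassigned


def qc_sample(
    total_reads: float,
    cpg_read_fraction: float,
    min_total_reads: float = PAPER_QC_MIN_READS,
    min_cpg_fraction: float = PAPER_QC_MIN_CPG_FRACTION,
) -> QcResult:
    """Good-quality sample rule: strictly more reads than the floor AND
    strictly more than the minimum CpG-read fraction."""
    reasons = []
    if not total_reads > min_total_reads:
        reasons.append(
            f"total reads {total_reads:g} not over {min_total_reads:g}"
        )
    if not cpg_read_fraction > min_cpg_fraction:
        reasons.append(
            f"CpG read fraction {cpg_read_fraction:.3f} not over {min_cpg_fraction:.3f}"
        )
    return QcResult(
        passed=not reasons,
        reasons=reasons,
        total_reads=total_reads,
        cpg_read_fraction=cpg_read_fraction,
    )


def qc_matrix(
    matrix: SiteCountMatrix,
    min_total_reads: float = TOY_QC_MIN_READS,
    min_cpg_fraction: float = PAPER_QC_MIN_CPG_FRACTION,
) -> dict[str, QcResult]:
    """Apply :func:`qc_sample` to every sample of a count matrix."""
    out = {}
    for s in matrix.samples:
        frac = (
            1.0
            if matrix.cpg_read_fraction is None
            else float(matrix.cpg_read_fraction[s])
        )
        out[s] = qc_sample(
            float(matrix.library_size[s]), frac, min_total_reads, min_cpg_fraction
        )
    return out
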