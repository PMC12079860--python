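"""Core in-memory containers shared across the pipeline.

The coordinate system is 0-based, half-open (BED convention) throughout.
An LpnPI site is represented by the position of the C of its CpG; the
site index is the single coordinate frame to which reads, counts,
regions and DMRs all refer.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAnnotation",
    "LpnPISiteIndex",
    "SiteCountMatrix",
    "site_label",
]


def site_label(chrom: str, pos: int) -> str:
    """Canonical string id of an LpnPI site, e.g. ``'chr1:1042'``."""
    return f"{chrom}:{pos}"


@dataclass(frozen=True)
class GenomeAnnotation:
    """Toy genome annotation: chromosome sizes, gene models, CpG islands.

    Parameters
    ----------
    chromosomes
        Mapping chromosome name -> length in bp.
    genes
        DataFrame with columns ``gene_id, chrom, strand, tss, tes``.
        ``tss < tes`` on the plus strand and ``tss > tes`` on minus.
    cpg_islands
        DataFrame with columns ``chrom, start, end`` (0-based half-open);
        island intervals are non-overlapping per chromosome.
    """

    chromosomes: Mapping[str, int]
    genes: pd.DataFrame
    cpg_islands: pd.DataFrame

    def validate(self) -> None:
        for _, g in self.genes.iterrows():
            size = self.chromosomes.get(g.chrom)
            if size is None:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            lo, hi = sorted((g.tss, g.tes))
            if lo < 0 or hi > size:
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")
            if g.strand == "+" and not g.tss < g.tes:
                raise ValueError(f"plus-strand gene {g.gene_id} must have tss < tes")
            if g.strand == "-" and not g.tss > g.tes:
                raise ValueError(f"minus-strand gene {g.gene_id} must have tss > tes")
        for chrom, sub in self.cpg_islands.groupby("chrom", sort=False):
            size = self.chromosomes.get(chrom)
            if size is None:
                raise ValueError(f"island on unknown chromosome {chrom}")
            sub = sub.sort_values("start")
            if (sub.start < 0).any() or (sub.end > size).any():
                raise ValueError(f"island outside chromosome {chrom}")
            if (sub.start >= sub.end).any():
                raise ValueError("empty island interval")
            if (sub.start.to_numpy()[1:] < sub.end.to_numpy()[:-1]).any():
                raise ValueError(f"overlapping islands on {chrom}")


@dataclass(frozen=True)
class LpnPISiteIndex:
    """Ordered genomic positions of CpG-containing LpnPI sites per chromosome."""

    positions: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError("positions must be 1-D per chromosome")
            if not np.all(np.diff(arr) > 0):
                arr = np.unique(arr)
            clean[chrom] = arr
        object.__setattr__(self, "positions", clean)

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    def labels(self) -> list[str]:
        return [site_label(c, p) for c, pos in self.positions.items() for p in pos]

    def sites_frame(self) -> pd.DataFrame:
        """Flat (chrom, pos) table in index order."""
        chroms: list[str] = []
        pos: list[np.ndarray] = []
        for c, p in self.positions.items():
            chroms.extend([c] * len(p))
            pos.append(p)
        flat = np.concatenate(pos) if pos else np.empty(0, dtype=np.int64)
        return pd.DataFrame({"chrom": chroms, "pos": flat})

    def contains(self, chrom: str, pos: int) -> bool:
        arr = self.positions.get(chrom)
        if arr is None or len(arr) == 0:
            return False
        i = np.searchsorted(arr, pos)
        return i < len(arr) and arr[i] == pos

    def subset(self, mask: np.ndarray) -> "LpnPISiteIndex":
        """Restrict to the flat boolean ``mask`` (index order)."""
        out: dict[str, np.ndarray] = {}
        off = 0
        for c, p in self.positions.items():
            m = mask[off : off + len(p)]
            off += len(p)
            if m.any():
                out[c] = p[m]
        return LpnPISiteIndex(out)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        for c, p in self.positions.items():
            for x in p:
                yield c, int(x)


@dataclass
class SiteCountMatrix:
    """Per-sample read counts at each LpnPI site.

    ``counts`` is a sites x samples DataFrame whose row index is the
    site labels of ``site_index`` in index order.  ``library_size`` is
    the total number of filtered reads per sample (>= column sum, since
    some reads may be unassignable); ``cpg_read_fraction`` is the
    per-sample fraction of reads containing an LpnPI/CpG site, the
    second sample-QC operand.
    """

    site_index: LpnPISiteIndex
    counts: pd.DataFrame
    library_size: pd.Series
    cpg_read_fraction: pd.Series | None = None

    def __post_init__(self) -> None:
        labels = self.site_index.labels()
        if list(self.counts.index) != labels:
            raise ValueError("counts rows do not match the site index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.library_size = pd.Series(self.library_size, dtype=float).reindex(
            self.counts.columns
        )
        if self.library_size.isna().any():
            raise ValueError("library_size missing for some samples")
        colsums = self.counts.sum(axis=0)
        if (colsums > self.library_size + 1e-9).any():
            raise ValueError("column sums exceed library_size")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def rpm(self) -> pd.DataFrame:
        """Reads-per-million normalized counts (per-sample)."""
        lib = self.library_size.replace(0, np.nan)
        return (self.counts / lib) * 1e6

    def subset_sites(self, mask: np.ndarray) -> "SiteCountMatrix":
        sub_index = self.site_index.subset(mask)
        return SiteCountMatrix(
            site_index=sub_index,
            counts=self.counts.loc[mask].copy(),
            library_size=self.library_size.copy(),
            cpg_read_fraction=None
            if self.cpg_read_fraction is None
            else self.cpg_read_fraction.copy(),
        )

    def sites_frame(self) -> pd.DataFrame:
        return self.site_index.sites_frame()
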