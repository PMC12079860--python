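"""File formats: BED for regions/DMRs, TSV for counts and scores,
FASTA for synthetic fragments, YAML for configs, JSON for reports.

Every writer stamps a provenance comment header (config hash and seed
when supplied); readers skip ``#`` comment lines.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import LpnPISiteIndex, SiteCountMatrix
from .reads import ReadRecord

__all__ = [
    "config_hash",
    "write_site_counts",
    "read_site_counts",
    "write_regions_bed",
    "read_regions_bed",
    "write_dmrs_bed",
    "write_fragments_fasta",
    "read_fragments_fasta",
    "write_json",
    "load_config",
    "save_config",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(provenance: dict | None) -> str:
    if not provenance:
        return ""
    items = " ".join(f"{k}={v}" for k, v in provenance.items())
    return f"# meddx {items}\n"


def write_site_counts(
    matrix: SiteCountMatrix, path: str | Path, provenance: dict | None = None
) -> None:
    """Counts as TSV: rows are ``chrom:pos`` sites, columns samples,
    plus trailing metadata rows for library size and CpG fraction."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(provenance))
        out = matrix.counts.copy()
        out.loc["__library_size__"] = matrix.library_size
        if matrix.cpg_read_fraction is not None:
            out.loc["__cpg_read_fraction__"] = matrix.cpg_read_fraction
        out.to_csv(fh, sep="\t", index_label="site")


def read_site_counts(path: str | Path) -> SiteCountMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = None
    lib = df.loc["__library_size__"].rename(None)
    frac = (
        df.loc["__cpg_read_fraction__"].rename(None)
        if "__cpg_read_fraction__" in df.index
        else None
    )
    counts = df.drop(
        index=[i for i in ("__library_size__", "__cpg_read_fraction__") if i in df.index]
    )
    positions: dict[str, list[int]] = {}
    for label in counts.index:
        chrom, pos = label.rsplit(":", 1)
        positions.setdefault(chrom, []).append(int(pos))
    index = LpnPISiteIndex({c: np.array(p) for c, p in positions.items()})
    return SiteCountMatrix(
        site_index=index,
        counts=counts.astype(np.int64),
        library_size=lib.astype(float),
        cpg_read_fraction=None if frac is None else frac.astype(float),
    )


def write_regions_bed(
    regions: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    """Regions as BED4; column 4 is ``region_id|class``."""
    with open(path, "w") as fh:
        fh.write(_header(provenance))
        for r in regions.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}|{r.cls}\n")


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, name = line.split("\t")[:4]
        region_id, cls = name.rsplit("|", 1)
        rows.append((region_id, chrom, int(start), int(end), cls))
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "cls"])


def write_dmrs_bed(
    dmrs: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    """DMRs as BED6+: chrom, start, end, id, -log10 min corrected p,
    strand encoding direction (+ hyper, - hypo), then n_sites,
    fold_change and the annotation classes."""
    with open(path, "w") as fh:
        fh.write(_header(provenance))
        for i, d in enumerate(dmrs.itertuples(index=False)):
            neglog = -np.log10(max(d.min_p_corrected, 1e-300))
            strand = "+" if d.direction == "hyper" else "-"
            classes = getattr(d, "classes", "NA")
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\tdmr{i}\t{neglog:.3f}\t{strand}"
                f"\t{d.n_sites}\t{d.fold_change:.4g}\t{classes}\n"
            )


def write_fragments_fasta(
    reads: Iterable[ReadRecord], path: str | Path
) -> None:
    """Synthetic 32-mers as FASTA; the CpG is written at its offsets so
    the parser can recover site positions from the sequence itself."""
    records = []
    for i, r in enumerate(reads):
        seq = ["A"] * r.length
        for o in r.site_offsets:
            seq[o] = "C"
            if o + 1 < r.length:
                seq[o + 1] = "G"
        records.append(
            SeqRecord(
                Seq("".join(seq)),
                id=f"read{i}",
                description=f"{r.chrom}:{r.start}",
            )
        )
    SeqIO.write(records, str(path), "fasta")


def read_fragments_fasta(path: str | Path) -> list[ReadRecord]:
    """Parse synthetic fragments; CG dinucleotides mark candidate sites."""
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        chrom, start = rec.description.split()[-1].rsplit(":", 1)
        seq = str(rec.seq)
        offsets = tuple(
            i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"
        )
        reads.append(ReadRecord(chrom, int(start), len(seq), offsets))
    return reads


def write_json(obj: dict, path: str | Path) -> None:
    def _default(x):
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
        raise TypeError(f"not JSON serializable: {type(x)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
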