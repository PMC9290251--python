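"""Readers and writers for the plain-text formats the pipeline touches.

All tables are tab-separated; '#' starts a comment line in the haplotype
dialect; "NA" is the missing-value sentinel in written matrices. BED
intervals are 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnnotationTrack,
    BetaMatrix,
    CpGSiteTable,
    HaplotypeRecord,
    MHBlock,
    MHLMatrix,
    block_from_sites,
    validate_clinical,
)

log = logging.getLogger("mhbkit")

NA = "NA"


# ---------------------------------------------------------------- CpG sites

def read_cpg_sites(path: str | Path) -> CpGSiteTable:
    """Read a sorted BED3 of CpG positions (chrom, pos, pos+1)."""
    pos: dict[str, list[int]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected BED3, got {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end != start + 1:
                raise ValueError(f"{path}:{ln}: CpG interval must be 1 bp wide")
            pos.setdefault(chrom, []).append(start)
    return CpGSiteTable({c: np.asarray(p) for c, p in pos.items()})


def write_cpg_sites(sites: CpGSiteTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sites.chroms:
            for p in sites.positions[chrom]:
                fh.write(f"{chrom}\t{p}\t{p + 1}\n")


# --------------------------------------------------------------- haplotypes

def read_haplotypes(path: str | Path, sites: CpGSiteTable) -> list[HaplotypeRecord]:
    """Parse the haplotype TSV dialect: chrom, sample, start_site_index, pattern, count."""
    records: list[HaplotypeRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 columns, got {len(parts)}")
            chrom, sample, start_s, pattern, count_s = parts
            try:
                start, count = int(start_s), int(count_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
            rec = HaplotypeRecord(sample=sample, chrom=chrom, start=start,
                                  pattern=pattern, count=count)
            try:
                rec.validate(sites)
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
            records.append(rec)
    return records


def write_haplotypes(records: Iterable[HaplotypeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tsample\tstart_site_index\tpattern\tcount\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.sample}\t{r.start}\t{r.pattern}\t{r.count}\n")


# ------------------------------------------------------------------- blocks

def write_blocks_bed(blocks: Sequence[MHBlock], path: str | Path) -> None:
    """Write blocks as BED4 (chrom, start, end, block_id)."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.block_id}\n")


def read_blocks_bed(path: str | Path, sites: CpGSiteTable) -> list[MHBlock]:
    """Read BED4 blocks, recovering member sites as the CpGs inside [start, end)."""
    blocks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected BED4")
            chrom, start, end, bid = parts[0], int(parts[1]), int(parts[2]), parts[3]
            pos = sites.positions[chrom]
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, end, side="left"))
            if hi <= lo:
                raise ValueError(f"{path}:{ln}: block {bid} contains no CpG sites")
            blocks.append(block_from_sites(bid, chrom, range(lo, hi), sites))
    return blocks


# -------------------------------------------------------------- beta matrix

def read_beta_matrix(values_path: str | Path, manifest_path: str | Path) -> BetaMatrix:
    """Read probes x samples beta TSV plus a BED4 manifest (chrom, start, end, probe_id).

    Probes absent from the manifest are dropped with a logged count.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0, na_values=[NA])
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicate probe id {dup!r} in {values_path}")
    arr = values.to_numpy(dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("beta value outside [0, 1]")

    manifest = pd.read_csv(manifest_path, sep="\t", header=None,
                           names=["chrom", "start", "end", "probe_id"], comment="#")
    if manifest["probe_id"].duplicated().any():
        raise ValueError("duplicate probe id in manifest")
    coords = manifest.set_index("probe_id")[["chrom", "start"]].rename(
        columns={"start": "pos"})

    keep = values.index.intersection(coords.index)
    dropped = len(values.index) - len(keep)
    if dropped:
        log.warning("dropping %d probe(s) without manifest coordinates", dropped)
    return BetaMatrix(values=values.loc[keep], coords=coords.loc[keep])


def write_beta_matrix(beta: BetaMatrix, values_path: str | Path,
                      manifest_path: str | Path) -> None:
    beta.values.to_csv(values_path, sep="\t", na_rep=NA, index_label="probe_id")
    with open(manifest_path, "w") as fh:
        for pid, row in beta.coords.iterrows():
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{pid}\n")


# ----------------------------------------------------------------- clinical

def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV: sample, os_time, os_event, pfs_time, pfs_event, covariates."""
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    return validate_clinical(df)


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    validate_clinical(df).to_csv(path, sep="\t", na_rep=NA, index=False)


# --------------------------------------------------------------- annotation

def read_annotation_bed(path: str | Path) -> AnnotationTrack:
    """Read a BED4 annotation track (chrom, start, end, class label)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            rows.append((parts[0], start, end, parts[3]))
    return AnnotationTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def write_annotation_bed(track: AnnotationTrack, path: str | Path) -> None:
    track.intervals.to_csv(path, sep="\t", header=False, index=False)


# --------------------------------------------------------------- MHL matrix

def write_mhl_matrix(matrix: MHLMatrix, path: str | Path,
                     support_path: str | Path | None = None) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep=NA, index_label="block_id")
    if support_path is not None:
        matrix.support.to_csv(support_path, sep="\t", index_label="block_id")


def read_mhl_matrix(path: str | Path,
                    support_path: str | Path | None = None) -> MHLMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    if support_path is not None:
        support = pd.read_csv(support_path, sep="\t", index_col=0)
    else:
        support = pd.DataFrame(np.nan, index=values.index, columns=values.columns)
    return MHLMatrix(values=values, support=support)
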