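"""Domain containers shared across the pipeline.

Coordinates are 0-based half-open everywhere. CpG sites are identified by
their rank (index) within a chromosome's ordered position list, so read
haplotype patterns are unambiguous under any reference assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd


class HaplotypeRecord(NamedTuple):
    """One observed read-level methylation pattern with multiplicity.

    ``start`` is the site index (rank within the chromosome's CpG table)
    of the first CpG covered; ``pattern`` is a string over {'1','0'}
    ('1' = methylated); ``count`` is the number of identical reads.
    """

    sample: str
    chrom: str
    start: int
    pattern: str
    count: int

    def validate(self, sites: "CpGSiteTable") -> None:
        if len(self.pattern) < 1:
            raise ValueError("empty haplotype pattern")
        if set(self.pattern) - {"0", "1"}:
            raise ValueError(f"pattern {self.pattern!r} has characters outside {{0,1}}")
        if self.count < 1:
            raise ValueError(f"non-positive count {self.count}")
        n = sites.n_sites(self.chrom)
        if self.start < 0 or self.start + len(self.pattern) > n:
            raise ValueError(
                f"haplotype [{self.start}, {self.start + len(self.pattern)}) "
                f"exceeds {n} sites on {self.chrom}"
            )


@dataclass(frozen=True)
class CpGSiteTable:
    """Ordered CpG positions per chromosome (forward-strand C, 0-based).

    Site index = rank within the chromosome; indices are dense from 0.
    """

    positions: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: positions must be 1-D")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{chrom}: CpG positions must be strictly increasing")
            clean[chrom] = arr
        object.__setattr__(self, "positions", clean)

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    def n_sites(self, chrom: str) -> int:
        if chrom not in self.positions:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return int(self.positions[chrom].size)

    def position(self, chrom: str, index: int) -> int:
        return int(self.positions[chrom][index])


@dataclass(frozen=True)
class MHBlock:
    """A methylation haplotype block: a run of tightly coupled CpG sites.

    ``sites`` are consecutive site indices into the CpG table; the genomic
    interval [start, end) spans the first to last member CpG (+1).
    """

    block_id: str
    chrom: str
    start: int
    end: int
    sites: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sites) < 1:
            raise ValueError("block with no member sites")
        if list(self.sites) != list(range(self.sites[0], self.sites[-1] + 1)):
            raise ValueError("member sites must be consecutive")
        if self.end - self.start < len(self.sites):
            raise ValueError("interval shorter than member count")

    @property
    def first_site(self) -> int:
        return self.sites[0]

    @property
    def last_site(self) -> int:
        return self.sites[-1]

    @property
    def n_cpgs(self) -> int:
        return len(self.sites)


def block_from_sites(block_id: str, chrom: str, site_indices: Iterable[int],
                     sites: CpGSiteTable) -> MHBlock:
    """Build a block from member site indices, deriving its genomic span."""
    idx = tuple(sorted(site_indices))
    start = sites.position(chrom, idx[0])
    end = sites.position(chrom, idx[-1]) + 1
    return MHBlock(block_id=block_id, chrom=chrom, start=start, end=end, sites=idx)


@dataclass
class MHLMatrix:
    """Blocks x samples MHL values in [0,1] (NaN = missing) plus read support."""

    values: pd.DataFrame
    support: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("duplicate block ids in MHL matrix")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("MHL values must lie in [0, 1]")

    @property
    def blocks(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class BetaMatrix:
    """Array-style beta values (probes x samples) with probe coordinates."""

    values: pd.DataFrame                 # probes x samples, NaN allowed
    coords: pd.DataFrame                 # index probe_id; columns chrom, pos

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("duplicate probe ids")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")


@dataclass
class AnnotationTrack:
    """Named, possibly overlapping genomic intervals with class labels."""

    intervals: pd.DataFrame              # columns chrom, start, end, label

    def __post_init__(self) -> None:
        df = self.intervals
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"empty/inverted interval {bad.chrom}:{bad.start}-{bad.end}")

    @property
    def classes(self) -> list[str]:
        return sorted(self.intervals["label"].unique())


CLINICAL_COLUMNS = ["sample", "os_time", "os_event", "pfs_time", "pfs_event"]


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical table: unique samples, non-negative times, binary events."""
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    for col in ("os_time", "pfs_time"):
        if (df[col].dropna() < 0).any():
            raise ValueError(f"negative time in column {col}")
    for col in ("os_event", "pfs_event"):
        vals = set(df[col].dropna().unique())
        if not vals <= {0, 1, 0.0, 1.0}:
            raise ValueError(f"non-binary event flag in column {col}: {sorted(vals)}")
    return df
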