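"""Methylation haplotype block detection.

Adjacent CpG pairs are scored with the two-locus linkage statistic r**2
computed from read haplotypes pooled across all samples; blocks are the
maximal runs of consecutive CpGs in which every adjacent pair is tightly
coupled (defined r**2 >= r2_min) and which contain at least min_cpgs sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import CpGSiteTable, HaplotypeRecord, MHBlock, block_from_sites

DEFAULT_R2_MIN = 0.5
DEFAULT_MIN_CPGS = 3
DEFAULT_MIN_PAIR_READS = 10


@dataclass(frozen=True)
class CpGPairLD:
    """Joint haplotype counts and linkage r**2 for adjacent sites (i, i+1).

    ``r2`` is None when undefined: fewer than min_pair_reads informative
    reads, or either site monomorphic across the pooled reads.
    """

    chrom: str
    left_index: int
    n11: int
    n10: int
    n01: int
    n00: int
    r2: float | None

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def methylation_ld(n11: int, n10: int, n01: int, n00: int,
                   min_pair_reads: int = DEFAULT_MIN_PAIR_READS) -> float | None:
    """r**2 between two CpG sites from joint haplotype counts.

    With p11 = n11/n, p1. = (n11+n10)/n, p.1 = (n11+n01)/n and
    D = p11 - p1.*p.1, r**2 = D**2 / (p1.(1-p1.) p.1(1-p.1)).
    Returns None (undefined) when n < min_pair_reads or a marginal is 0 or 1.
    """
    for c in (n11, n10, n01, n00):
        if c < 0:
            raise ValueError("negative haplotype count")
    n = n11 + n10 + n01 + n00
    if n < min_pair_reads:
        return None
    p11 = n11 / n
    p1_ = (n11 + n10) / n
    p_1 = (n11 + n01) / n
    denom = p1_ * (1 - p1_) * p_1 * (1 - p_1)
    if denom == 0:  # monomorphic marginal: no linkage evidence
        return None
    d = p11 - p1_ * p_1
    return float(min(1.0, d * d / denom))


def pair_ld(records: Iterable[HaplotypeRecord], sites: CpGSiteTable,
            min_pair_reads: int = DEFAULT_MIN_PAIR_READS) -> dict[str, list[CpGPairLD]]:
    """Joint counts and r**2 for every adjacent site pair with any coverage.

    Reads are pooled across samples; only reads covering both sites of a
    pair contribute. Returns per-chromosome lists ordered by site index.
    """
    counts: dict[tuple[str, int], np.ndarray] = {}
    for rec in records:
        pat = rec.pattern
        for k in range(len(pat) - 1):
            key = (rec.chrom, rec.start + k)
            cell = counts.get(key)
            if cell is None:
                cell = counts[key] = np.zeros(4, dtype=np.int64)
            # order: 11, 10, 01, 00
            idx = (1 - int(pat[k])) * 2 + (1 - int(pat[k + 1]))
            cell[idx] += rec.count

    out: dict[str, list[CpGPairLD]] = {}
    for (chrom, i), (n11, n10, n01, n00) in sorted(counts.items()):
        r2 = methylation_ld(int(n11), int(n10), int(n01), int(n00), min_pair_reads)
        out.setdefault(chrom, []).append(
            CpGPairLD(chrom, i, int(n11), int(n10), int(n01), int(n00), r2))
    return out


def partition_blocks(ld: dict[str, Sequence[CpGPairLD]], sites: CpGSiteTable,
                     r2_min: float = DEFAULT_R2_MIN,
                     min_cpgs: int = DEFAULT_MIN_CPGS) -> list[MHBlock]:
    """Partition each chromosome into maximal tightly-coupled runs.

    A run extends over consecutive sites while every adjacent pair has a
    defined r**2 >= r2_min; an undefined pair (or a gap in the pair list)
    breaks the run. Runs shorter than min_cpgs are discarded.
    """
    blocks: list[MHBlock] = []
    for chrom in sorted(ld):
        pairs = ld[chrom]
        idx = [p.left_index for p in pairs]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"{chrom}: LD pairs not ordered by site index")
        run_start: int | None = None
        prev_left: int | None = None

        def flush(last_site: int) -> None:
            nonlocal run_start
            if run_start is not None and last_site - run_start + 1 >= min_cpgs:
                bid = f"{chrom}:{run_start}-{last_site}"
                blocks.append(block_from_sites(bid, chrom, range(run_start, last_site + 1), sites))
            run_start = None

        for p in pairs:
            linked = p.r2 is not None and p.r2 >= r2_min
            if run_start is not None and prev_left is not None and p.left_index != prev_left + 1:
                flush(prev_left + 1)  # gap in pair coverage breaks the run
            if linked:
                if run_start is None:
                    run_start = p.left_index
            else:
                flush(p.left_index)
            prev_left = p.left_index
        if prev_left is not None:
            flush(prev_left + 1)
    return blocks


def detect_blocks(records: Iterable[HaplotypeRecord], sites: CpGSiteTable,
                  r2_min: float = DEFAULT_R2_MIN,
                  min_cpgs: int = DEFAULT_MIN_CPGS,
                  min_pair_reads: int = DEFAULT_MIN_PAIR_READS) -> list[MHBlock]:
    """Convenience wrapper: pooled pair LD then run partitioning."""
    return partition_blocks(pair_ld(records, sites, min_pair_reads), sites,
                            r2_min=r2_min, min_cpgs=min_cpgs)
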