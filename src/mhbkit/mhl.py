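"""Methylation haplotype load (MHL) scoring and mean-methylation summaries.

MHL for a block is a weighted mean, over substring lengths l = 1..L (L the
longest within-block stretch observed on any read), of m_l = the fraction of
fully methylated contiguous windows of l member CpGs among all such windows
observed across reads, with weights w_l = l:

    MHL = sum_l l * m_l / sum_l l

Windows are formed within single reads only; a read partially covering a
block contributes only the windows it fully contains. Unlike the plain mean
(m_1), MHL rewards long runs of concordant methylation, which is what makes
block-level haplotype signal more discriminative than per-CpG averages.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotationTrack, CpGSiteTable, HaplotypeRecord, MHBlock, MHLMatrix

DEFAULT_MIN_BLOCK_READS = 5


def _window_counts(sub: str, count: int, meth: list[int], total: list[int]) -> None:
    """Accumulate fully-methylated / total window counts for one read segment."""
    m = len(sub)
    while len(meth) < m:
        meth.append(0)
        total.append(0)
    for l in range(1, m + 1):
        total[l - 1] += (m - l + 1) * count
    # fully methylated windows of length l inside a '1'-run of length r: r-l+1
    run = 0
    for ch in sub + "0":
        if ch == "1":
            run += 1
        else:
            if run:
                for l in range(1, run + 1):
                    meth[l - 1] += (run - l + 1) * count
            run = 0


def compute_block_mhl(records: Iterable[HaplotypeRecord], block: MHBlock,
                      min_block_reads: int = DEFAULT_MIN_BLOCK_READS
                      ) -> tuple[float, int]:
    """MHL of one block from one sample's reads; returns (value, supporting reads).

    Only pattern positions falling on block member sites contribute. The
    value is NaN (missing) when the total number of observed single-CpG
    windows is below ``min_block_reads``. Records not overlapping the block
    are ignored.
    """
    lo, hi = block.first_site, block.last_site
    meth: list[int] = []
    total: list[int] = []
    support = 0
    for rec in records:
        if rec.chrom != block.chrom:
            continue
        a = max(rec.start, lo)
        b = min(rec.start + len(rec.pattern) - 1, hi)
        if a > b:
            continue
        support += rec.count
        _window_counts(rec.pattern[a - rec.start: b - rec.start + 1], rec.count,
                       meth, total)
    if not total or total[0] < min_block_reads:
        return (math.nan, support)
    num = sum(l * meth[l - 1] / total[l - 1]
              for l in range(1, len(total) + 1) if total[l - 1] > 0)
    den = sum(l for l in range(1, len(total) + 1) if total[l - 1] > 0)
    return (num / den, support)


def build_mhl_matrix(records: Iterable[HaplotypeRecord], blocks: Sequence[MHBlock],
                     samples: Sequence[str] | None = None,
                     min_block_reads: int = DEFAULT_MIN_BLOCK_READS) -> MHLMatrix:
    """Blocks x samples MHL matrix; each cell scores that sample's reads on that block."""
    ids = [b.block_id for b in blocks]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate block ids")

    # per-chromosome sorted block ranges for overlap lookup
    by_chrom: dict[str, tuple[list[int], list[int], list[MHBlock]]] = {}
    for b in sorted(blocks, key=lambda b: (b.chrom, b.first_site)):
        starts, ends, blist = by_chrom.setdefault(b.chrom, ([], [], []))
        starts.append(b.first_site)
        ends.append(b.last_site)
        blist.append(b)

    cell_records: dict[tuple[str, str], list[HaplotypeRecord]] = {}
    seen_samples: list[str] = []
    seen = set()
    for rec in records:
        if rec.sample not in seen:
            seen.add(rec.sample)
            seen_samples.append(rec.sample)
        entry = by_chrom.get(rec.chrom)
        if entry is None:
            continue
        starts, ends, blist = entry
        r_lo, r_hi = rec.start, rec.start + len(rec.pattern) - 1
        i = bisect_right(starts, r_hi) - 1
        while i >= 0 and ends[i] >= r_lo:
            cell_records.setdefault((blist[i].block_id, rec.sample), []).append(rec)
            i -= 1

    cols = list(samples) if samples is not None else seen_samples
    values = pd.DataFrame(math.nan, index=ids, columns=cols, dtype=float)
    support = pd.DataFrame(0, index=ids, columns=cols, dtype=int)
    for b in blocks:
        for s in cols:
            recs = cell_records.get((b.block_id, s))
            if recs is None:
                continue
            v, n = compute_block_mhl(recs, b, min_block_reads)
            values.at[b.block_id, s] = v
            support.at[b.block_id, s] = n
    return MHLMatrix(values=values, support=support)


def filter_missing_blocks(matrix: MHLMatrix, policy: str = "any") -> MHLMatrix:
    """Drop blocks by missingness: 'any' (>=1 missing) or 'all' (missing everywhere)."""
    if policy not in ("any", "all"):
        raise ValueError(f"unknown policy {policy!r}")
    isna = matrix.values.isna()
    drop = isna.any(axis=1) if policy == "any" else isna.all(axis=1)
    keep = matrix.values.index[~drop]
    return MHLMatrix(values=matrix.values.loc[keep], support=matrix.support.loc[keep])


def compute_bin_methylation(records: Iterable[HaplotypeRecord], sites: CpGSiteTable,
                            bin_size: int = 10_000) -> pd.DataFrame:
    """Tile each chromosome in half-open bins and tally MC / MT / 5mC% = MC/(MC+MT).

    Every methylation call (each pattern position, weighted by read count)
    is assigned to exactly one bin by its CpG genomic position.
    """
    acc: dict[tuple[str, int], list[int]] = {}
    for rec in records:
        pos = sites.positions[rec.chrom]
        for k, ch in enumerate(rec.pattern):
            b = int(pos[rec.start + k]) // bin_size
            cell = acc.setdefault((rec.chrom, b), [0, 0])
            cell[0 if ch == "1" else 1] += rec.count
    rows = []
    for (chrom, b), (mc, mt) in sorted(acc.items()):
        rows.append((chrom, b * bin_size, (b + 1) * bin_size, mc, mt,
                     mc / (mc + mt) if mc + mt else math.nan))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "MC", "MT", "level"])


def element_methylation(records: Iterable[HaplotypeRecord], sites: CpGSiteTable,
                        track: AnnotationTrack) -> pd.DataFrame:
    """Per-element mean methylation MC/(MC+MT) over contained CpG calls.

    Elements may overlap; a call contributes to every element containing
    its position (half-open interval test). Level is NaN with no calls.
    """
    iv = track.intervals.reset_index(drop=True)
    mc = np.zeros(len(iv), dtype=np.int64)
    mt = np.zeros(len(iv), dtype=np.int64)
    by_chrom = {c: sub for c, sub in iv.groupby("chrom")}
    for rec in records:
        sub = by_chrom.get(rec.chrom)
        if sub is None:
            continue
        pos = sites.positions[rec.chrom]
        for k, ch in enumerate(rec.pattern):
            p = int(pos[rec.start + k])
            hit = sub.index[(sub["start"] <= p) & (p < sub["end"])]
            if ch == "1":
                mc[hit] += rec.count
            else:
                mt[hit] += rec.count
    out = iv.copy()
    out["MC"], out["MT"] = mc, mt
    tot = mc + mt
    with np.errstate(invalid="ignore"):
        out["level"] = np.where(tot > 0, mc / np.maximum(tot, 1), math.nan)
    return out


def profile_correlation(levels_a: pd.Series, levels_b: pd.Series) -> float:
    """Pearson r between two binned methylation profiles over shared bins.

    Bins missing in either profile are excluded; at least 3 shared bins and
    non-zero variance in both profiles are required.
    """
    joined = pd.concat([levels_a, levels_b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} shared non-missing bins (need >= 3)")
    a, b = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a methylation profile")
    return float(stats.pearsonr(a, b)[0])
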