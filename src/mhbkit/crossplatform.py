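"""Projection of the block classifier onto array beta values.

Array platforms report per-probe beta values without haplotype phase, so
blocks are summarized by the plain mean beta of their overlapping probes
and the same NMF discovery recipe is re-run on the region matrix — the
strategy used to carry a sequencing-derived classifier onto 450K/EPIC
validation cohorts.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BetaMatrix, MHBlock
from .subtype import (DEFAULT_RANK, DEFAULT_RUNS, DEFAULT_SPECIFICITY,
                      DEFAULT_TOP_K, SubtypeAssignment, classify)

log = logging.getLogger("mhbkit")


def map_probes_to_blocks(coords: pd.DataFrame,
                         blocks: Sequence[MHBlock]) -> pd.Series:
    """Map each probe (index probe_id; columns chrom, pos) to the block
    whose half-open interval [start, end) contains its position.

    Blocks must be disjoint, so the containing block is unique. Probes
    falling in no block are dropped with a logged count.
    """
    by_chrom: dict[str, list[MHBlock]] = {}
    for b in sorted(blocks, key=lambda b: (b.chrom, b.start)):
        lst = by_chrom.setdefault(b.chrom, [])
        if lst and b.start < lst[-1].end:
            raise ValueError(f"overlapping blocks {lst[-1].block_id} and {b.block_id}")
        lst.append(b)

    mapped: dict[str, str] = {}
    for pid, row in coords.iterrows():
        lst = by_chrom.get(row["chrom"])
        if not lst:
            continue
        starts = [b.start for b in lst]
        i = int(np.searchsorted(starts, row["pos"], side="right")) - 1
        if i >= 0 and row["pos"] < lst[i].end:
            mapped[pid] = lst[i].block_id
    n_drop = len(coords) - len(mapped)
    if n_drop:
        log.info("dropped %d probe(s) outside every block", n_drop)
    return pd.Series(mapped, name="block_id")


def summarize_region_beta(beta: BetaMatrix, probe_map: pd.Series) -> pd.DataFrame:
    """Region x samples matrix: mean of non-missing probe betas per block.

    A region value is missing only when every overlapping probe is missing
    for that sample.
    """
    if probe_map.empty:
        raise ValueError("empty probe-to-block map")
    sub = beta.values.loc[beta.values.index.intersection(probe_map.index)]
    grouped = sub.groupby(probe_map.loc[sub.index]).mean()
    grouped.index.name = "block_id"
    return grouped


def classify_external(regions: pd.DataFrame, top_k: int = DEFAULT_TOP_K,
                      rank: int = DEFAULT_RANK, runs: int = DEFAULT_RUNS,
                      seed: int = 0,
                      specificity: float = DEFAULT_SPECIFICITY) -> SubtypeAssignment:
    """Run the discovery recipe on a region-beta matrix from an external cohort.

    Rows with any missing value are dropped first; at least 2 complete rows
    and 2 samples must remain, and the matrix must not be degenerate
    (identical columns carry no clustering signal).
    """
    complete = regions.dropna(axis=0, how="any")
    if complete.shape[0] < 2 or complete.shape[1] < 2:
        raise ValueError(
            f"need >= 2 complete regions and >= 2 samples, got {complete.shape}")
    if (complete.std(axis=1, ddof=1) == 0).all():
        raise ValueError("degenerate region matrix: zero variance in every region")
    assignment, _ = classify(complete, top_k=top_k, rank=rank, runs=runs,
                             seed=seed, specificity=specificity)
    return assignment
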