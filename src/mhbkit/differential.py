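"""Differential MHB calling between sample groups and annotation enrichment.

Per block: two-sided Wilcoxon rank-sum test, Benjamini-Hochberg FDR across
tested blocks, and a hyper/hypo call requiring both the adjusted p-value
and a minimum absolute difference in group mean MHL. Enrichment of a
differential block set in an annotation class is log2(obs/exp), with the
expected fraction taken from the background (all tested) blocks so that
block ascertainment is controlled for.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AnnotationTrack, MHBlock, MHLMatrix

DEFAULT_DELTA_MIN = 0.2
DEFAULT_ALPHA = 0.05

HYPER, HYPO, NONE = "hyper", "hypo", "none"


def differential_blocks(matrix: MHLMatrix | pd.DataFrame,
                        group_a: Sequence[str], group_b: Sequence[str],
                        delta_min: float = DEFAULT_DELTA_MIN,
                        alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Call hyper-/hypomethylated blocks for group_a relative to group_b.

    A block is tested only when both groups have >= 2 non-missing values.
    Output columns: mean_a, mean_b, delta, pvalue, qvalue, call.
    """
    df = matrix.values if isinstance(matrix, MHLMatrix) else matrix
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = df[list(group_a)]
    b = df[list(group_b)]

    rows = []
    for bid in df.index:
        xa = a.loc[bid].dropna().to_numpy()
        xb = b.loc[bid].dropna().to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            rows.append((bid, np.nan, np.nan, np.nan, np.nan))
            continue
        if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
            p = 1.0  # identical constant groups: no evidence by construction
        else:
            p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        rows.append((bid, float(xa.mean()), float(xb.mean()),
                     float(xa.mean() - xb.mean()), p))
    out = pd.DataFrame(rows, columns=["block_id", "mean_a", "mean_b", "delta",
                                      "pvalue"]).set_index("block_id")

    tested = out["pvalue"].notna()
    out["qvalue"] = np.nan
    if tested.any():
        out.loc[tested, "qvalue"] = multipletests(out.loc[tested, "pvalue"],
                                                  method="fdr_bh")[1]
    out["call"] = NONE
    sig = tested & (out["qvalue"] <= alpha)
    out.loc[sig & (out["delta"] >= delta_min), "call"] = HYPER
    out.loc[sig & (out["delta"] <= -delta_min), "call"] = HYPO
    return out


def _block_overlaps_class(trees: dict[str, IntervalTree], block: MHBlock) -> bool:
    tree = trees.get(block.chrom)
    return bool(tree is not None and tree.overlap(block.start, block.end))


def annotation_enrichment(diff_ids: Iterable[str], background_ids: Iterable[str],
                          blocks: Sequence[MHBlock],
                          track: AnnotationTrack) -> pd.DataFrame:
    """log2(obs/exp) overlap enrichment of a differential block set per class.

    obs = fraction of differential blocks overlapping the class (>= 1 bp,
    half-open); exp = the same fraction among background blocks. The ratio
    is undefined (NaN, flagged) when exp = 0.
    """
    diff = set(diff_ids)
    bg = set(background_ids)
    if not diff:
        raise ValueError("empty differential set")
    if not diff <= bg:
        raise ValueError("differential ids must be a subset of background ids")
    by_id = {b.block_id: b for b in blocks}
    missing = (diff | bg) - set(by_id)
    if missing:
        raise ValueError(f"block ids without intervals: {sorted(missing)[:5]}")

    rows = []
    for cls, sub in track.intervals.groupby("label"):
        trees: dict[str, IntervalTree] = {}
        for chrom, csub in sub.groupby("chrom"):
            trees[chrom] = IntervalTree.from_tuples(
                zip(csub["start"], csub["end"]))
        n_diff = sum(_block_overlaps_class(trees, by_id[i]) for i in diff)
        n_bg = sum(_block_overlaps_class(trees, by_id[i]) for i in bg)
        obs = n_diff / len(diff)
        exp = n_bg / len(bg)
        if exp > 0:
            ratio = np.log2(obs / exp) if obs > 0 else -np.inf
            undefined = False
        else:
            ratio, undefined = np.nan, True
        rows.append((cls, n_diff, len(diff), n_bg, len(bg), obs, exp, ratio,
                     undefined))
    return pd.DataFrame(rows, columns=[
        "class", "n_diff_overlap", "n_diff", "n_bg_overlap", "n_bg",
        "obs_frac", "exp_frac", "log2_ratio", "undefined"]).set_index("class")
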