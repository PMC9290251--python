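"""Differential MHB calling, BH adjustment and annotation enrichment."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from mhbkit.core import AnnotationTrack, MHBlock
from mhbkit.differential import (HYPER, HYPO, NONE, annotation_enrichment,
                                 differential_blocks)
from conftest import brute_force_bh


def matrix_from(rows, samples):
    return pd.DataFrame(rows, index=[f"b{i}" for i in range(len(rows))],
                        columns=samples, dtype=float)


class TestDifferentialBlocks:
    def test_identical_groups_yield_no_calls(self):
        rng = np.random.default_rng(0)
        vals = rng.random((20, 5))
        df = matrix_from(np.hstack([vals, vals]),
                         [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)])
        res = differential_blocks(df, [f"a{i}" for i in range(5)],
                                  [f"b{i}" for i in range(5)])
        assert (res["call"] == NONE).all()

    def test_separated_block_called_hyper(self):
        rng = np.random.default_rng(1)
        rows = [np.concatenate([rng.normal(0.8, 0.05, 10).clip(0, 1),
                                rng.normal(0.2, 0.05, 10).clip(0, 1)])]
        # pad with null blocks so BH has something to adjust over
        for _ in range(9):
            rows.append(rng.random(20))
        samples = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        res = differential_blocks(matrix_from(rows, samples), samples[:10],
                                  samples[10:], delta_min=0.2, alpha=0.05)
        assert res.loc["b0", "call"] == HYPER
        assert res.loc["b0", "delta"] == pytest.approx(0.6, abs=0.1)

    def test_delta_below_threshold_never_called(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.55, 0.01, 10).clip(0, 1)
        b = rng.normal(0.45, 0.01, 10).clip(0, 1)
        samples = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        res = differential_blocks(matrix_from([np.concatenate([a, b])], samples),
                                  samples[:10], samples[10:], delta_min=0.2)
        # strongly significant but |delta| = 0.1 < 0.2
        assert res.loc["b0", "qvalue"] < 0.05
        assert res.loc["b0", "call"] == NONE

    def test_hypo_direction(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.2, 0.05, 8).clip(0, 1)
        b = rng.normal(0.8, 0.05, 8).clip(0, 1)
        samples = [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)]
        res = differential_blocks(matrix_from([np.concatenate([a, b])], samples),
                                  samples[:8], samples[8:])
        assert res.loc["b0", "call"] == HYPO

    def test_small_group_rejected(self):
        df = matrix_from([[0.1, 0.2, 0.3]], ["a1", "b1", "b2"])
        with pytest.raises(ValueError, match="at least 2"):
            differential_blocks(df, ["a1"], ["b1", "b2"])

    def test_blocks_with_missing_values_untested(self):
        df = matrix_from([[np.nan, 0.2, 0.8, 0.9], [0.1, 0.2, 0.8, 0.9]],
                         ["a1", "a2", "b1", "b2"])
        res = differential_blocks(df, ["a1", "a2"], ["b1", "b2"])
        assert np.isnan(res.loc["b0", "pvalue"])
        assert res.loc["b0", "call"] == NONE
        assert np.isfinite(res.loc["b1", "pvalue"])


class TestBHAdjustment:
    def test_matches_brute_force_step_up(self):
        """statsmodels fdr_bh against a literal step-up implementation."""
        rng = np.random.default_rng(4)
        for n in (1, 5, 100, 1000):
            p = rng.random(n)
            np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1],
                                       brute_force_bh(p), atol=1e-12)


def block_at(bid, start, end):
    return MHBlock(bid, "chr1", start, end, (0,))


class TestEnrichment:
    @pytest.fixture
    def setup(self):
        blocks = [MHBlock(f"b{i}", "chr1", i * 100, i * 100 + 10,
                          (i,)) for i in range(8)]
        track = AnnotationTrack(pd.DataFrame(
            [("chr1", 0, 110, "alu"),        # overlaps b0 and b1 only
             ("chr2", 0, 100, "elsewhere")],
            columns=["chrom", "start", "end", "label"]))
        return blocks, track

    def test_identity_when_diff_equals_background(self, setup):
        blocks, track = setup
        ids = [b.block_id for b in blocks]
        res = annotation_enrichment(ids, ids, blocks, track)
        assert res.loc["alu", "log2_ratio"] == pytest.approx(0.0)

    def test_twofold_enrichment(self, setup):
        blocks, track = setup
        ids = [b.block_id for b in blocks]
        # diff set: 2 of 4 in alu (obs 0.5); background: 2 of 8 (exp 0.25)
        res = annotation_enrichment(["b0", "b1", "b4", "b5"], ids, blocks, track)
        assert res.loc["alu", "obs_frac"] == pytest.approx(0.5)
        assert res.loc["alu", "exp_frac"] == pytest.approx(0.25)
        assert res.loc["alu", "log2_ratio"] == pytest.approx(1.0)

    def test_class_absent_from_background_is_flagged(self, setup):
        blocks, track = setup
        res = annotation_enrichment(["b4"], ["b4", "b5"], blocks, track)
        row = res.loc["elsewhere"]
        assert row["undefined"] and np.isnan(row["log2_ratio"])

    def test_empty_diff_and_non_subset_rejected(self, setup):
        blocks, track = setup
        ids = [b.block_id for b in blocks]
        with pytest.raises(ValueError, match="empty"):
            annotation_enrichment([], ids, blocks, track)
        with pytest.raises(ValueError, match="subset"):
            annotation_enrichment(["b0"], ["b1"], blocks, track)

    def test_planted_enrichment_recovered(self):
        """Hypomethylated blocks planted in an annotation class at twice the
        background rate give log2 ratio near 1."""
        rng = np.random.default_rng(5)
        ratios = []
        for rep in range(10):
            n, class_frac, n_diff = 500, 0.2, 100
            blocks = [MHBlock(f"b{i}", "chr1", i * 1000, i * 1000 + 100, (i,))
                      for i in range(n)]
            in_class = np.zeros(n, dtype=bool)
            in_class[rng.choice(n, int(n * class_frac), replace=False)] = True
            track = AnnotationTrack(pd.DataFrame(
                [("chr1", i * 1000, i * 1000 + 100, "cls")
                 for i in range(n) if in_class[i]],
                columns=["chrom", "start", "end", "label"]))
            # diff blocks land in the class at twice the background rate
            n_in = rng.binomial(n_diff, 2 * class_frac)
            chosen = np.concatenate([
                rng.choice(np.flatnonzero(in_class), n_in, replace=False),
                rng.choice(np.flatnonzero(~in_class), n_diff - n_in,
                           replace=False)])
            diff = [f"b{i}" for i in chosen]
            res = annotation_enrichment(diff, [b.block_id for b in blocks],
                                        blocks, track)
            obs, exp = res.loc["cls", ["obs_frac", "exp_frac"]]
            ratios.append(float(np.log2(obs / exp)))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.3)
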