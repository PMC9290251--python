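"""MHL scoring against the brute-force window oracle, plus bin/element
methylation and profile correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhbkit.core import AnnotationTrack, CpGSiteTable, MHBlock
from mhbkit.mhl import (build_mhl_matrix, compute_bin_methylation,
                        compute_block_mhl, element_methylation,
                        filter_missing_blocks, profile_correlation)
from conftest import brute_force_mhl, make_records


@pytest.fixture
def block3(tiny_sites):
    return MHBlock("b3", "chr1", 100, 121, (0, 1, 2))


class TestComputeBlockMHL:
    def test_two_cpg_discordant_reads(self, tiny_sites):
        block = MHBlock("b2", "chr1", 100, 111, (0, 1))
        recs = make_records([("10", 1), ("01", 1)])
        v, _ = compute_block_mhl(recs, block, min_block_reads=1)
        assert v == pytest.approx(1 / 6)

    def test_three_cpg_mixed_reads(self, block3):
        recs = make_records([("111", 1), ("110", 1), ("000", 1), ("101", 1)])
        v, _ = compute_block_mhl(recs, block3, min_block_reads=1)
        assert v == pytest.approx(25 / 72)

    def test_fully_methylated_reads_give_one(self, block3):
        recs = make_records([("111", 8)])
        v, n = compute_block_mhl(recs, block3, min_block_reads=1)
        assert v == 1.0 and n == 8

    @pytest.mark.parametrize("p", [0.0, 0.25, 0.5, 1.0])
    def test_concordant_read_limit(self, block3, p):
        """All-or-nothing reads spanning the block: MHL equals the
        methylated-read fraction exactly."""
        n_meth = int(p * 8)
        recs = make_records([("111", n_meth)] if n_meth else [])
        recs += make_records([("000", 8 - n_meth)] if 8 - n_meth else [])
        v, _ = compute_block_mhl(recs, block3, min_block_reads=1)
        assert v == pytest.approx(p, abs=1e-15)

    def test_partial_reads_contribute_contained_windows_only(self, block3):
        # read "11" on sites (1,2): windows l=1 x2, l=2 x1; no l=3 windows
        recs = make_records([("11", 1)], start=1)
        v, _ = compute_block_mhl(recs, block3, min_block_reads=1)
        assert v == pytest.approx((1 * 1.0 + 2 * 1.0) / 3)

    def test_non_overlapping_record_ignored(self, block3):
        recs = make_records([("1", 5)], start=9)
        v, n = compute_block_mhl(recs, block3, min_block_reads=1)
        assert math.isnan(v) and n == 0

    def test_missing_below_min_reads(self, block3):
        recs = make_records([("111", 1)])
        v, n = compute_block_mhl(recs, block3, min_block_reads=5)
        assert math.isnan(v) and n == 1

    def test_matches_brute_force_on_random_instances(self, block3):
        rng = np.random.default_rng(3)
        sites = CpGSiteTable({"c": np.arange(6) * 2})
        for _ in range(300):
            k = int(rng.integers(1, 7))
            block = MHBlock("b", "c", 0, 2 * k - 1 or 1, tuple(range(k)))
            pats = []
            for _ in range(int(rng.integers(1, 21))):
                lo = int(rng.integers(0, k))
                hi = int(rng.integers(lo, k))
                pat = "".join(rng.choice(["0", "1"], hi - lo + 1))
                pats.append((lo, pat, int(rng.integers(1, 4))))
            recs = [r for lo, p, c in pats
                    for r in make_records([(p, c)], chrom="c", start=lo)]
            got, _ = compute_block_mhl(recs, block, min_block_reads=1)
            expected = brute_force_mhl([(p, c) for _, p, c in pats])
            assert got == pytest.approx(expected, abs=1e-12)

    def test_mhl_never_exceeds_mean_methylation(self):
        rng = np.random.default_rng(5)
        block = MHBlock("b", "c", 0, 9, tuple(range(5)))
        for _ in range(100):
            pats = [("".join(rng.choice(["0", "1"], 5)), 1) for _ in range(10)]
            recs = make_records(pats, chrom="c")
            v, _ = compute_block_mhl(recs, block, min_block_reads=1)
            m1 = np.mean([int(ch) for p, _ in pats for ch in p])
            assert v <= m1 + 1e-12

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 3),
                              st.text(alphabet="01", min_size=1, max_size=4),
                              st.integers(1, 3)),
                    min_size=1, max_size=8))
    def test_oracle_agreement_property(self, reads):
        """Any mix of partially overlapping reads matches the enumerator."""
        block = MHBlock("b", "c", 0, 7, (0, 1, 2, 3))
        reads = [(lo, pat[:4 - lo], c) for lo, pat, c in reads]
        recs = [r for lo, p, c in reads
                for r in make_records([(p, c)], chrom="c", start=lo)]
        got, _ = compute_block_mhl(recs, block, min_block_reads=1)
        expected = brute_force_mhl([(p, c) for _, p, c in reads])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_count_splitting_and_order(self, block3):
        recs = make_records([("110", 3), ("011", 2)])
        split = make_records([("110", 1)] * 3 + [("011", 1)] * 2)[::-1]
        v1, _ = compute_block_mhl(recs, block3, min_block_reads=1)
        v2, _ = compute_block_mhl(split, block3, min_block_reads=1)
        assert v1 == v2


class TestMatrix:
    def test_cells_match_direct_computation(self, small_cohort):
        blocks = small_cohort.blocks[:5]
        mat = build_mhl_matrix(small_cohort.records, blocks)
        for b in blocks:
            for s in mat.samples:
                recs = [r for r in small_cohort.records
                        if r.sample == s and r.chrom == b.chrom
                        and r.start <= b.last_site
                        and r.start + len(r.pattern) - 1 >= b.first_site]
                v, n = compute_block_mhl(recs, b)
                cell = mat.values.at[b.block_id, s]
                assert (math.isnan(v) and math.isnan(cell)) or cell == pytest.approx(v)
                assert mat.support.at[b.block_id, s] == n

    def test_sample_without_reads_is_missing(self, tiny_sites):
        block = MHBlock("b", "chr1", 100, 121, (0, 1, 2))
        recs = make_records([("111", 6)], sample="A")
        mat = build_mhl_matrix(recs, [block], samples=["A", "B"])
        assert mat.values.at["b", "A"] == 1.0
        assert math.isnan(mat.values.at["b", "B"])

    def test_duplicate_block_ids_rejected(self, tiny_sites):
        b1 = MHBlock("b", "chr1", 100, 121, (0, 1, 2))
        b2 = MHBlock("b", "chr1", 150, 171, (5, 6, 7))
        with pytest.raises(ValueError, match="duplicate"):
            build_mhl_matrix([], [b1, b2])

    @pytest.mark.parametrize("policy,expected_rows", [("all", 2), ("any", 1)])
    def test_filter_missing_policies(self, policy, expected_rows):
        values = pd.DataFrame(
            [[0.5, 0.5], [np.nan, 0.4], [np.nan, np.nan]],
            index=["full", "partial", "empty"], columns=["A", "B"])
        from mhbkit.core import MHLMatrix
        mat = MHLMatrix(values=values, support=values.notna().astype(int))
        out = filter_missing_blocks(mat, policy=policy)
        assert len(out.values) == expected_rows
        assert list(out.values.index) == ["full", "partial"][:expected_rows]


class TestBinsAndElements:
    def test_bin_level_and_boundary(self):
        sites = CpGSiteTable({"chr1": np.array([50, 9_999, 10_000, 15_000])})
        recs = make_records([("1101", 1)])
        bins = compute_bin_methylation(recs, sites)
        first = bins[bins["start"] == 0].iloc[0]
        second = bins[bins["start"] == 10_000].iloc[0]
        assert (first["MC"], first["MT"]) == (2, 0)
        # position 10000 falls in the second half-open bin with 15000
        assert (second["MC"], second["MT"]) == (1, 1)
        assert second["level"] == 0.5
        assert second["end"] == 20_000

    def test_call_totals_conserved(self, small_cohort):
        bins = compute_bin_methylation(small_cohort.records, small_cohort.sites,
                                       bin_size=1000)
        total_calls = sum(len(r.pattern) * r.count for r in small_cohort.records)
        assert (bins["MC"] + bins["MT"]).sum() == total_calls

    def test_element_levels_and_boundaries(self):
        tss = 5_000
        sites = CpGSiteTable({"chr1": np.array(
            [tss - 500, tss + 999, tss + 1000, tss + 1001])})
        track = AnnotationTrack(pd.DataFrame(
            [("chr1", tss - 1000, tss + 1000, "promoter")],
            columns=["chrom", "start", "end", "label"]))
        recs = make_records([("1011", 1)])
        out = element_methylation(recs, sites, track)
        # only the first two CpGs fall inside the half-open promoter
        assert (out.iloc[0]["MC"], out.iloc[0]["MT"]) == (1, 1)
        assert out.iloc[0]["level"] == pytest.approx(0.5)

    def test_element_ratio(self, tiny_sites):
        track = AnnotationTrack(pd.DataFrame(
            [("chr1", 0, 1000, "e")], columns=["chrom", "start", "end", "label"]))
        recs = make_records([("1000", 1)])
        out = element_methylation(recs, tiny_sites, track)
        assert out.iloc[0]["level"] == pytest.approx(0.25)


class TestProfileCorrelation:
    def test_identical_and_reflected(self):
        a = pd.Series([0.1, 0.5, 0.9, 0.3])
        assert profile_correlation(a, a) == pytest.approx(1.0)
        assert profile_correlation(a, 1 - a) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        a = pd.Series([0.0, 1.0, 2.0])
        b = pd.Series([0.0, 2.0, 1.0])
        assert profile_correlation(a, b) == pytest.approx(0.5)

    def test_too_few_shared_bins(self):
        a = pd.Series([0.1, np.nan, 0.3, np.nan])
        b = pd.Series([0.2, 0.4, np.nan, 0.5])
        with pytest.raises(ValueError, match="shared"):
            profile_correlation(a, b)

    def test_zero_variance_rejected(self):
        a = pd.Series([0.5, 0.5, 0.5])
        b = pd.Series([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="variance"):
            profile_correlation(a, b)
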