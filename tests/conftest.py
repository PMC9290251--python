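"""Shared fixtures and independent brute-force oracles.

The oracles re-derive each quantity by direct enumeration and never call
the implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from mhbkit.core import CpGSiteTable, HaplotypeRecord, MHBlock
from mhbkit.simulate import SimulationConfig, generate_cohort


# ------------------------------------------------------------------ oracles

def brute_force_mhl(patterns: list[tuple[str, int]],
                    min_block_reads: int = 1) -> float:
    """MHL by explicit enumeration of every within-read window.

    ``patterns`` are read segments already restricted to block member CpGs,
    with multiplicities. Weights are w_l = l over l = 1..max observed length.
    """
    L = max((len(p) for p, _ in patterns), default=0)
    meth = [0] * L
    tot = [0] * L
    for pat, count in patterns:
        m = len(pat)
        for l in range(1, m + 1):
            for s in range(m - l + 1):
                tot[l - 1] += count
                if all(ch == "1" for ch in pat[s:s + l]):
                    meth[l - 1] += count
    if L == 0 or tot[0] < min_block_reads:
        return math.nan
    num = sum(l * meth[l - 1] / tot[l - 1] for l in range(1, L + 1) if tot[l - 1])
    den = sum(l for l in range(1, L + 1) if tot[l - 1])
    return num / den


def brute_force_runs(defined_linked: list[bool], min_cpgs: int) -> list[tuple[int, int]]:
    """Maximal qualifying runs over sites 0..n from adjacent-pair link flags.

    ``defined_linked[i]`` says whether the pair (i, i+1) is defined and
    above threshold. Returns (first_site, last_site) tuples, found by
    checking every candidate interval for qualification and maximality.
    """
    n_sites = len(defined_linked) + 1
    runs = []
    for a in range(n_sites):
        for b in range(a + min_cpgs - 1, n_sites):
            if all(defined_linked[k] for k in range(a, b)):
                left_ext = a > 0 and defined_linked[a - 1]
                right_ext = b < n_sites - 1 and defined_linked[b]
                if not left_ext and not right_ext:
                    runs.append((a, b))
    return sorted(set(runs))


def brute_force_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values via the literal step-up rule."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def logrank_by_hand(time, event, group):
    """Log-rank chi-square from explicit O/E/V tables at each event time."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    g1 = np.unique(group)[0]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == g1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == g1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


# ----------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def tiny_sites() -> CpGSiteTable:
    return CpGSiteTable({"chr1": np.arange(20) * 10 + 100,
                         "chr2": np.arange(5) * 50})


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down cohort for fast unit tests (defaults stay untouched)."""
    return SimulationConfig(n_samples=10, n_blocks=60, n_signature_blocks=10,
                            coverage=20.0)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, seed=11)


def make_records(patterns: list[tuple[str, int]], chrom: str = "chr1",
                 start: int = 0, sample: str = "S") -> list[HaplotypeRecord]:
    return [HaplotypeRecord(sample=sample, chrom=chrom, start=start,
                            pattern=p, count=c) for p, c in patterns]
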