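"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes, so every stage is
testable without sequencing data: two latent sample subtypes; a set of
signature blocks hypermethylated in one subtype by a fixed shift delta;
read-level haplotypes with tunable within-read concordance rho and Poisson
coverage; survival under a subtype hazard ratio with independent censoring;
and an array-style beta matrix derived from the same ground truth.

Per read, a latent methylation state is drawn from the block's
subtype-specific target level; each CpG copies the latent state with
probability rho and is drawn independently from the target level with
probability 1 - rho. rho -> 1 gives fully concordant haplotypes (where MHL
equals the methylated-read fraction), rho -> 0 independent CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (BetaMatrix, CpGSiteTable, HaplotypeRecord, MHBlock,
                   block_from_sites)

CHROM = "chr1"


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for a synthetic two-subtype cohort.

    Defaults describe a 50-sample cohort split evenly between subtypes,
    500 blocks of 4-8 CpGs of which 60 are hypermethylated by delta = 0.3
    in the second ("high") subtype, 30x mean read coverage per block with
    within-read concordance 0.9, subtype hazard ratio 3 with 30% censoring,
    and an array arm with 10 probes per block and beta noise SD 0.05.
    """

    n_samples: int = 50
    proportions: tuple[float, float] = (0.5, 0.5)
    n_blocks: int = 500
    n_signature_blocks: int = 60
    cpgs_per_block: tuple[int, int] = (4, 8)
    baseline_beta_params: tuple[float, float] = (2.0, 2.0)
    delta: float = 0.3
    rho: float = 0.9
    coverage: float = 30.0
    read_span: str = "block"            # reads span the whole block
    baseline_hazard: float = 0.03       # events per month for the low subtype
    hazard_ratio: float = 3.0
    censoring_fraction: float = 0.3
    probes_per_block: int = 10
    beta_noise_sd: float = 0.05
    cpg_spacing: int = 25               # bp between CpGs inside a block
    block_gap: int = 500                # bp between consecutive blocks

    def validate(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.n_signature_blocks > self.n_blocks:
            raise ValueError("more signature blocks than blocks")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring fraction must be in [0, 1)")
        if self.read_span != "block":
            raise ValueError(f"unsupported read span mode {self.read_span!r}")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort."""

    subtype: pd.Series                  # sample -> "low" | "high"
    signature_blocks: list[str]
    targets: pd.DataFrame               # block x {low, high} target methylation
    blocks: list[MHBlock]
    sites: CpGSiteTable
    config: SimulationConfig


@dataclass
class SyntheticCohort:
    records: list[HaplotypeRecord]
    sites: CpGSiteTable
    blocks: list[MHBlock]
    clinical: pd.DataFrame
    truth: SyntheticTruth


def _layout_genome(cfg: SimulationConfig, rng: np.random.Generator
                   ) -> tuple[CpGSiteTable, list[MHBlock]]:
    lo, hi = cfg.cpgs_per_block
    n_cpgs = rng.integers(lo, hi + 1, size=cfg.n_blocks)
    positions: list[int] = []
    blocks: list[MHBlock] = []
    cursor = 1000
    site = 0
    for i, k in enumerate(n_cpgs):
        pos = [cursor + j * cfg.cpg_spacing for j in range(k)]
        positions.extend(pos)
        sites_idx = range(site, site + k)
        site += int(k)
        cursor = pos[-1] + cfg.block_gap
        blocks.append(MHBlock(block_id=f"B{i:04d}", chrom=CHROM,
                              start=pos[0], end=pos[-1] + 1,
                              sites=tuple(sites_idx)))
    table = CpGSiteTable({CHROM: np.asarray(positions)})
    return table, blocks


def _draw_targets(cfg: SimulationConfig, blocks: list[MHBlock],
                  rng: np.random.Generator) -> tuple[pd.DataFrame, list[str]]:
    a, b = cfg.baseline_beta_params
    base = rng.beta(a, b, size=cfg.n_blocks)
    sig_idx = np.sort(rng.choice(cfg.n_blocks, size=cfg.n_signature_blocks,
                                 replace=False))
    is_sig = np.zeros(cfg.n_blocks, dtype=bool)
    is_sig[sig_idx] = True
    low = np.clip(base, 0.02, 0.98)
    # signature baselines are rescaled so low + delta stays inside [0, 0.95]
    low[is_sig] = 0.05 + base[is_sig] * (0.90 - cfg.delta)
    high = low.copy()
    high[is_sig] = low[is_sig] + cfg.delta
    ids = [bl.block_id for bl in blocks]
    targets = pd.DataFrame({"low": low, "high": high}, index=ids)
    return targets, [ids[i] for i in sig_idx]


def _subtype_allocation(cfg: SimulationConfig) -> pd.Series:
    """Deterministic allocation: subtype counts match proportions exactly."""
    n_low = round(cfg.n_samples * cfg.proportions[0])
    names = [f"S{i:03d}" for i in range(cfg.n_samples)]
    labels = ["low"] * n_low + ["high"] * (cfg.n_samples - n_low)
    return pd.Series(labels, index=names, name="subtype")


def _simulate_reads(cfg: SimulationConfig, blocks: list[MHBlock],
                    targets: pd.DataFrame, subtype: pd.Series,
                    rng: np.random.Generator) -> list[HaplotypeRecord]:
    records: list[HaplotypeRecord] = []
    for sample, st in subtype.items():
        for bl in blocks:
            t = float(targets.at[bl.block_id, st])
            n = int(rng.poisson(cfg.coverage))
            if n == 0:
                continue
            k = bl.n_cpgs
            latent = rng.random(n) < t
            indep = rng.random((n, k)) < t
            copy = rng.random((n, k)) < cfg.rho
            pat = np.where(copy, latent[:, None], indep).astype(np.uint8)
            uniq, counts = np.unique(pat, axis=0, return_counts=True)
            for row, c in zip(uniq, counts):
                records.append(HaplotypeRecord(
                    sample=sample, chrom=bl.chrom, start=bl.first_site,
                    pattern="".join("1" if x else "0" for x in row),
                    count=int(c)))
    return records


def _simulate_survival(cfg: SimulationConfig, subtype: pd.Series,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Exponential event times; hazard multiplied by HR for the high subtype.

    Censoring times are exponential with rate h * c / (1 - c), which makes
    the expected censoring fraction exactly c in each subtype.
    """
    rows = []
    for sample, st in subtype.items():
        h = cfg.baseline_hazard * (cfg.hazard_ratio if st == "high" else 1.0)
        row = {"sample": sample}
        for prefix, mult in (("os", 1.0), ("pfs", 1.5)):
            rate = h * mult
            t_event = rng.exponential(1.0 / rate)
            if cfg.censoring_fraction > 0:
                c_rate = rate * cfg.censoring_fraction / (1 - cfg.censoring_fraction)
                t_cens = rng.exponential(1.0 / c_rate)
            else:
                t_cens = np.inf
            row[f"{prefix}_time"] = float(min(t_event, t_cens))
            row[f"{prefix}_event"] = int(t_event <= t_cens)
        row["age"] = float(np.round(rng.normal(65, 8), 1))
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample", "os_time", "os_event",
                                       "pfs_time", "pfs_event", "age"])


def generate_cohort(config: SimulationConfig | None = None,
                    seed: int = 0) -> SyntheticCohort:
    """Generate reads, sites, true blocks, clinical data and ground truth."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sites, blocks = _layout_genome(cfg, rng)
    targets, sig_ids = _draw_targets(cfg, blocks, rng)
    subtype = _subtype_allocation(cfg)
    records = _simulate_reads(cfg, blocks, targets, subtype, rng)
    clinical = _simulate_survival(cfg, subtype, rng)
    truth = SyntheticTruth(subtype=subtype, signature_blocks=sig_ids,
                           targets=targets, blocks=blocks, sites=sites,
                           config=cfg)
    return SyntheticCohort(records=records, sites=sites, blocks=blocks,
                           clinical=clinical, truth=truth)


def generate_array_cohort(truth: SyntheticTruth, seed: int = 0
                          ) -> BetaMatrix:
    """Array arm from the same truth: probes at member CpG positions.

    Probe positions are sampled uniformly (with replacement) from the
    block's member CpGs; beta = subtype target level plus Gaussian noise,
    clipped to [0, 1].
    """
    cfg = truth.config
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    samples = list(truth.subtype.index)
    probe_rows = []
    values = []
    for bl in truth.blocks:
        pos = [truth.sites.position(bl.chrom, s) for s in bl.sites]
        chosen = rng.choice(pos, size=cfg.probes_per_block, replace=True)
        t_low = truth.targets.at[bl.block_id, "low"]
        t_high = truth.targets.at[bl.block_id, "high"]
        for j, p in enumerate(sorted(int(x) for x in chosen)):
            probe_rows.append((f"p_{bl.block_id}_{j}", bl.chrom, p))
            t = np.where(truth.subtype.to_numpy() == "high", t_high, t_low)
            beta = np.clip(t + rng.normal(0, cfg.beta_noise_sd, len(samples)),
                           0.0, 1.0)
            values.append(beta)
    coords = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos"]
                          ).set_index("probe_id")
    df = pd.DataFrame(values, index=coords.index, columns=samples)
    return BetaMatrix(values=df, coords=coords)


def generate_null_cohort(config: SimulationConfig | None = None,
                         seed: int = 0) -> SyntheticCohort:
    """Cohort with no signature blocks and hazard ratio 1.

    Both subtypes are statistically identical; useful for type-I error and
    false-labeling checks.
    """
    cfg = config or SimulationConfig()
    cfg = replace(cfg, n_signature_blocks=0, hazard_ratio=1.0, delta=cfg.delta)
    return generate_cohort(cfg, seed=seed)
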