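# mhbkit

Tumor methylation-subtype discovery from read-level bisulfite data.
`mhbkit` takes read-level CpG methylation haplotypes (the ordered
methylated/unmethylated pattern each sequencing read shows over consecutive
CpGs), partitions the genome into **methylation haplotype blocks (MHBs)** —
runs of tightly coupled CpG sites — scores each block with the
**methylation haplotype load (MHL)**, and discovers **Methy-High /
Methy-Low epi-clusters** by rank-2 non-negative matrix factorization. The
classifier can be projected onto array-style beta matrices (450K/EPIC) for
external cohorts, and cluster labels are tied to outcomes via Kaplan–Meier,
log-rank and Cox proportional-hazards analysis. A synthetic-cohort
generator with known ground truth makes every stage testable end to end.

It is written for computational epigenomics researchers who have
post-alignment methylation haplotype calls (WGBS or targeted bisulfite
sequencing) and want a tested, scriptable implementation of the block-level
workflow rather than a collection of one-off scripts.

## The model

**Blocks.** For each adjacent CpG pair, reads covering both sites are pooled
across samples into joint haplotype counts n₁₁, n₁₀, n₀₁, n₀₀, and coupling
is the two-locus linkage statistic

    r² = D² / (p₁·(1−p₁·) p·₁(1−p·₁)),  D = p₁₁ − p₁· p·₁ .

An MHB is a maximal run of consecutive CpGs in which every adjacent pair has
defined r² ≥ 0.5 (defaults: ≥ 3 CpGs, ≥ 10 informative reads per pair).

**MHL.** For substring lengths l = 1..L (L the longest within-block stretch
observed on a read), let mₗ be the fraction of fully methylated contiguous
windows of l member CpGs among all such windows across reads. Then

    MHL = Σₗ l·mₗ / Σₗ l .

m₁ is the plain mean methylation; the length weighting makes MHL reward long
concordant methylation runs, so discordant haplotypes score far below their
per-CpG average.

**Subtypes.** After dropping blocks with missing MHL and keeping the top
20,000 most variable blocks (by SD across samples), a rank-2
multiplicative-update NMF (Frobenius loss, best of 100 seeded random
restarts) factorizes the matrix; each sample goes to its dominant component,
per-component signature blocks are extracted by basis-row specificity, and
the cluster with the higher mean MHL over signature blocks is labeled
Methy-High (the hypermethylated, worse-prognosis epi-cluster).

## Worked example

```sh
python examples/03_mhl_scoring.py
```

```
concordant reads (half fully methylated): MHL = 0.5000
discordant reads (same 50% mean methylation): MHL = 0.0833
```

Both read sets have mean methylation 0.5; only the concordant one (pure
`111`/`000` haplotypes) keeps MHL at 0.5, while shuffled haplotypes are
down-weighted by the length terms — the property that makes block-level
haplotype signal more discriminative than per-CpG averages.

```sh
python examples/04_subtype_discovery.py
```

```
Methy-Low     50.0
Methy-High    50.0
signature blocks per component: {1: 0, 2: 14}
adjusted Rand index vs simulated truth: 1.000
```

On a 20-sample synthetic cohort the NMF recipe recovers the two simulated
subtypes exactly (ARI = 1.0) and labels the hypermethylated one Methy-High;
the percentages are the cluster shares of the cohort. The other scripts in
`examples/` walk through block detection, array projection, differential /
enrichment analysis and survival association the same way.

A `mhbkit` command-line entry point mirrors the library
(`simulate | blocks | mhl | classify | project | diff | enrich | survival`)
for shell pipelines.

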