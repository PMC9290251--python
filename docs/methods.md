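# Methods

## Scope and data model

`mhbkit` operates downstream of bisulfite alignment: its input is read-level
methylation haplotype calls, i.e. for each read the ordered pattern of
methylated (`1`) / unmethylated (`0`) states over consecutive CpG sites,
with a multiplicity for identical reads. CpGs are strand-collapsed to the
forward-strand C and identified by their rank within a chromosome's ordered
position table, so haplotype patterns are unambiguous under any reference
assembly. All coordinates are 0-based half-open; written matrices use the
literal `NA` for missing values. Alignment, duplicate handling and
bisulfite conversion QC are out of scope.

## Block detection

Coupling between adjacent CpGs i and i+1 is the standard two-locus linkage
r², computed from joint haplotype counts over reads covering both sites,
pooled across all samples (tumor and normal alike — pooling is symmetric
and block detection is sample-label invariant). r² is *undefined*, and
breaks a run, when fewer than `min_pair_reads` (default 10) informative
reads exist or either site is monomorphic in the pooled reads: a
monomorphic pair carries no linkage evidence, and treating it as perfectly
coupled would glue unrelated runs together. Blocks are maximal runs of
consecutive sites in which every adjacent pair has defined r² ≥ `r2_min`
(default 0.5) and which contain at least `min_cpgs` sites (default 3).
Only adjacent pairs are scored — runs are fully determined by them, and
windowed all-pairs definitions are deliberately not implemented. The
partitioner is validated against an exhaustive maximal-run enumerator on
random tracks.

## MHL scoring

For one block and one sample, every read segment overlapping the block is
clipped to the member sites (a read contributes only windows it fully
contains; unobserved CpG states are never imputed, and windows never span
two reads). For l = 1..L, with L the longest clipped segment observed,

m_l = (# fully methylated contiguous windows of l member CpGs) / (# such windows),
MHL = Σ l·m_l / Σ l.

Linear-in-length weights w_l = l are the convention of the metric's
originating work; they are config-exposed in the brute-force test oracle
but fixed in the scorer. An entry is missing when fewer than
`min_block_reads` (default 5) single-CpG windows were observed — a variance
guard at low coverage; the supporting read count is recorded alongside each
entry. Useful identities, both tested: with fully concordant reads spanning
the block MHL equals the fraction of methylated reads, and MHL ≤ m₁ always.

Bin-level (default 10 kb, tiled from coordinate 0 per chromosome) and
annotation-element-level summaries use plain mean methylation
MC/(MC+MT); pairwise profile similarity is Pearson correlation over bins
non-missing in both profiles (≥ 3 shared bins, non-zero variance required).

## Missingness policy

"Drop blocks with NA" is ambiguous between drop-if-any and drop-if-all;
both are implemented (`filter_missing_blocks(policy="any"|"all")`). The
NMF input uses `any` because the factorization cannot consume missing
values; `all` is retained for descriptive summaries.

## Subtype discovery

The complete MHL matrix is restricted to the `top_k` = 20,000 most variable
blocks (sample SD, ddof = 1, stable sort; fewer rows pass through with a
warning). Factorization is non-negative matrix factorization with
multiplicative updates under the Frobenius objective (rank 2, 500 max
iterations, relative-change tolerance 1e−6), restarted from 100 random
initializations whose seeds are drawn from one master seed stream — so runs
1..n are reproducible and extendable — keeping the run with minimum
reconstruction error. The factorization backend is scikit-learn's
multiplicative-update solver; consensus clustering across runs is
deliberately out of scope (best-of-runs is the reference behavior for a
fixed rank).

Signature extraction: each basis row is normalized to sum 1; a block is a
component's signature when its normalized weight is ≥ 0.75 on that
component *and* its unnormalized row maximum is at least the median row
maximum (excluding near-zero rows). This concrete deterministic rule stands
in for a library-default feature extractor whose exact behavior is not
specified anywhere; the threshold is exposed. Samples take the component
with the largest coefficient (ties to the lower index, for determinism).
The cluster with the higher mean MHL over the union of signature blocks is
labeled Methy-High; if a component has no signature blocks the mean is
taken over all selected blocks instead (warned). In practice one component
often models the shared baseline and contributes few specific rows; the
fallback keeps labeling well-defined in that case.

## Cross-platform projection

Array probes carry no haplotype phase, so blocks are summarized on arrays
by the plain mean beta of overlapping probes (probe position contained in
the half-open block interval; blocks must be disjoint so the mapping is
unique). External cohorts are re-factorized independently with the same
select/factorize/extract/label recipe rather than projected onto the
discovery basis — matching how array validation cohorts are typically
re-clustered. Rows with any missing region value are dropped first; a
degenerate matrix (zero variance everywhere) is an error.

## Differential blocks and enrichment

Per block, a two-sided Wilcoxon rank-sum test between groups (each needing
≥ 2 non-missing values; otherwise the block is untested), Benjamini–
Hochberg FDR across tested blocks, and a call of hyper/hypo requiring
adjusted p ≤ 0.05 *and* |Δ mean MHL| ≥ 0.2. These DMR-style criteria are
conventional defaults, fully config-exposed, because no canonical choice
exists for block-level calls. Enrichment of a differential set in an
annotation class is log2(obs/exp) with obs/exp the overlap fractions
(any-overlap, ≥ 1 bp, half-open) among differential and background blocks
respectively; the background is all tested blocks, which controls for block
ascertainment. exp = 0 yields a flagged undefined ratio.

## Survival

Kaplan–Meier estimation, the two-group log-rank test and Cox
proportional-hazards fits (Efron tie handling, Newton iterations, 95% Wald
intervals) are computed via lifelines behind the module surface; tests
check them against hand-computed product-limit tables, explicit O/E/V
log-rank sums, and the identity between the Cox score test at β = 0 and the
log-rank statistic. Times are months; administrative truncation at a fixed
horizon is available as a config option (applied as censoring). The
univariate-then-multivariate covariate workflow is a recipe: covariates
with univariate Wald p below a threshold (default 0.05) enter the
multivariate fit. Note one subtlety: duplicating a dataset creates ties,
so under Efron handling the duplicated-data estimate is only near-identical
to the original (the invariance is exact under Breslow, which lifelines
does not implement).

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes, with one
interpretable concordance knob instead of a per-CpG correlation matrix:
per read a latent state is drawn from the block's subtype-specific target
level t; each CpG copies the latent state with probability ρ and is drawn
independently from t otherwise. ρ → 1 gives fully concordant haplotypes
(MHL → methylated-read fraction), ρ → 0 independent CpGs. Defaults, used by
the acceptance suites: 50 samples split 50/50 between subtypes, 500 blocks
of 4–8 CpGs (25 bp spacing, 500 bp gaps on one synthetic chromosome), 60
signature blocks, per-block baseline methylation Beta(2,2), signature shift
δ = 0.3 (signature baselines rescaled into [0.05, 0.95−δ] so the shifted
level stays inside [0,1] and the realized shift is exactly δ), ρ = 0.9,
Poisson coverage 30× with reads spanning the whole block, hazard ratio 3
for the hypermethylated subtype on an exponential baseline (0.03
events/month; PFS uses 1.5× the OS hazard), 30% censoring via an
independent exponential censor with rate h·c/(1−c) (which gives expected
censoring fraction exactly c), and an array arm with 10 probes per block
and truncated-Gaussian beta noise (SD 0.05, clipped to [0,1]). Subtype
counts follow the configured proportions deterministically, not by
sampling. Array probes are placed uniformly *with replacement* on member
CpG positions, since the default probe count exceeds the CpGs of a small
block; distinct probe ids may share a position.

What the generator does **not** emulate: sequencing error and bisulfite
conversion failure, read-length variation and partial block coverage,
copy-number effects on coverage, probe-specific array biases, covariate-
dependent hazards, and genome-scale block counts. Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
structure under idealized noise — not performance on real cohorts, where
missingness, batch effects and weaker separations dominate.

## Problem sizes and determinism

The test and acceptance suites use 20 seeded replicates of the default
cohort for subtype recovery and label transfer, 1,000 random instances for
the MHL-vs-enumeration check, 500 random tracks for the partition check,
2,000 null replicates (50 + 50 samples) for log-rank calibration and 200
replicates (n = 200) for Cox CI coverage — sizes chosen so the whole cycle
runs in minutes on a single CPU while keeping Monte-Carlo error well inside
the asserted bounds. Every stochastic step derives from an explicit seed;
NMF restart seeds come from a spawned stream so adding runs never changes
earlier ones.

## Known limitations

- Block detection needs pooled pair coverage; sparse data fragments runs
  at undefined pairs rather than bridging them.
- The signature-extraction rule is a declared stand-in, not a reimplementation
  of any particular library's feature extractor.
- Rank selection is not implemented; rank 2 is the supported design point.
- Genome-wide block counts at cohort scale (hundreds of thousands) are out
  of reach of the synthetic scale and are not claimed.
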