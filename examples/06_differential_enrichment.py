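"""Call differential blocks between subtypes and test annotation enrichment.

Per block: Wilcoxon rank-sum, Benjamini-Hochberg FDR <= 0.05 and a minimum
mean-MHL difference of 0.2. Enrichment of the hypermethylated set in an
annotation class is log2 of observed vs expected overlap fractions, with
the expectation taken over all tested blocks.
"""

import pandas as pd

from mhbkit import (AnnotationTrack, SimulationConfig, annotation_enrichment,
                    build_mhl_matrix, differential_blocks,
                    filter_missing_blocks, generate_cohort)

cohort = generate_cohort(SimulationConfig(n_samples=20, n_blocks=120,
                                          n_signature_blocks=20), seed=13)
matrix = filter_missing_blocks(
    build_mhl_matrix(cohort.records, cohort.blocks), policy="any")
truth = cohort.truth.subtype
res = differential_blocks(matrix, list(truth.index[truth == "high"]),
                          list(truth.index[truth == "low"]))
print("differential calls:", res["call"].value_counts().to_dict())

# annotate the true signature block intervals and test their enrichment
sig = set(cohort.truth.signature_blocks)
track = AnnotationTrack(pd.DataFrame(
    [(b.chrom, b.start, b.end, "signature") for b in cohort.blocks
     if b.block_id in sig], columns=["chrom", "start", "end", "label"]))
hyper = list(res.index[res["call"] == "hyper"])
enr = annotation_enrichment(hyper, list(res.index), cohort.blocks, track)
print(enr[["obs_frac", "exp_frac", "log2_ratio"]].round(3).to_string())
# A large positive log2 ratio: hypermethylated calls concentrate in the
# intervals where the simulation actually planted the subtype signal.
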