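"""Generate a small synthetic two-subtype cohort and look at its pieces.

The generator emulates a bisulfite cohort: read-level CpG haplotypes with
tunable within-read concordance, a subset of blocks hypermethylated in one
subtype, exponential survival with a subtype hazard ratio, and an array arm
derived from the same truth.
"""

from mhbkit import SimulationConfig, generate_cohort

cfg = SimulationConfig(n_samples=12, n_blocks=60, n_signature_blocks=10)
cohort = generate_cohort(cfg, seed=7)

print(f"samples: {cfg.n_samples}, blocks: {len(cohort.blocks)}, "
      f"read records: {len(cohort.records)}")
print("subtype counts:", cohort.truth.subtype.value_counts().to_dict())
print("first signature blocks:", cohort.truth.signature_blocks[:5])
print(cohort.clinical.head().to_string(index=False))
# os_time/pfs_time are months; *_event = 1 marks an observed event, 0 censoring.
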