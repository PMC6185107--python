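"""Simulate a four-layer stress time course and call regulatory events.

Generates negative-binomial sequencing counts and log-normal protein
intensities for 2,000 genes at 0/1/4/8 h in two replicates and two stress
conditions, with step-change events planted in 10% of genes per regulatory
level, then runs the full pipeline: filtering, normalization, log series,
paired-layer change-point scores, and the both-replicate FDR<0.2 rule.
"""

import stressomics as so

cfg = so.SimConfig(seed=1)
data = so.generate_multiomics(cfg)
print(f"planted events: {len(data.truth)} "
      f"({data.truth['level'].value_counts().to_dict()})")

result = so.run_event_pipeline(data.counts, peptide_counts=data.peptides)
print(f"core gene set: {len(result.core_genes)} genes")
print(f"called events: {len(result.events)}")
print(result.events.head())

report = so.recovery_report(result.events, data.truth, cfg.times)
print("\nrecovery against planted truth:")
for key, val in report.items():
    print(f"  {key}: {val:.4g}" if isinstance(val, float) else f"  {key}: {val}")
print(
    "\nSensitivity is the fraction of planted (gene, level, condition, "
    "direction) events re-called; the empirical FDR counts called events "
    "explained by no planted event at any cascade-visible level; time error "
    "is measured in boundary-index units on the 0/1/4/8 h grid."
)
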