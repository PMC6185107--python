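# stressomics

Multi-layer time-course analysis of the cellular stress response, for
computational biologists studying how cells reshape gene expression under
proteostatic (ER) and oxidative stress.  The package takes per-sample count
tables from four layers — RNA exon counts, ribosome-footprint CDS counts,
non-ribosomal protein-footprint UTR counts, and protein intensities —
measured at 0/1/4/8 h in replicate under two stress conditions, and turns
them into *regulatory events*: per-gene, per-level, per-time-boundary calls
of transcription, translation, RNA-binding and protein-turnover changes,
with replicate-consistent FDR control.  Around the event caller it provides
the comparative analyses such a study needs (stress-specific vs shared
responses, concordant vs discordant multi-level regulation, event timing,
expression clustering, category enrichment), plus two companion modules:
footprint occupancy around conserved UTR secondary structures, and
junction-read splice-event calling with PSI time courses.  A synthetic-data
generator with planted ground truth makes every stage testable end to end.

## The statistic at its core

For each gene g the paired-layer signal is m(t) = log output(t) − log
input(t) (e.g. translation: log RPF − log RNA), so changes explained
upstream cancel.  At each boundary i between consecutive times,

    d_g(i) = m_g(t_{i+1}) − m_g(t_i)
    z_g(i) = (d_g(i) − median_g d)/(1.4826 · MAD_g d)

with two-sided normal p and Benjamini–Hochberg q over all genes ×
boundaries of a run.  An event for (gene, level, condition, direction)
requires q < 0.2 with consistent sign in **both** replicates, at any
boundary; its time is the replicate-mean of the later endpoint of the
best-q boundary.  Overlaps between event sets are tested with the exact
hypergeometric upper tail; structure binding changes with an exact
conditional binomial; splice-choice linkage with Fisher's exact test.

## Worked example

```python
import stressomics as so

cfg = so.SimConfig(seed=1)                      # 2,000 genes, 4 layers
data = so.generate_multiomics(cfg)              # counts + planted truth
res = so.run_event_pipeline(data.counts, peptide_counts=data.peptides)
print(len(res.core_genes), len(res.events))
print(so.recovery_report(res.events, data.truth, cfg.times))
```

prints

```
2000 1076
{'n_planted': 951, 'n_called': 1076, 'sensitivity': 0.8843322818086226,
 'empirical_fdr': 0.015799256505576207,
 'mean_time_error_h': 0.022592152199762187,
 'mean_time_error_boundaries': 0.006539833531510107}
```

meaning: of 951 planted step events (10% of genes per regulatory level,
1 natural-log-unit steps), 88.4% are re-called with the right gene, level,
condition and direction; 1.6% of the 1,076 called events are explained by
no planted event; and the called event times sit essentially on the planted
boundaries.  The `examples/` directory holds one short narrative script per
capability (event calling, shared/specific splits, concordance/timing/
clustering, structure occupancy, splice events); each prints its numbers
with a line on what they mean.

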