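"""Junction-read splice events and a stress-responsive PSI time course.

Builds an annotated exon model with a skippable exon, simulates junction
reads whose percent-spliced-in (PSI) drops at 1 h - the signature of a
stress-induced exon-skipping switch - then filters junctions, classifies
the event, quantifies PSI over time, and tests whether two splice choices
are linked with a Fisher exact test on phased counts.
"""

import stressomics as so

model, event = so.generate_splice_models(1, seed=0, types=("exon_skipping",))[0]
print(f"exon model on {model.chrom}{model.strand}: "
      f"{ {t: v for t, v in model.transcripts.items()} }")

schedule = (0.8, 0.4, 0.8, 0.8)  # inclusion dips one hour after stress
junctions = so.generate_junctions(event, schedule, depth=1000, seed=6)
kept = so.filter_junctions(junctions, model, min_reads=2)
found = so.classify_events(kept, model)
print(f"\nclassified events: {[ (e.type, e.exons) for e in found ]}")

psi = so.psi_series(found[0], kept)
psi["time_h"] = [float(s.split(':')[1]) for s in psi["sample"]]
print(psi.sort_values("time_h")[["time_h", "psi",
                                 "inclusion_reads", "exclusion_reads"]])

# phased molecule counts over two events (e.g. alternative first exon x
# exon skipping): rows = first choice, cols = second choice
table = [[8, 2], [1, 9]]
res = so.linked_event_test(table)
print(f"\nlinked-event test on {table}: odds ratio {res['odds_ratio']:.1f}, "
      f"one-sided p = {res['p_greater']:.4f}")
print(
    "\nPSI near 0.8 at 0/4/8 h and 0.4 at 1 h reproduces the planted "
    "schedule; the small Fisher p says the second splice choice depends on "
    "the first - two coupled splicing decisions on one transcript."
)
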