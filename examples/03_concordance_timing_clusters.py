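"""Concordance between levels, event timing, and expression clustering.

Asks three questions of the called events: do transcription and
translation move the same genes in the same or opposite directions
(hypergeometric Venn); when do events occur (histogram of replicate-mean
event times); and how does the z-scored fold-change matrix partition into
response-shape clusters (complete-linkage, 1-Pearson distance, elbow
criterion for k)?
"""

import stressomics as so

cfg = so.SimConfig(seed=3)
data = so.generate_multiomics(cfg)
result = so.run_event_pipeline(data.counts, peptide_counts=data.peptides)
events = result.events[result.events["condition"] == "tm"]
universe = len(result.core_genes)

trxp_up = set(events.query("level=='TRXP_RNADEG' and direction=='up'")["gene"])
trl_dn = set(events.query("level=='TRL' and direction=='down'")["gene"])
venn = so.concordance_venn(trxp_up, trl_dn, ("up", "down"), universe)
print("transcription-up vs translation-down (discordant pair):")
print(f"  only TRXP {venn['only_1']}, only TRL {venn['only_2']}, "
      f"both {venn['both']}, p = {venn['p_overlap']:.3g}")

print("\nevent timing (TRXP up, h -> events):")
print(so.temporal_histogram(events, level="TRXP_RNADEG", direction="up"))

z = so.fold_change_zscore(result.series)
suggested, curve = so.elbow_k(z.iloc[:400], k_range=range(1, 12))
labels = so.hierarchical_cluster(z.iloc[:400], k=suggested)
print(f"\nelbow-suggested k = {suggested}; cluster sizes:")
print(labels.value_counts().sort_index().to_dict())
print(
    "\nThe Venn counts quantify counterbalancing regulation; the histogram "
    "shows when each regulatory process acts; the clusters group genes with "
    "a common normalized response shape across layers and stresses."
)
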