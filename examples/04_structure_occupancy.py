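"""Protein-footprint occupancy around 3'UTR secondary structures.

Simulates per-base footprint coverage with Gaussian peaks at annotated
structure midpoints, applies the transcribed filter (mean untreated
coverage >= 10 in a +-200 nt window), builds the +-250 nt metagene
profile, tests 0 h vs 8 h local coverage with the exact conditional
binomial, and scans the surrounding sequence for known regulator motifs.
"""

import numpy as np

import stressomics as so

cfg = so.CoverageConfig(seed=4, diff_fraction=0.05, diff_fold=4.0)
cov = so.generate_coverage(100, cfg)
pop = cov.samples[cov.samples["layer"] == "POP"]

wc200, _ = so.window_counts(
    cov.tracks, cov.structures, list(pop.index), halfwidth=200
)
untreated = list(pop[pop["time"] == 0].index)
transcribed = so.transcribed_filter(wc200, untreated, min_mean=10)
print(f"transcribed structures: {len(transcribed)} / {len(cov.structures)}")

wc100, _ = so.window_counts(
    cov.tracks, cov.structures, list(pop.index), halfwidth=100
)
occupied = so.occupancy_flag(wc100)
print(f"footprint-occupied (+-100 nt): {int(occupied.sum())}")

_, mean_profile = so.profile_matrix(cov.tracks, cov.structures, list(pop.index))
print(f"mean profile peak offset: {so.profile_peak_offset(mean_profile)} nt "
      f"(peak {mean_profile.max():.1f} TPM vs edge {mean_profile.iloc[0]:.1f})")

s0 = list(pop[pop["time"] == 0].index)
s8 = list(pop[pop["time"] == 8].index)
libs = {s: sum(d.sum() for (t, sid), d in cov.tracks.items() if sid == s)
        for s in s0 + s8}
diff = so.differential_binding(
    wc200[s0].sum(axis=1), wc200[s8].sum(axis=1),
    sum(libs[s] for s in s0), sum(libs[s] for s in s8),
)
hits = diff[diff["q"] < 0.01].sort_values("q")
print(f"\ndifferentially bound at q<0.01: {len(hits)} "
      f"(planted: {sorted(cov.truth['structure_id'])})")
print(hits[["count_a", "count_b", "log2_fold_change", "q"]].head())

rng = np.random.default_rng(0)
seqs = {}
for i in range(50):
    s = "".join(rng.choice(list("ACGU"), size=201))
    seqs[f"s{i}"] = s[:115] + "AAUAAA" + s[121:]  # poly(A) signal at +15
hist = so.motif_positions(seqs)["polyA_signal"]
print(f"\npoly(A)-signal scan: strongest offset {hist.idxmax():+d} nt "
      f"(per-structure probability {hist.max():.2f})")
print(
    "\nThe profile peaking at offset ~0 shows footprints centred on the "
    "structures; q<0.01 rows are structures whose local binding changed "
    "between 0 h and 8 h beyond sequencing-depth expectation."
)
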