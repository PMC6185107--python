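"""Windowed occupancy, profiles, differential binding, motif scanning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stressomics as so


def one_structure(midpoint=500, tid="T1", span=100):
    return pd.DataFrame(
        {
            "structure_id": ["S1"],
            "transcript_id": [tid],
            "region": ["3UTR"],
            "midpoint": [midpoint],
            "span": [span],
        }
    )


# ---------------------------------------------------------------------------
# window counts


def test_window_counts_inclusive_window():
    depth = np.zeros(1000, dtype=int)
    depth[[490, 700, 701]] = 1
    tracks = {("T1", "s1"): depth}
    wc, clipped = so.window_counts(tracks, one_structure(), ["s1"], halfwidth=200)
    assert wc.loc["S1", "s1"] == 2  # [300, 700] inclusive
    assert not clipped.any()
    zero, _ = so.window_counts(
        {("T1", "s1"): np.zeros(1000, dtype=int)}, one_structure(), ["s1"]
    )
    assert zero.loc["S1", "s1"] == 0


def test_window_counts_degenerate_and_clipped():
    depth = np.zeros(1000, dtype=int)
    depth[500] = 3
    depth[501] = 1
    tracks = {("T1", "s1"): depth}
    wc, _ = so.window_counts(tracks, one_structure(), ["s1"], halfwidth=0)
    assert wc.loc["S1", "s1"] == 3
    wc_all, clipped = so.window_counts(
        tracks, one_structure(), ["s1"], halfwidth=2000
    )
    assert wc_all.loc["S1", "s1"] == depth.sum()  # conservation
    assert clipped.loc["S1"]


def test_window_counts_errors_and_skips():
    tracks = {("T1", "s1"): np.zeros(100, dtype=int)}
    with pytest.raises(ValueError, match="outside"):
        so.window_counts(tracks, one_structure(midpoint=150), ["s1"])
    with pytest.warns(UserWarning, match="without coverage"):
        wc, _ = so.window_counts(
            tracks, one_structure(tid="absent", midpoint=50), ["s1"]
        )
    assert wc.empty


# ---------------------------------------------------------------------------
# transcribed filter and occupancy flags


def test_transcribed_filter_boundary():
    occ = pd.DataFrame(
        {"u1": [12.0, 0.0, 9.0], "u2": [8.0, 0.0, 9.0]},
        index=["a", "b", "c"],
    )
    kept = so.transcribed_filter(occ, ["u1", "u2"], min_mean=10)
    assert kept == ["a"]  # mean (12+8)/2 = 10 kept; 9 < 10 dropped
    assert so.transcribed_filter(occ, ["u1", "u2"], min_mean=9) == ["a", "c"]
    # raising the cutoff never adds structures
    assert set(so.transcribed_filter(occ, ["u1", "u2"], 12)) <= set(kept)


def test_occupancy_flag_boundaries_and_monotonicity():
    depth = np.zeros(1000, dtype=int)
    depth[600] = 1  # exactly mid + 100
    tracks = {("T1", "s1"): depth}
    wc, _ = so.window_counts(tracks, one_structure(), ["s1"], halfwidth=100)
    assert so.occupancy_flag(wc).loc["S1"]
    depth2 = np.zeros(1000, dtype=int)
    depth2[601] = 1  # just outside
    wc2, _ = so.window_counts(
        {("T1", "s1"): depth2}, one_structure(), ["s1"], halfwidth=100
    )
    assert not so.occupancy_flag(wc2).loc["S1"]
    flags_loose = so.occupancy_flag(wc, min_reads=1)
    flags_strict = so.occupancy_flag(wc, min_reads=2)
    assert flags_strict.sum() <= flags_loose.sum()


def test_tabulate_regions():
    structures = pd.DataFrame(
        {
            "structure_id": ["a", "b", "c"],
            "transcript_id": ["T1", "T2", "T3"],
            "region": ["5UTR", "3UTR", "3UTR"],
            "midpoint": [10, 10, 10],
            "span": [50, 50, 50],
        }
    )
    tab = so.tabulate_regions(structures, flagged=["b"])
    tab = tab.set_index("region")
    assert tab.loc["3UTR", "n_occupied"] == 1
    assert tab.loc["5UTR", "n_occupied"] == 0


# ---------------------------------------------------------------------------
# profiles


def test_profile_flat_track_gives_flat_mean():
    tracks = {("T1", "s1"): np.ones(1000, dtype=int)}
    matrix, mean = so.profile_matrix(
        tracks, one_structure(), ["s1"], halfwidth=250
    )
    assert mean.nunique() == 1


def test_profile_peak_at_midpoint_and_conservation():
    cfg = so.CoverageConfig(seed=3)
    cov = so.generate_coverage(100, cfg)
    pop0 = [
        s for s, row in cov.samples.iterrows() if row["layer"] == "POP"
    ]
    matrix, mean = so.profile_matrix(cov.tracks, cov.structures, pop0)
    assert abs(so.profile_peak_offset(mean)) <= 2
    rna0 = [
        s for s, row in cov.samples.iterrows()
        if row["layer"] == "RNA" and row["time"] == 0
    ]
    _, rna_mean = so.profile_matrix(cov.tracks, cov.structures, rna0)
    # protein-footprint profile peaks while matched RNA profile stays flat
    flank = pd.concat([mean.iloc[:100], mean.iloc[-100:]]).mean()
    assert mean.max() / flank > 2
    rna_flank = pd.concat([rna_mean.iloc[:100], rna_mean.iloc[-100:]]).mean()
    assert rna_mean.max() / rna_flank < 2
    # conservation for a single sample: un-scaled row sum == window count
    s = pop0[0]
    lib = sum(d.sum() for (t, sid), d in cov.tracks.items() if sid == s)
    wc, _ = so.window_counts(cov.tracks, cov.structures, [s], halfwidth=250)
    m_one, _ = so.profile_matrix(
        cov.tracks, cov.structures, [s], library_sizes={s: lib}
    )
    row_sums = m_one.sum(axis=1) * lib / 1e6
    assert np.allclose(row_sums, wc[s].to_numpy(), atol=1e-6)


# ---------------------------------------------------------------------------
# differential binding


def binom_two_sided_oracle(k, n, p):
    """Minimum-likelihood two-sided exact binomial p by enumeration."""
    pk = stats.binom.pmf(np.arange(n + 1), n, p)
    return float(pk[pk <= pk[k] * (1 + 1e-12)].sum())


def test_differential_binding_symmetric_null_and_example():
    idx = pd.Index(["s1", "s2"], name="structure_id")
    res = so.differential_binding(
        pd.Series([10, 10], index=idx), pd.Series([10, 40], index=idx),
        library_a=1e6, library_b=1e6,
    )
    assert res.loc["s1", "p"] == pytest.approx(1.0)
    assert res.loc["s2", "p"] == pytest.approx(
        binom_two_sided_oracle(40, 50, 0.5)
    )
    assert res.loc["s2", "log2_fold_change"] > 1.9


def test_differential_binding_more_evidence_smaller_p():
    idx = pd.Index(["s"], name="structure_id")
    p1 = so.differential_binding(
        pd.Series([10], idx), pd.Series([20], idx), 1e6, 1e6
    ).loc["s", "p"]
    p2 = so.differential_binding(
        pd.Series([20], idx), pd.Series([40], idx), 2e6, 2e6
    ).loc["s", "p"]
    assert p2 < p1


def test_differential_binding_matches_enumeration_up_to_n30():
    for lib_a, lib_b in [(1e6, 1e6), (1e6, 3e6)]:
        p0 = lib_b / (lib_a + lib_b)
        for n in range(0, 31):
            ca = np.arange(n + 1)
            idx = pd.Index([f"s{i}" for i in ca], name="structure_id")
            res = so.differential_binding(
                pd.Series(ca, index=idx), pd.Series(n - ca, index=idx),
                lib_a, lib_b,
            )
            for i, c in enumerate(ca):
                expected = (
                    1.0 if n == 0 else binom_two_sided_oracle(n - c, n, p0)
                )
                assert res["p"].iloc[i] == pytest.approx(expected, abs=1e-9)


def test_planted_fold_change_recovered():
    cfg = so.CoverageConfig(seed=17, diff_fraction=0.05, diff_fold=4.0)
    cov = so.generate_coverage(100, cfg)
    pop = cov.samples[cov.samples["layer"] == "POP"]
    s0 = list(pop[pop["time"] == 0].index)
    s8 = list(pop[pop["time"] == 8].index)
    wc, _ = so.window_counts(cov.tracks, cov.structures, s0 + s8, halfwidth=200)
    libs = {
        s: sum(d.sum() for (t, sid), d in cov.tracks.items() if sid == s)
        for s in s0 + s8
    }
    res = so.differential_binding(
        wc[s0].sum(axis=1), wc[s8].sum(axis=1),
        sum(libs[s] for s in s0), sum(libs[s] for s in s8),
    )
    planted = set(cov.truth["structure_id"])
    assert planted and (res.loc[sorted(planted), "q"] < 0.05).all()


# ---------------------------------------------------------------------------
# motifs


def test_motif_planted_offset_spike():
    hw = 100
    rng = np.random.default_rng(6)
    seqs = {}
    for i in range(20):
        s = "".join(rng.choice(list("ACGT"), size=2 * hw + 1))
        s = s[: hw + 15] + "AATAAA" + s[hw + 21 :]
        seqs[f"s{i}"] = s
    hists = so.motif_positions(seqs, {"polyA_signal": "AAUAAA"})
    hist = hists["polyA_signal"]
    assert hist.idxmax() == 15
    assert hist.loc[15] == pytest.approx(1.0, abs=0.2)  # rare chance extras


def test_motif_absent_gives_zero_histogram():
    seqs = {"a": "ACGU" * 50 + "A"}
    hists = so.motif_positions(seqs, {"m": "AAUAAA"})
    assert (hists["m"] == 0).all()


def test_motif_background_rate_matches_closed_form():
    rng = np.random.default_rng(7)
    n, hw = 500, 100
    seqs = {
        f"s{i}": "".join(rng.choice(list("ACGU"), size=2 * hw + 1))
        for i in range(n)
    }
    hist = so.motif_positions(seqs, {"m": "AAUAAA"})["m"]
    p = 0.25**6
    sd = np.sqrt(p * (1 - p) / n)
    assert (np.abs(hist.to_numpy() - p) <= 3 * sd + 1e-12).mean() > 0.98
    assert hist.mean() == pytest.approx(p, rel=0.5)


def test_motif_rejects_non_iupac():
    with pytest.raises(ValueError, match="non-IUPAC"):
        so.motif_positions({"a": "ACGUACG"}, {"bad": "AA?A"})
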