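"""Cross-condition and cross-level comparison of regulatory events.

Once events are called per stress condition and regulatory level, the
questions the study design poses are combinatorial: which genes respond to
only one stress and which are shared (with a hypergeometric test against
the core-gene universe); which genes are regulated at two levels in the
same (concordant) or opposite (discordant) direction; when the events
occur; which expression clusters and which functional categories they
enrich.  Unless stated otherwise the hypergeometric universe is the core
gene set - the genes with complete measurements in every layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .changepoint import bh_fdr


def overlap_hypergeom(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric overlap probability P(X >= k).

    ``N`` universe size, ``K`` and ``n`` the two set sizes, ``k`` their
    observed intersection.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(
            f"inconsistent counts: N={N}, K={K}, n={n}, k={k}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EventComparison:
    level: str
    direction: str
    set_a_specific: frozenset
    set_b_specific: frozenset
    shared: frozenset
    universe_size: int
    p_overlap: float


def split_specific_shared(
    events_a: Iterable[str],
    events_b: Iterable[str],
    level: str,
    direction: str,
    universe_size: int,
) -> EventComparison:
    """Partition two conditions' event gene sets into specific and shared.

    The shared set's size is tested against the hypergeometric null of two
    random draws of the observed sizes from the universe.
    """
    a, b = set(events_a), set(events_b)
    if universe_size < len(a | b):
        raise ValueError(
            f"universe ({universe_size}) smaller than the union ({len(a | b)})"
        )
    shared = a & b
    p = overlap_hypergeom(universe_size, len(a), len(b), len(shared))
    return EventComparison(
        level=level,
        direction=direction,
        set_a_specific=frozenset(a - b),
        set_b_specific=frozenset(b - a),
        shared=frozenset(shared),
        universe_size=universe_size,
        p_overlap=p,
    )


def concordance_venn(
    genes_level1: Iterable[str],
    genes_level2: Iterable[str],
    directions: tuple[str, str],
    universe_size: int,
) -> dict:
    """Two-level Venn counts with the hypergeometric intersection test.

    ``directions`` are the directions of the two gene sets (e.g. ("up",
    "down") for transcription-up against translation-down); equal
    directions label the intersection concordant, unequal discordant.
    """
    s1, s2 = set(genes_level1), set(genes_level2)
    both = s1 & s2
    p = overlap_hypergeom(universe_size, len(s1), len(s2), len(both))
    return {
        "only_1": len(s1 - s2),
        "only_2": len(s2 - s1),
        "both": len(both),
        "genes_both": frozenset(both),
        "relation": "concordant" if directions[0] == directions[1] else "discordant",
        "p_overlap": p,
    }


def temporal_histogram(
    events: pd.DataFrame,
    level: str | None = None,
    direction: str | None = None,
    condition: str | None = None,
) -> pd.Series:
    """Event counts per achievable replicate-mean event time.

    Filters the event table to the requested level/direction/condition and
    counts events per distinct ``event_time`` value (the grid of means of
    observed time points).  The sum over bins equals the number of events.
    """
    sub = events
    for col, val in (
        ("level", level),
        ("direction", direction),
        ("condition", condition),
    ):
        if val is not None:
            sub = sub[sub[col] == val]
    return sub["event_time"].value_counts().sort_index().rename("n_events")


# ---------------------------------------------------------------------------
# clustering of the z-scored fold-change matrix


def _correlation_distance(z: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance; constant rows use r = 0 (warned)."""
    sd = z.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant rows: correlation undefined, "
            "assigned zero correlation to all other rows"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(z)
    r = np.nan_to_num(r, nan=0.0)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)
    d = 1.0 - np.clip(r, -1.0, 1.0)
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def hierarchical_cluster(z_matrix: pd.DataFrame, k: int = 20) -> pd.Series:
    """Complete-linkage clustering on 1 - Pearson correlation, cut at k.

    Row labels are arbitrary cluster ids 1..k; the partition is invariant
    to row order up to relabeling.
    """
    if k < 1 or k > len(z_matrix):
        raise ValueError("k must be between 1 and the number of rows")
    z = z_matrix.to_numpy(dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z-matrix must be finite")
    link = hierarchy.linkage(_correlation_distance(z), method="complete")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=z_matrix.index, name="cluster")


def _within_dispersion(z: np.ndarray, labels: np.ndarray) -> float:
    # SSE around cluster centroids; rows standardized to mean 0 / sd 1 make
    # this proportional to the summed 1 - r against the centroid direction
    total = 0.0
    for lab in np.unique(labels):
        block = z[labels == lab]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def elbow_k(
    z_matrix: pd.DataFrame, k_range: Sequence[int] | None = None
) -> tuple[int, pd.Series]:
    """Within-cluster dispersion curve and its elbow.

    Cuts the same complete-linkage tree at every k in ``k_range`` and
    computes the within-cluster sum of squared deviations from cluster
    centroids.  Because the cuts are nested, the curve is non-increasing
    in k.  The suggested k maximizes the second difference (the sharpest
    kink); for structureless data the suggestion is unstable and small.
    """
    z = z_matrix.to_numpy(dtype=float)
    if k_range is None:
        k_range = range(1, min(len(z_matrix), 25) + 1)
    k_range = [int(k) for k in k_range]
    if max(k_range) > len(z_matrix):
        raise ValueError("k_range exceeds the number of rows")
    link = hierarchy.linkage(_correlation_distance(z), method="complete")
    curve = {}
    for k in k_range:
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
        curve[k] = _within_dispersion(z, labels)
    curve = pd.Series(curve, name="within_dispersion").sort_index()
    if len(curve) >= 3:
        second = curve.diff().diff().shift(-1)  # W(k-1) - 2 W(k) + W(k+1)
        suggested = int(second.idxmax())
    else:
        suggested = int(curve.index[0])
    return suggested, curve


def category_enrichment(
    event_genes: Iterable[str],
    categories: Mapping[str, str],
    universe: Iterable[str],
    direction: str = "",
) -> pd.DataFrame:
    """Fisher tests of event genes against each gene category.

    ``categories`` maps gene -> primary category; universe genes without a
    category are pooled as ``other``.  Each category's 2x2 table (in
    event set x in category) is tested two-sided plus one-sided in both
    directions; q is BH over categories on the two-sided p.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    ev = set(event_genes) & uni
    cat_of = {g: categories.get(g, "other") for g in universe}
    rows = []
    for cat in sorted(set(cat_of.values())):
        in_cat = {g for g, c in cat_of.items() if c == cat}
        a = len(ev & in_cat)
        b = len(ev - in_cat)
        c = len(in_cat - ev)
        d = len(uni) - a - b - c
        table = [[a, b], [c, d]]
        if ev:
            odds, p_two = stats.fisher_exact(table)
            _, p_enrich = stats.fisher_exact(table, alternative="greater")
            _, p_deplete = stats.fisher_exact(table, alternative="less")
        else:
            odds, p_two, p_enrich, p_deplete = np.nan, 1.0, 1.0, 1.0
        rows.append(
            {
                "category": cat,
                "direction": direction,
                "n_events_in_category": a,
                "n_category": len(in_cat),
                "n_events": len(ev),
                "universe": len(uni),
                "odds_ratio": odds,
                "p_enrichment": p_enrich,
                "p_depletion": p_deplete,
                "p": p_two,
            }
        )
    res = pd.DataFrame(rows)
    res["q"] = bh_fdr(res["p"].to_numpy())
    return res
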