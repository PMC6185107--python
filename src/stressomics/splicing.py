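"""Junction-read splice-event analysis.

Alternative splicing is read off exon-exon junction reads: each junction is
a genomic (donor, acceptor) pair with per-sample read counts.  Junctions
are filtered against an annotated exon model (single-read junctions and
junctions touching no known exon boundary are discarded), assembled into
classified events - exon skipping, alternative 5'/3' splice sites and
mutually exclusive exons - and quantified as percent-spliced-in (PSI) time
courses.  A Fisher test on phased two-event counts asks whether two splice
choices on the same transcript are linked.

Genomic coordinates are 0-based half-open internally; a junction is stored
by its ``left``/``right`` genomic ends, where ``left`` equals the upstream
exon's end coordinate and ``right`` the downstream exon's start.  On the
plus strand the donor is the left end; on the minus strand the roles swap.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

JUNCTION_COLUMNS = ["chrom", "donor", "acceptor", "strand", "sample", "count"]


@dataclass(frozen=True)
class ExonModel:
    """Annotated exon structures of one gene locus.

    ``transcripts`` maps transcript id to a coordinate-sorted tuple of
    0-based half-open exon intervals.  The annotated boundary sets are the
    union of exon starts and ends over all transcripts.
    """

    chrom: str
    strand: str
    transcripts: Mapping[str, tuple[tuple[int, int], ...]]

    def __post_init__(self) -> None:
        for tid, exons in self.transcripts.items():
            exs = sorted(exons)
            for (s1, e1), (s2, e2) in zip(exs, exs[1:]):
                if e1 > s2:
                    raise ValueError(
                        f"overlapping exons in transcript {tid!r}: "
                        f"({s1},{e1}) and ({s2},{e2})"
                    )

    @property
    def exon_starts(self) -> frozenset[int]:
        return frozenset(
            s for exons in self.transcripts.values() for s, _ in exons
        )

    @property
    def exon_ends(self) -> frozenset[int]:
        return frozenset(
            e for exons in self.transcripts.values() for _, e in exons
        )


@dataclass(frozen=True)
class SpliceEvent:
    """A classified splice event defined by its junction sets.

    ``inclusion_junctions`` and ``exclusion_junctions`` are disjoint tuples
    of (left, right) genomic junction coordinates; ``exons`` are the
    internal exon interval(s) the event decides over.
    """

    event_id: str
    type: str  # exon_skipping | alt5 | alt3 | mutually_exclusive
    chrom: str
    strand: str
    inclusion_junctions: tuple[tuple[int, int], ...]
    exclusion_junctions: tuple[tuple[int, int], ...]
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if set(self.inclusion_junctions) & set(self.exclusion_junctions):
            raise ValueError("inclusion and exclusion junction sets overlap")


def _left_right(donor: int, acceptor: int) -> tuple[int, int]:
    return (donor, acceptor) if donor < acceptor else (acceptor, donor)


def filter_junctions(
    junctions: pd.DataFrame,
    model: ExonModel,
    min_reads: int = 2,
    pooled: bool = False,
) -> pd.DataFrame:
    """Apply the junction quality rules against an annotated exon model.

    Drops (junction, sample) observations with fewer than ``min_reads``
    reads (``pooled=True`` pools counts across samples before applying the
    threshold), junctions on the wrong strand (warned), and junctions where
    neither end coincides with an annotated exon boundary.  A junction with
    one annotated and one novel end survives; a novel exon therefore enters
    the downstream classification only when junction reads support both of
    its boundaries, since events are assembled exclusively from retained
    junctions.  Idempotent, and monotone in ``min_reads``.
    """
    j = junctions.copy()
    wrong = (j["strand"] != model.strand) | (j["chrom"] != model.chrom)
    if wrong.any():
        warnings.warn(
            f"dropping {int(wrong.sum())} junction rows with strand/chrom "
            f"mismatch against model {model.chrom}{model.strand}"
        )
        j = j[~wrong]
    lr = [
        _left_right(d, a) for d, a in zip(j["donor"], j["acceptor"])
    ]
    j = j.assign(
        _left=[x[0] for x in lr], _right=[x[1] for x in lr]
    )
    starts, ends = model.exon_starts, model.exon_ends
    known = j["_left"].isin(ends) | j["_right"].isin(starts)
    j = j[known]
    if pooled:
        totals = j.groupby(["_left", "_right"])["count"].transform("sum")
        j = j[totals >= min_reads]
    else:
        j = j[j["count"] >= min_reads]
    return j.drop(columns=["_left", "_right"]).reset_index(drop=True)


def _junction_set(junctions: pd.DataFrame) -> set[tuple[int, int]]:
    return {
        _left_right(d, a)
        for d, a in zip(junctions["donor"], junctions["acceptor"])
    }


def classify_events(
    junctions: pd.DataFrame, model: ExonModel
) -> list[SpliceEvent]:
    """Assemble classified splice events from the retained junctions.

    * exon skipping: junctions A->B and B->C (the inclusion path through
      exon B) together with the direct A->C exclusion junction;
    * mutually exclusive exons: inclusion paths A->B->D and A->C->D with
      neither B->C nor the direct A->D junction present;
    * alternative 5'/3' splice sites: two junctions sharing one end, the
      other ends being alternative boundaries of a single exon (pairs
      explained by a skipping or mutually-exclusive topology are not
      reported again; strand decides the 5'/3' label).
    """
    J = sorted(_junction_set(junctions))
    Jset = set(J)
    by_left: dict[int, list[int]] = {}
    by_right: dict[int, list[int]] = {}
    for l, r in J:
        by_left.setdefault(l, []).append(r)
        by_right.setdefault(r, []).append(l)

    events: list[SpliceEvent] = []
    claimed: list[frozenset[tuple[int, int]]] = []
    counter = itertools.count(1)

    def _new(type_, inc, exc, exons):
        ev = SpliceEvent(
            event_id=f"{model.chrom}{model.strand}_{type_}_{next(counter)}",
            type=type_,
            chrom=model.chrom,
            strand=model.strand,
            inclusion_junctions=tuple(sorted(inc)),
            exclusion_junctions=tuple(sorted(exc)),
            exons=tuple(sorted(exons)),
        )
        events.append(ev)
        claimed.append(frozenset(inc) | frozenset(exc))

    # exon skipping: (a,b), (c,d) with exon [b,c), plus direct (a,d)
    for (a, b) in J:
        for c in [x for x in by_left if b < x]:
            for d in by_left[c]:
                if (a, d) in Jset and (c, d) in Jset and b < c:
                    _new(
                        "exon_skipping",
                        inc=[(a, b), (c, d)],
                        exc=[(a, d)],
                        exons=[(b, c)],
                    )

    # mutually exclusive: A->B->D and A->C->D, no B->C, no A->D
    for a in by_left:
        # internal exons reachable as (a, start) ... (end, d)
        for d in {r for l in by_left for r in by_left[l]}:
            if (a, d) in Jset:
                continue  # a direct junction means skipping, handled above
            internals = [
                (b, c)
                for b in by_left.get(a, [])
                for c in by_right.get(d, [])
                if b < c and (a, b) in Jset and (c, d) in Jset
            ]
            if len(internals) < 2:
                continue
            for (b1, c1), (b2, c2) in itertools.combinations(
                sorted(internals), 2
            ):
                if c1 <= b2 and (c1, b2) not in Jset:
                    _new(
                        "mutually_exclusive",
                        inc=[(a, b1), (c1, d)],
                        exc=[(a, b2), (c2, d)],
                        exons=[(b1, c1), (b2, c2)],
                    )

    # alternative splice-site pairs not already explained
    def _explained(j1, j2):
        return any({j1, j2} <= ev for ev in claimed)

    for l, rights in by_left.items():
        for r1, r2 in itertools.combinations(sorted(rights), 2):
            if _explained((l, r1), (l, r2)):
                continue
            # a junction landing on r2 from within [r1, r2) implies skipping
            if any(r1 <= x < r2 for x in by_right.get(r2, []) if x != l):
                continue
            type_ = "alt3" if model.strand == "+" else "alt5"
            _new(type_, inc=[(l, r1)], exc=[(l, r2)], exons=[(r1, r2)])
    for r, lefts in by_right.items():
        for l1, l2 in itertools.combinations(sorted(lefts), 2):
            if _explained((l1, r), (l2, r)):
                continue
            if any(l1 < x <= l2 for x in by_left.get(l1, []) if x != r):
                continue
            type_ = "alt5" if model.strand == "+" else "alt3"
            _new(type_, inc=[(l2, r)], exc=[(l1, r)], exons=[(l1, l2)])
    return events


def psi_series(
    event: SpliceEvent,
    junctions: pd.DataFrame,
    samples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Percent-spliced-in per sample for one event.

    psi = mean(inclusion-junction counts) / (mean inclusion + mean
    exclusion); NaN where no supporting reads exist.  ``samples`` (indexed
    by sample id, e.g. with condition/time/replicate columns) is merged
    into the result when given.  Scaling all counts leaves psi unchanged.
    """
    j = junctions.copy()
    lr = [_left_right(d, a) for d, a in zip(j["donor"], j["acceptor"])]
    j["_j"] = lr
    inc = set(event.inclusion_junctions)
    exc = set(event.exclusion_junctions)
    out = []
    for sample, grp in j.groupby("sample"):
        counts = grp.set_index("_j")["count"].groupby(level=0).sum()
        inc_mean = float(np.mean([counts.get(x, 0) for x in inc]))
        exc_mean = float(np.mean([counts.get(x, 0) for x in exc]))
        denom = inc_mean + exc_mean
        out.append(
            {
                "event_id": event.event_id,
                "sample": sample,
                "psi": inc_mean / denom if denom > 0 else np.nan,
                "inclusion_reads": inc_mean,
                "exclusion_reads": exc_mean,
            }
        )
    res = pd.DataFrame(out)
    if samples is not None:
        res = res.join(samples, on="sample")
    return res


def linked_event_test(table) -> dict:
    """Fisher exact test for association between two splice choices.

    ``table`` is a 2x2 array of phased molecule counts, rows = first-event
    choice, columns = second-event choice.  Returns the odds ratio, the
    one-sided (enrichment of the diagonal) and the two-sided p-value,
    computed from the conditional hypergeometric distribution.  Any zero
    margin gives p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 and nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; association undefined")
        return {"odds_ratio": np.nan, "p_greater": 1.0, "p_two_sided": 1.0}
    odds, p_two = stats.fisher_exact(t, alternative="two-sided")
    _, p_greater = stats.fisher_exact(t, alternative="greater")
    return {
        "odds_ratio": float(odds),
        "p_greater": float(p_greater),
        "p_two_sided": float(p_two),
    }
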