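"""Readers and writers for the plain-text interchange formats.

Count tables and junction counts travel as TSV, per-base coverage as
bedGraph (0-based half-open), structure annotations as BED6, exon models
as GTF (1-based, closed intervals; converted at the boundary).
"""

from __future__ import annotations

import os
from typing import Mapping

import gffutils
import numpy as np
import pandas as pd

from .splicing import ExonModel


def write_multiomics(data, outdir) -> None:
    """Write a generated multi-omics dataset as TSV tables.

    One ``<layer>.tsv`` count table plus design sidecar per layer, the
    planted truth and the peptide-count table.
    """
    from .normalize import write_counts, write_design

    os.makedirs(outdir, exist_ok=True)
    for layer, cm in data.counts.items():
        write_counts(cm, os.path.join(outdir, f"{layer}.tsv"))
        write_design(cm.design, os.path.join(outdir, f"{layer}.design.tsv"))
    data.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    data.peptides.to_csv(
        os.path.join(outdir, "peptides.tsv"), sep="\t", index_label="gene"
    )


def write_coverage(cov, outdir) -> None:
    """Write a coverage dataset: per-sample bedGraph, BED6 structures, truth."""
    os.makedirs(outdir, exist_ok=True)
    for sid in cov.samples.index:
        path = os.path.join(outdir, f"{sid.replace(':', '_')}.bedgraph")
        first = True
        for (tid, s), depth in cov.tracks.items():
            if s == sid:
                write_bedgraph(depth, tid, path, append=not first)
                first = False
    write_structures_bed(cov.structures, os.path.join(outdir, "structures.bed"))
    cov.truth.to_csv(
        os.path.join(outdir, "differential_truth.tsv"), sep="\t", index=False
    )


def write_bedgraph(
    track: np.ndarray, chrom: str, path, append: bool = False
) -> None:
    """Write one per-base track as bedGraph, merging equal-value runs."""
    depth = np.asarray(track)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if len(depth) == 0:
            return
        boundaries = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(depth)]])
        for s, e in zip(starts, ends):
            v = depth[s]
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-chrom arrays of the given lengths."""
    tracks = {c: np.zeros(n) for c, n in lengths.items()}
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "value"], comment="#"
    )
    for row in df.itertuples():
        if row.chrom not in tracks:
            raise ValueError(f"unknown chrom {row.chrom!r} in {path}")
        tracks[row.chrom][row.start : row.end] = row.value
    return tracks


def write_structures_bed(structures: pd.DataFrame, path) -> None:
    """Structure annotation as BED6 on transcript coordinates."""
    with open(path, "w") as fh:
        for row in structures.itertuples():
            half = row.span // 2
            fh.write(
                f"{row.transcript_id}\t{row.midpoint - half}\t"
                f"{row.midpoint + half}\t{row.structure_id}\t0\t+\n"
            )


def read_structures_bed(path, region: str = "3UTR") -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "structure_id": bed["name"],
            "transcript_id": bed["chrom"],
            "region": region,
            "midpoint": (bed["start"] + bed["end"]) // 2,
            "span": bed["end"] - bed["start"],
        }
    )


def write_junctions(junctions: pd.DataFrame, path) -> None:
    junctions.to_csv(path, sep="\t", index=False)


def read_junctions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "donor", "acceptor", "strand", "sample", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"junction table is missing columns {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ValueError("negative junction counts")
    return df


def write_exon_model_gtf(model: ExonModel, path, gene_id: str = "gene1") -> None:
    """GTF exon lines (1-based closed coordinates) for one exon model."""
    with open(path, "w") as fh:
        for tid, exons in model.transcripts.items():
            for s, e in exons:
                attrs = f'gene_id "{gene_id}"; transcript_id "{tid}";'
                fh.write(
                    f"{model.chrom}\tstressomics\texon\t{s + 1}\t{e}\t.\t"
                    f"{model.strand}\t.\t{attrs}\n"
                )


def read_exon_model_gtf(path) -> ExonModel:
    """Parse a single-locus GTF into an :class:`ExonModel` via gffutils."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: dict[str, list[tuple[int, int]]] = {}
    chroms, strands = set(), set()
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        transcripts.setdefault(tid, []).append((feat.start - 1, feat.end))
        chroms.add(feat.seqid)
        strands.add(feat.strand)
    if len(chroms) != 1 or len(strands) != 1:
        raise ValueError("exon model must live on one chrom and one strand")
    return ExonModel(
        chrom=chroms.pop(),
        strand=strands.pop(),
        transcripts={t: tuple(sorted(v)) for t, v in transcripts.items()},
    )
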