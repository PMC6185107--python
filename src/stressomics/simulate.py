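"""Synthetic multi-omics time courses with planted ground truth.

The generators emulate the study design the analysis assumes: four layers
(RNA exon counts, ribosome-footprint CDS counts, protein-footprint UTR
counts, protein intensities) measured at 0/1/4/8 h in two replicates under
two stress conditions, with the untreated 0 h sample shared between
conditions within a replicate.  Regulatory events are single step changes
of a gene's latent log abundance at one time boundary, propagated down the
expression cascade:

* a transcription event (``TRXP_RNADEG``) steps the RNA latent series and
  propagates additively to ribosome footprints, protein footprints and
  protein;
* a translation event (``TRL``) steps ribosome footprints and protein but
  leaves RNA untouched;
* a ``TRL_RNADEG`` event steps the protein-footprint series only;
* a ``TRL_PROTDEG`` event steps protein only.

Sequencing layers emit negative-binomial counts (variance m + phi*m^2);
the protein layer emits log-normal intensities with a given CV.  Setting
``nb_dispersion`` or ``protein_cv`` to 0 yields the exact noise-free limit
(counts equal their expectations), which downstream tests use to verify
the subtraction property exactly.

Separate generators produce per-base coverage tracks with Gaussian peaks
centered on annotated UTR structure midpoints, and junction read counts
following a binomial percent-spliced-in schedule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .changepoint import LEVELS
from .normalize import CountMatrix, LAYERS, make_design, sample_id
from .splicing import ExonModel, SpliceEvent

#: layers whose latent series a planted event at each level steps
CASCADE_LAYERS: dict[str, tuple[str, ...]] = {
    "TRXP_RNADEG": ("RNA", "RPF", "POP", "PROT"),
    "TRL": ("RPF", "PROT"),
    "TRL_RNADEG": ("POP",),
    "TRL_PROTDEG": ("PROT",),
}

TRUTH_COLUMNS = ["gene", "level", "condition", "boundary", "direction", "delta"]


@dataclass
class SimConfig:
    """Study-design and noise parameters of the multi-omics generator.

    Defaults reproduce the emulated design: 2,000 genes, times 0/1/4/8 h,
    two replicates, two stress conditions, 10% of genes per level carrying
    a one-natural-log-unit step event.  The baseline log abundance is drawn
    so the median gene has ~100 reads per sample at a 5e6-read library.
    """

    n_genes: int = 2000
    times: tuple[float, ...] = (0.0, 1.0, 4.0, 8.0)
    n_replicates: int = 2
    conditions: tuple[str, ...] = ("tm", "h2o2")
    event_fraction_per_level: float = 0.10
    effect_size_delta: float = 1.0
    nb_dispersion: float = 0.005
    protein_cv: float = 0.10
    library_size: float = 5e6
    baseline_log_sd: float = 0.5
    shared_event_fraction: float = 0.2
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        t = np.asarray(self.times, dtype=float)
        if t[0] != 0 or (np.diff(t) <= 0).any():
            raise ValueError("times must start at 0 and increase strictly")
        if not 0 <= self.event_fraction_per_level <= 1:
            raise ValueError("event_fraction_per_level must be in [0, 1]")
        if self.nb_dispersion < 0 or self.protein_cv < 0:
            raise ValueError("noise parameters must be >= 0 (0 = noise-free)")

    @property
    def baseline_log_mean(self) -> float:
        return float(np.log(100.0 * self.library_size / 5e6))


@dataclass
class MultiomicsData:
    counts: dict[str, CountMatrix]
    truth: pd.DataFrame
    peptides: pd.DataFrame  # proteins x replicate peptide-count table


def nb_counts(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial draws with variance ``m + dispersion * m**2``.

    ``dispersion=0`` returns the expectations themselves (noise-free limit).
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return mean.copy()
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean)).astype(float)


def _plant_events(cfg: SimConfig, rng: np.random.Generator, genes) -> pd.DataFrame:
    n_events = int(round(cfg.event_fraction_per_level * cfg.n_genes))
    order = rng.permutation(cfg.n_genes)
    rows = []
    cursor = 0
    n_bound = len(cfg.times) - 1
    for level in LEVELS:
        if cfg.allow_overlap:
            idx = rng.choice(cfg.n_genes, size=n_events, replace=False)
        else:
            idx = order[cursor : cursor + n_events]
            cursor += n_events
            if len(idx) < n_events:
                raise ValueError(
                    "not enough genes for disjoint events across levels; "
                    "set allow_overlap=True or lower event_fraction_per_level"
                )
        for g in idx:
            boundary = int(rng.integers(0, n_bound))
            direction = int(rng.choice([-1, 1]))
            if rng.random() < cfg.shared_event_fraction:
                conds = list(cfg.conditions)
            else:
                conds = [cfg.conditions[int(rng.integers(len(cfg.conditions)))]]
            for cond in conds:
                rows.append(
                    {
                        "gene": genes[g],
                        "level": level,
                        "condition": cond,
                        "boundary": boundary,
                        "direction": direction,
                        "delta": cfg.effect_size_delta,
                    }
                )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def generate_multiomics(cfg: SimConfig) -> MultiomicsData:
    """Generate all four layers plus the planted-truth table.

    Deterministic under a fixed seed.  The 0 h sample of each replicate is
    generated once per layer and shared between the two conditions, as in
    the emulated experimental design.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = pd.Index([f"G{i:05d}" for i in range(cfg.n_genes)], name="gene")
    T = len(cfg.times)
    base = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    truth = _plant_events(cfg, rng, genes)

    gene_pos = {g: i for i, g in enumerate(genes)}
    # latent[layer][condition]: genes x T
    latent = {
        layer: {c: np.tile(base[:, None], (1, T)) for c in cfg.conditions}
        for layer in LAYERS
    }
    for row in truth.itertuples():
        for layer in CASCADE_LAYERS[row.level]:
            latent[layer][row.condition][
                gene_pos[row.gene], row.boundary + 1 :
            ] += row.direction * row.delta

    sigma_prot = float(np.sqrt(np.log1p(cfg.protein_cv**2)))
    counts: dict[str, CountMatrix] = {}
    reps = list(range(1, cfg.n_replicates + 1))
    for layer in LAYERS:
        design = make_design(layer, cfg.conditions, cfg.times, reps)
        values = pd.DataFrame(index=genes, columns=design.index, dtype=float)
        shared_t0: dict[int, np.ndarray] = {}
        for cond in cfg.conditions:
            for ti, t in enumerate(cfg.times):
                mu = np.exp(latent[layer][cond][:, ti])
                for rep in reps:
                    col = sample_id(layer, cond, t, rep)
                    if t == 0 and rep in shared_t0:
                        values[col] = shared_t0[rep]
                        continue
                    if layer == "PROT":
                        if cfg.protein_cv == 0:
                            v = mu.copy()
                        else:
                            v = mu * np.exp(
                                rng.normal(0.0, sigma_prot, cfg.n_genes)
                            )
                    else:
                        v = nb_counts(mu, cfg.nb_dispersion, rng)
                    values[col] = v
                    if t == 0:
                        shared_t0[rep] = v
        counts[layer] = CountMatrix(values, design)

    peptides = pd.DataFrame(
        2 + rng.poisson(3.0, size=(cfg.n_genes, cfg.n_replicates)),
        index=genes,
        columns=[f"rep{r}" for r in reps],
    )
    return MultiomicsData(counts=counts, truth=truth, peptides=peptides)


# ---------------------------------------------------------------------------
# coverage tracks around UTR structures


@dataclass
class CoverageConfig:
    """Parameters of the structure-coverage generator.

    Each transcript carries one annotated structure; protein-footprint
    tracks get a Gaussian read peak (sd ~20 nt) at the structure midpoint
    on top of a uniform background, matched RNA tracks are uniform.
    Structures designated differential have their peak amplitude multiplied
    by ``diff_fold`` in the final-time samples.
    """

    transcript_length: int = 1500
    background_rate: float = 0.02  # reads per base per sample
    rna_rate: float = 0.10
    peak_reads: float = 100.0
    peak_sd: float = 20.0
    diff_fraction: float = 0.05
    diff_fold: float = 4.0
    times: tuple[float, ...] = (0.0, 1.0, 4.0, 8.0)
    n_replicates: int = 2
    condition: str = "tm"
    span: int = 100
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transcript_length < 600:
            raise ValueError(
                "transcript_length must be >= 600 so +-250 nt windows plus "
                "margin fit around a structure midpoint"
            )
        if self.peak_sd <= 0:
            raise ValueError("peak_sd must be positive")


@dataclass
class CoverageData:
    tracks: dict[tuple[str, str], np.ndarray]  # (transcript, sample) -> depth
    samples: pd.DataFrame  # index sample_id: layer, condition, time, replicate
    structures: pd.DataFrame  # structure_id, transcript_id, region, midpoint, span
    truth: pd.DataFrame  # structure_id, fold
    transcript_lengths: dict[str, int]


def _peak_positions(
    rng: np.random.Generator, mid: int, amplitude: float, sd: float, noise: bool
) -> np.ndarray:
    if noise:
        n = rng.poisson(amplitude)
        pos = mid + rng.normal(0.0, sd, n)
    else:
        n = int(round(amplitude))
        q = (np.arange(n) + 0.5) / n
        pos = mid + sd * stats.norm.ppf(q)
    return np.rint(pos).astype(int)


def _uniform_positions(
    rng: np.random.Generator, length: int, rate: float, noise: bool
) -> np.ndarray:
    if rate <= 0:
        return np.empty(0, dtype=int)
    if noise:
        n = rng.poisson(rate * length)
        return rng.integers(0, length, n)
    n = int(round(rate * length))
    return np.linspace(0, length - 1, n).astype(int)


def generate_coverage(
    n_structures: int, cfg: CoverageConfig | None = None
) -> CoverageData:
    """Per-base read 5'-end coverage around planted UTR structures.

    Returns protein-footprint (``POP``) and matched ``RNA`` tracks for all
    time/replicate samples, the structure annotation, and the truth table
    of differentially bound structures.  ``cfg.noise=False`` places reads
    deterministically at peak quantiles so window counts equal the peak
    mass exactly.
    """
    cfg = cfg or CoverageConfig()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.transcript_length
    margin = 300
    tids = [f"T{i:04d}" for i in range(n_structures)]
    midpoints = rng.integers(margin, L - margin, n_structures)
    structures = pd.DataFrame(
        {
            "structure_id": [f"S{i:04d}" for i in range(n_structures)],
            "transcript_id": tids,
            "region": "3UTR",
            "midpoint": midpoints,
            "span": cfg.span,
        }
    )
    n_diff = int(round(cfg.diff_fraction * n_structures))
    diff_idx = rng.choice(n_structures, size=n_diff, replace=False)
    is_diff = np.zeros(n_structures, dtype=bool)
    is_diff[diff_idx] = True
    truth = structures.loc[is_diff, ["structure_id"]].copy()
    truth["fold"] = cfg.diff_fold
    if cfg.diff_fold == 1.0:  # fold 1 plants no change anywhere
        truth = truth.iloc[0:0]
        is_diff[:] = False

    sample_rows = []
    tracks: dict[tuple[str, str], np.ndarray] = {}
    reps = list(range(1, cfg.n_replicates + 1))
    t_final = cfg.times[-1]
    for layer in ("POP", "RNA"):
        for t in cfg.times:
            for rep in reps:
                sid = sample_id(layer, cfg.condition, t, rep)
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "layer": layer,
                        "condition": cfg.condition,
                        "time": float(t),
                        "replicate": rep,
                    }
                )
                for i, tid in enumerate(tids):
                    depth = np.zeros(L, dtype=int)
                    if layer == "POP":
                        amp = cfg.peak_reads
                        if is_diff[i] and t == t_final:
                            amp *= cfg.diff_fold
                        pos = _peak_positions(
                            rng, int(midpoints[i]), amp, cfg.peak_sd, cfg.noise
                        )
                        pos = np.concatenate(
                            [
                                pos,
                                _uniform_positions(
                                    rng, L, cfg.background_rate, cfg.noise
                                ),
                            ]
                        )
                    else:
                        pos = _uniform_positions(rng, L, cfg.rna_rate, cfg.noise)
                    pos = pos[(pos >= 0) & (pos < L)]
                    np.add.at(depth, pos, 1)
                    tracks[(tid, sid)] = depth
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    return CoverageData(
        tracks=tracks,
        samples=samples,
        structures=structures,
        truth=truth.reset_index(drop=True),
        transcript_lengths={tid: L for tid in tids},
    )


# ---------------------------------------------------------------------------
# junction reads


def generate_junctions(
    event: SpliceEvent,
    psi_schedule: Sequence[float],
    depth: int,
    seed: int,
    times: Sequence[float] = (0.0, 1.0, 4.0, 8.0),
    n_replicates: int = 1,
    condition: str = "tm",
) -> pd.DataFrame:
    """Binomial junction read counts following a per-time PSI schedule.

    For each sample the inclusion draw is X ~ Binomial(depth, psi(t)); every
    inclusion junction of the event reports X reads (they tag the same
    molecules) and every exclusion junction reports depth - X, so the PSI
    estimator mean(inclusion)/(mean inclusion + mean exclusion) recovers
    psi(t) in expectation.
    """
    psi = np.asarray(psi_schedule, dtype=float)
    if len(psi) != len(times):
        raise ValueError("psi_schedule and times lengths differ")
    if ((psi < 0) | (psi > 1)).any():
        raise ValueError("psi values must lie in [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for ti, t in enumerate(times):
        for rep in range(1, n_replicates + 1):
            x = int(rng.binomial(depth, psi[ti]))
            sample = f"{condition}:{int(t)}:{rep}"
            for l, r in event.inclusion_junctions:
                d, a = (l, r) if event.strand == "+" else (r, l)
                rows.append((event.chrom, d, a, event.strand, sample, x))
            for l, r in event.exclusion_junctions:
                d, a = (l, r) if event.strand == "+" else (r, l)
                rows.append(
                    (event.chrom, d, a, event.strand, sample, depth - x)
                )
    return pd.DataFrame(
        rows, columns=["chrom", "donor", "acceptor", "strand", "sample", "count"]
    )


def generate_splice_models(
    n_models: int,
    seed: int,
    types: Sequence[str] = (
        "exon_skipping",
        "alt5",
        "alt3",
        "mutually_exclusive",
    ),
) -> list[tuple[ExonModel, SpliceEvent]]:
    """Random annotated exon models, each with one planted splice event.

    Event types cycle through ``types``; coordinates, exon and intron
    lengths are random but the planted junction topology is exact, so a
    classifier must recover precisely one event per model.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[ExonModel, SpliceEvent]] = []
    for i in range(n_models):
        type_ = types[i % len(types)]
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = f"chr{i + 1}"
        start = int(rng.integers(1_000, 1_000_000))

        def _exon(pos: int) -> tuple[int, int]:
            return (pos, pos + int(rng.integers(80, 300)))

        def _gap() -> int:
            return int(rng.integers(200, 2000))

        exons: list[tuple[int, int]] = []
        pos = start
        n_exons = {"exon_skipping": 3, "mutually_exclusive": 4}.get(type_, 2)
        for _ in range(n_exons):
            ex = _exon(pos)
            exons.append(ex)
            pos = ex[1] + _gap()

        eid = f"planted_{i}"
        if type_ == "exon_skipping":
            A, B, C = exons
            inc = [(A[1], B[0]), (B[1], C[0])]
            exc = [(A[1], C[0])]
            transcripts = {
                f"t{i}_inc": (A, B, C),
                f"t{i}_exc": (A, C),
            }
            ev_exons = [B]
        elif type_ == "mutually_exclusive":
            A, B, C, D = exons
            inc = [(A[1], B[0]), (B[1], D[0])]
            exc = [(A[1], C[0]), (C[1], D[0])]
            transcripts = {
                f"t{i}_inc": (A, B, D),
                f"t{i}_exc": (A, C, D),
            }
            ev_exons = [B, C]
        else:
            A, Bx = exons
            shift = int(rng.integers(30, 70))
            # genomic pattern: shared-left = alt3 on +, alt5 on -;
            # pick the pattern matching the requested transcription-strand type
            shared_left = (type_ == "alt3") == (strand == "+")
            if shared_left:
                b1 = (Bx[0], Bx[1])
                b2 = (Bx[0] + shift, Bx[1])
                inc = [(A[1], b1[0])]
                exc = [(A[1], b2[0])]
                transcripts = {f"t{i}_inc": (A, b1), f"t{i}_exc": (A, b2)}
                ev_exons = [(b1[0], b2[0])]
            else:
                a1 = (A[0], A[1] - shift)
                a2 = (A[0], A[1])
                inc = [(a2[1], Bx[0])]
                exc = [(a1[1], Bx[0])]
                transcripts = {f"t{i}_inc": (a2, Bx), f"t{i}_exc": (a1, Bx)}
                ev_exons = [(a1[1], a2[1])]
        model = ExonModel(
            chrom=chrom,
            strand=strand,
            transcripts={k: tuple(v) for k, v in transcripts.items()},
        )
        event = SpliceEvent(
            event_id=eid,
            type=type_,
            chrom=chrom,
            strand=strand,
            inclusion_junctions=tuple(sorted(inc)),
            exclusion_junctions=tuple(sorted(exc)),
            exons=tuple(sorted(ev_exons)),
        )
        out.append((model, event))
    return out
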