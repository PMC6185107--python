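"""End-to-end driver: raw count tables to called regulatory events.

Chains the standard stages - minimum-count filtering, median-of-ratios
normalization for the sequencing layers, per-stress geometric-mean
normalization for protein intensities, restriction to the core gene set,
natural-log median-centered series, optional Gaussian-process smoothing,
paired-layer change-point scoring and the both-replicate event rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import changepoint as cp
from . import events as ev
from . import normalize as nz


@dataclass
class PipelineResult:
    scores: pd.DataFrame
    events: pd.DataFrame
    core_genes: list[str]
    series: pd.DataFrame  # tidy log series of all layers
    size_factors: dict[str, pd.Series]


def run_event_pipeline(
    counts: dict[str, nz.CountMatrix],
    fdr_threshold: float = 0.2,
    min_count: float = 10,
    smooth: bool = False,
    peptide_counts: pd.DataFrame | None = None,
    scale_floor: float | None = None,
    min_genes: int = 50,
    same_boundary: bool = False,
) -> PipelineResult:
    """Run the full regulatory-event analysis over the provided layers.

    ``counts`` maps layer names (RNA, RPF, POP, PROT - any subset
    containing RNA) to their count matrices.  Levels whose output layer is
    missing are skipped.  Returns per-run change-point scores, the called
    events, the core gene set and the intermediate log series.
    """
    if "RNA" not in counts:
        raise ValueError("the RNA layer is required (it is every level's input)")
    normalized: dict[str, nz.CountMatrix] = {}
    factors: dict[str, pd.Series] = {}
    for layer, cm in counts.items():
        if layer == "PROT":
            normalized[layer], factors[layer] = nz.normalize_protein(
                cm, peptide_counts
            )
        else:
            filtered = nz.filter_min_count(cm, threshold=min_count)
            normalized[layer], factors[layer] = nz.normalize_median_ratio(
                filtered
            )
    core = nz.core_gene_set(normalized)
    normalized = {l: cm.subset_genes(core) for l, cm in normalized.items()}

    series = pd.concat(
        [nz.to_log_series(cm) for cm in normalized.values()],
        ignore_index=True,
    )

    design = counts["RNA"].design
    times = sorted(design["time"].unique())
    conditions = sorted(design["condition"].unique())
    replicates = sorted(design["replicate"].unique())

    score_frames = []
    for level, (out_layer, in_layer) in cp.LEVEL_PAIRING.items():
        if out_layer not in normalized:
            continue
        for cond in conditions:
            for rep in replicates:
                out_wide = nz.pivot_series(series, out_layer, cond, rep)
                if smooth:
                    out_wide = nz.gp_smooth(out_wide)
                if in_layer is None:
                    signal = cp.regulatory_signal(out_wide, None)
                else:
                    in_wide = nz.pivot_series(series, in_layer, cond, rep)
                    if smooth:
                        in_wide = nz.gp_smooth(in_wide)
                    signal = cp.regulatory_signal(
                        out_wide, in_wide.loc[out_wide.index]
                    )
                score_frames.append(
                    cp.changepoint_scores(
                        signal,
                        level=level,
                        condition=cond,
                        replicate=rep,
                        min_genes=min_genes,
                        scale_floor=scale_floor,
                    )
                )
    scores = pd.concat(score_frames, ignore_index=True)
    events = ev.call_events(
        scores, times, fdr_threshold=fdr_threshold, same_boundary=same_boundary
    )
    return PipelineResult(
        scores=scores,
        events=events,
        core_genes=core,
        series=series,
        size_factors=factors,
    )
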