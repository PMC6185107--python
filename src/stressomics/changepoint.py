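"""Paired-layer regulatory signals and change-point scoring.

Each regulatory level is defined by subtracting an "input" layer from an
"output" layer on the natural-log scale, so that changes already explained
upstream cancel:

====================  ======  =====
level                 output  input
====================  ======  =====
``TRXP_RNADEG``       RNA     constant (DNA abundance assumed unchanged)
``TRL``               RPF     RNA
``TRL_RNADEG``        POP     RNA
``TRL_PROTDEG``       PROT    RNA
====================  ======  =====

A regulatory event at time boundary i (between consecutive observed times
t_i and t_{i+1}) shifts the signal m(t) by a step.  The score for gene g at
boundary i is the adjacent difference d_g(i) = m_g(t_{i+1}) - m_g(t_i),
standardized against the cross-gene empirical null at that boundary: the
per-boundary median of d is removed (absorbing global responses such as
bulk translation shutdown) and the robust scale is 1.4826 x MAD.  Two-sided
normal p-values are Benjamini-Hochberg adjusted over all genes and
boundaries of the run (one level/condition/replicate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

LEVELS = ("TRXP_RNADEG", "TRL", "TRL_RNADEG", "TRL_PROTDEG")

#: output and input layer per regulatory level (input None = constant)
LEVEL_PAIRING: dict[str, tuple[str, str | None]] = {
    "TRXP_RNADEG": ("RNA", None),
    "TRL": ("RPF", "RNA"),
    "TRL_RNADEG": ("POP", "RNA"),
    "TRL_PROTDEG": ("PROT", "RNA"),
}


def regulatory_signal(
    output: pd.DataFrame, input_: pd.DataFrame | None
) -> pd.DataFrame:
    """Log output-minus-input series, genes x times.

    ``input_=None`` means a constant input (transcription level: DNA
    abundance does not change), i.e. the signal is the output itself.
    Raises on mismatched gene or time grids.
    """
    if input_ is None:
        return output.copy()
    if not output.index.equals(input_.index) or list(output.columns) != list(
        input_.columns
    ):
        raise ValueError("output and input series are on different grids")
    return output - input_


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(p, method="bh")


def changepoint_scores(
    signal: pd.DataFrame,
    level: str,
    condition: str,
    replicate: int,
    min_genes: int = 50,
    center: bool = True,
    scale_floor: float | None = None,
) -> pd.DataFrame:
    """Score every (gene, boundary) of one level/condition/replicate run.

    ``signal`` is genes x times (columns sorted ascending, in hours).
    Returns a frame with columns gene, level, condition, replicate,
    boundary, d, z, p, q; one row per gene and boundary.

    The per-boundary robust scale must be positive; a zero scale means a
    degenerate (noise-free) input and raises unless ``scale_floor`` is set,
    in which case the scale is floored at that value.
    """
    times = np.asarray(signal.columns, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least 2 time points")
    if signal.shape[0] < min_genes:
        raise ValueError(
            f"only {signal.shape[0]} genes; at least {min_genes} are needed "
            "to estimate the per-boundary scale (pool runs or lower min_genes)"
        )
    m = signal.to_numpy(dtype=float)
    d = np.diff(m, axis=1)  # genes x (T-1)
    med = np.median(d, axis=0) if center else np.zeros(d.shape[1])
    resid = d - med
    s = 1.4826 * np.median(np.abs(resid - np.median(resid, axis=0)), axis=0)
    if center:
        # residual median is 0 by construction; keep formula explicit anyway
        s = 1.4826 * np.median(np.abs(resid), axis=0)
    if scale_floor is not None:
        s = np.maximum(s, scale_floor)
    if (s <= 0).any():
        bad = int(np.argmin(s))
        raise ValueError(
            f"zero robust scale at boundary {bad}: degenerate (noise-free) "
            "signal; pass scale_floor to score anyway"
        )
    z = resid / s
    p = 2 * stats.norm.sf(np.abs(z))
    q = bh_fdr(p.ravel()).reshape(p.shape)
    n_genes, n_bound = d.shape
    return pd.DataFrame(
        {
            "gene": np.repeat(signal.index.to_numpy(), n_bound),
            "level": level,
            "condition": condition,
            "replicate": replicate,
            "boundary": np.tile(np.arange(n_bound), n_genes),
            "d": d.ravel(),
            "z": z.ravel(),
            "p": p.ravel(),
            "q": q.ravel(),
        }
    )
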