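"""Count ingestion, filtering and normalization for the four expression layers.

The pipeline measures each gene at four layers along the gene-expression
cascade: RNA exon counts (``RNA``), ribosome-footprint CDS counts (``RPF``),
non-ribosomal protein-footprint UTR counts (``POP``) and protein intensities
(``PROT``), at several time points after stress treatment, in replicate, under
two stress conditions.  This module turns raw per-sample tables into the
median-centered natural-log abundance series that the change-point analysis
consumes, and into the z-scored fold-change matrix used for clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LAYERS = ("RNA", "RPF", "POP", "PROT")

DESIGN_COLUMNS = ("layer", "condition", "time", "replicate")


def sample_id(layer: str, condition: str, time: float, replicate: int) -> str:
    """Canonical sample identifier, ``layer:condition:time:replicate``."""
    t = int(time) if float(time) == int(time) else time
    return f"{layer}:{condition}:{t}:{replicate}"


def make_design(
    layer: str,
    conditions: Sequence[str],
    times: Sequence[float],
    replicates: Sequence[int],
) -> pd.DataFrame:
    """Build a sample design table for one layer (full factorial grid)."""
    rows = []
    for cond in conditions:
        for t in times:
            for rep in replicates:
                rows.append(
                    {
                        "sample_id": sample_id(layer, cond, t, rep),
                        "layer": layer,
                        "condition": cond,
                        "time": float(t),
                        "replicate": int(rep),
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def validate_design(design: pd.DataFrame) -> None:
    """Check design invariants: unique keys, complete time grid per series."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design is missing columns {missing}")
    keys = design[list(DESIGN_COLUMNS)]
    if keys.duplicated().any():
        bad = keys[keys.duplicated()].iloc[0].to_dict()
        raise ValueError(f"duplicate (layer, condition, time, replicate): {bad}")
    all_times = set(design["time"])
    for (layer, cond, rep), grp in design.groupby(
        ["layer", "condition", "replicate"]
    ):
        if set(grp["time"]) != all_times:
            raise ValueError(
                f"incomplete time grid for layer={layer} condition={cond} "
                f"replicate={rep}: has {sorted(grp['time'])}, "
                f"expected {sorted(all_times)}"
            )


@dataclass
class CountMatrix:
    """Gene x sample measurements with their sample design.

    ``values`` is a genes-by-samples DataFrame of nonnegative reads or
    intensities; ``design`` is indexed by sample id with columns
    ``layer, condition, time, replicate`` and must cover exactly the columns
    of ``values``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if (self.values.to_numpy() < 0).any():
            g, s = np.argwhere(self.values.to_numpy() < 0)[0]
            raise ValueError(
                f"negative value for gene {self.values.index[g]!r} "
                f"in sample {self.values.columns[s]!r}"
            )
        if list(self.values.columns) != list(self.design.index):
            raise ValueError("design index does not match value columns")
        validate_design(self.design)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        keep = [g for g in genes if g in self.values.index]
        return CountMatrix(self.values.loc[keep], self.design)


def write_counts(cm: CountMatrix, path) -> None:
    cm.values.to_csv(path, sep="\t", index_label="gene")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t").set_index("sample_id")
    design["time"] = design["time"].astype(float)
    design["replicate"] = design["replicate"].astype(int)
    return design


def read_counts(path, design: pd.DataFrame) -> CountMatrix:
    """Read a genes-x-samples TSV whose header must match ``design``.

    Raises with the offending row or sample named on malformed input.
    """
    values = pd.read_csv(path, sep="\t", index_col="gene")
    values.columns.name = "sample_id"
    extra = [c for c in values.columns if c not in design.index]
    absent = [s for s in design.index if s not in values.columns]
    if extra or absent:
        raise ValueError(
            f"header/design mismatch: unexpected samples {extra}, "
            f"missing samples {absent}"
        )
    values = values[list(design.index)]
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            bad = values[pd.to_numeric(values[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric count in sample {col!r}, "
                f"gene {bad.index[0] if len(bad) else '?'}"
            )
    neg = values.lt(0).any(axis=1)
    if neg.any():
        raise ValueError(f"negative count in row for gene {values.index[neg][0]!r}")
    return CountMatrix(values, design)


# ---------------------------------------------------------------------------
# normalization


def size_factors_median_ratio(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (the DESeq-style estimator).

    For every gene with all-positive counts, compute the ratio of each
    sample's count to the gene's geometric mean across samples; the sample's
    size factor is the median of these ratios.  Dividing counts by the
    factors equalizes sequencing depth.
    """
    v = cm.values.to_numpy(dtype=float)
    allpos = (v > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has all-positive counts; filter genes or check input"
        )
    pos = v[allpos]
    geomean = np.exp(np.mean(np.log(pos), axis=1))
    ratios = pos / geomean[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=cm.samples, name="size_factor")


def normalize_median_ratio(cm: CountMatrix) -> tuple[CountMatrix, pd.Series]:
    factors = size_factors_median_ratio(cm)
    return CountMatrix(cm.values / factors, cm.design), factors


def filter_min_count(
    cm: CountMatrix, threshold: float = 10, per_sample: bool = False
) -> CountMatrix:
    """Keep genes with summed count across all samples >= ``threshold``.

    ``per_sample=True`` instead requires every sample to reach the threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if per_sample:
        keep = cm.values.ge(threshold).all(axis=1)
    else:
        keep = cm.values.sum(axis=1) >= threshold
    return CountMatrix(cm.values.loc[keep], cm.design)


def normalize_protein(
    cm: CountMatrix,
    peptide_counts: pd.DataFrame | None = None,
    min_peptides: int = 2,
) -> tuple[CountMatrix, pd.Series]:
    """Filter and depth-normalize protein intensities.

    Proteins with a missing (NaN or zero) intensity in any sample, or
    identified by fewer than ``min_peptides`` peptides in either replicate
    (``peptide_counts``: proteins x replicates), are removed.  Within each
    stress condition separately, each protein's intensities are divided by
    the protein's geometric mean across that condition's samples; the median
    of these ratios over proteins is the per-sample size factor.
    """
    values = cm.values.copy()
    bad = values.isna().any(axis=1) | values.le(0).any(axis=1)
    if peptide_counts is not None:
        pc = peptide_counts.reindex(values.index)
        bad |= pc.isna().any(axis=1) | pc.lt(min_peptides).any(axis=1)
    values = values.loc[~bad]
    if values.empty:
        raise ValueError("all proteins removed by missingness/peptide filters")
    factors = pd.Series(index=cm.samples, dtype=float, name="size_factor")
    for cond, grp in cm.design.groupby("condition"):
        cols = [s for s in cm.samples if s in grp.index]
        sub = values[cols].to_numpy(dtype=float)
        geomean = np.exp(np.mean(np.log(sub), axis=1))
        ratios = sub / geomean[:, None]
        factors[cols] = np.median(ratios, axis=0)
    return CountMatrix(values / factors, cm.design), factors


def core_gene_set(cms: Mapping[str, CountMatrix]) -> list[str]:
    """Genes present in every layer after filtering (sorted, stable).

    The paper calls this the core set: genes with complete measurements in
    all layers and replicates.  Returns an empty list (with a warning) if
    the intersection is empty.
    """
    if not cms:
        return []
    its: set[str] | None = None
    for cm in cms.values():
        genes = set(cm.genes)
        its = genes if its is None else its & genes
    if not its:
        warnings.warn("core gene set is empty: layers share no genes")
        return []
    first = next(iter(cms.values()))
    return [g for g in first.genes if g in its]


# ---------------------------------------------------------------------------
# log series and smoothing


def to_log_series(cm: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Natural-log, median-centered abundance series (tidy long format).

    Values become ``ln(count + pseudocount)`` and are centered per gene by
    the median over all samples of that layer/condition (both replicates,
    all times).  Columns: gene, layer, condition, replicate, time, value.
    """
    logged = np.log(cm.values + pseudocount)
    out = []
    for (layer, cond), grp in cm.design.groupby(["layer", "condition"]):
        cols = [s for s in cm.samples if s in grp.index]
        block = logged[cols]
        centered = block.sub(block.median(axis=1), axis=0)
        long = centered.reset_index(names="gene").melt(
            id_vars="gene", var_name="sample_id", value_name="value"
        )
        long["layer"] = layer
        long["condition"] = cond
        long["time"] = long["sample_id"].map(grp["time"])
        long["replicate"] = long["sample_id"].map(grp["replicate"])
        out.append(long.drop(columns="sample_id"))
    return pd.concat(out, ignore_index=True)


def pivot_series(
    series: pd.DataFrame, layer: str, condition: str, replicate: int
) -> pd.DataFrame:
    """One (layer, condition, replicate) series as a genes x times frame."""
    sub = series[
        (series["layer"] == layer)
        & (series["condition"] == condition)
        & (series["replicate"] == replicate)
    ]
    wide = sub.pivot(index="gene", columns="time", values="value")
    return wide[sorted(wide.columns)]


def gp_smooth(
    wide: pd.DataFrame,
    lengthscale: float = 4.0,
    noise_to_signal: float = 0.25,
    enabled: bool = True,
) -> pd.DataFrame:
    """Gaussian-process smoothing of each gene's time series.

    Squared-exponential kernel over the observed times (frame columns, in
    hours) with lengthscale 4 h; the signal variance is the series' sample
    variance (floored at 1e-6) and the noise variance is ``noise_to_signal``
    times it.  Returns the posterior mean at the observed times.  Because
    noise is parametrized as a fixed fraction of the signal variance, the
    posterior mean reduces to a single linear smoother shared by all genes:
    ``mu + K (K + rho I)^{-1} (y - mu)`` with rho = noise_to_signal.

    A constant series is returned unchanged; with ``enabled=False`` the
    input is returned as-is.
    """
    if not enabled:
        return wide
    times = np.asarray(wide.columns, dtype=float)
    if len(times) < 3:
        raise ValueError("GP smoothing needs at least 3 time points")
    sq = (times[:, None] - times[None, :]) ** 2
    K = np.exp(-0.5 * sq / lengthscale**2)
    smoother = K @ np.linalg.inv(K + noise_to_signal * np.eye(len(times)))
    y = wide.to_numpy(dtype=float)
    mu = y.mean(axis=1, keepdims=True)
    smoothed = mu + (y - mu) @ smoother.T
    return pd.DataFrame(smoothed, index=wide.index, columns=wide.columns)


def fold_change_zscore(series: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Z-scored log10 fold changes versus time 0, for clustering.

    For each gene and each (layer, condition, replicate) series the entry at
    time t>0 is ``log10(value_t / value_0)`` (computed from the natural-log
    series).  Each gene's entries are then standardized within a
    (layer, condition) block: mean-centered and divided by the population
    standard deviation (``ddof=0``; set ``ddof=1`` for the sample SD).
    Blocks with zero SD are set to 0 with a warning.

    Returns genes x (layer, condition, replicate, time) with a column
    MultiIndex.
    """
    sub = series[series["time"] > 0].copy()
    t0 = series[series["time"] == 0]
    if t0.empty:
        raise ValueError("time 0 is required to form fold changes")
    key = ["gene", "layer", "condition", "replicate"]
    base = t0.set_index(key)["value"]
    sub["lfc"] = (
        sub["value"].to_numpy()
        - base.reindex(pd.MultiIndex.from_frame(sub[key])).to_numpy()
    ) / np.log(10)
    wide = sub.pivot_table(
        index="gene",
        columns=["layer", "condition", "replicate", "time"],
        values="lfc",
    )
    zero_sd = 0
    for (layer, cond) in {(l, c) for l, c, _, _ in wide.columns}:
        cols = [c for c in wide.columns if c[0] == layer and c[1] == cond]
        block = wide[cols].to_numpy()
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=ddof, keepdims=True)
        flat = sd[:, 0] == 0
        zero_sd += int(flat.sum())
        sd[flat] = 1.0
        wide[cols] = (block - mean) / sd
        wide.loc[flat, cols] = 0.0
    if zero_sd:
        warnings.warn(f"{zero_sd} gene/block rows had zero SD; set to 0")
    return wide
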