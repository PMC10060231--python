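"""Fold-change trajectories across prophase-I stages and pattern clustering.

For every gene, normalized window counts (pause / body / post-PAS) in each
stage are expressed as log2 fold changes relative to the earliest stage (LZ),
giving a 9-column trajectory. Genes are then grouped by trajectory shape with
seeded k-means on per-gene z-scored rows, after setting aside near-flat
trajectories; this recovers the biologically expected archetypes — a
pachynema transcriptional burst (pause-release targets) versus steady
transcription that decays in diplonema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .runon import LibraryNorm

__all__ = [
    "TrajectoryMatrix",
    "ClusterResult",
    "build_trajectories",
    "cluster_trajectories",
    "pattern_pi_contrast",
    "concordance",
]

WINDOWS = ("pause", "body", "postpas")


@dataclass(frozen=True)
class ClusterResult:
    """Cluster assignments (-1 = unassigned) and per-cluster mean trajectories."""

    assignments: pd.Series
    centroids: pd.DataFrame
    k: int


def build_trajectories(
    counts: dict[str, pd.DataFrame],
    size_factors: dict[str, float] | list[LibraryNorm],
    pseudocount: float = 1.0,
    reference: str = "LZ",
    rescale_size_factors: bool = True,
) -> pd.DataFrame:
    """Log2 fold-change trajectory matrix relative to the reference stage.

    Parameters
    ----------
    counts :
        Per stage, a DataFrame indexed by gene id with columns
        ``pause, body, postpas`` of raw window counts.
    size_factors :
        Per-stage DESeq2-style size factors (counts are divided by them), or
        the LibraryNorm list from :func:`prophasetx.runon.normalization_factors`.
    pseudocount :
        Added to normalized counts before the log ratio (default 1).
    rescale_size_factors :
        Rescale the size factors to geometric mean 1 (the DESeq2 convention)
        so normalized counts stay on the raw-count scale and the pseudocount
        acts as intended. Ratios between stages are unaffected.

    Genes missing from any stage are dropped. Reference-stage columns are
    identically zero by construction.
    """
    if isinstance(size_factors, list):
        size_factors = {n.stage: n.size_factor for n in size_factors}
    if rescale_size_factors:
        gm = float(np.exp(np.mean(np.log(list(size_factors.values())))))
        size_factors = {s: f / gm for s, f in size_factors.items()}
    if reference not in counts:
        raise KeyError(f"reference stage {reference!r} missing from counts")
    stages = [reference] + [s for s in counts if s != reference]
    common = None
    for s in stages:
        idx = counts[s].index
        common = idx if common is None else common.intersection(idx)
    common = common.sort_values()
    dropped = set().union(*(set(counts[s].index) for s in stages)) - set(common)
    norm = {
        s: counts[s].loc[common, list(WINDOWS)] / size_factors[s] for s in stages
    }
    cols, data = [], []
    ref = norm[reference]
    for s in stages:
        for w in WINDOWS:
            cols.append(f"{s}_{w}")
            data.append(
                np.log2((norm[s][w] + pseudocount) / (ref[w] + pseudocount))
            )
    M = pd.DataFrame(dict(zip(cols, data)), index=common)
    M.attrs["dropped_genes"] = sorted(dropped)
    M.attrs["reference"] = reference
    return M


def cluster_trajectories(
    M: pd.DataFrame,
    k: int,
    seed: int = 0,
    flatness_threshold: float = 0.1,
) -> ClusterResult:
    """Seeded k-means over z-scored trajectories with a flatness filter.

    Genes whose trajectory never departs the reference by more than
    ``flatness_threshold`` (max |log2 FC|) are left unassigned (-1), mirroring
    tightness-based cluster exclusion. Rows are processed in sorted gene-id
    order so assignments are invariant to input row order.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(M):
        raise ValueError(f"k={k} exceeds number of genes ({len(M)})")
    M = M.sort_index()
    X = M.to_numpy(dtype=float)
    span = np.abs(X).max(axis=1)
    row_sd = X.std(axis=1)
    usable = (span >= flatness_threshold) & (row_sd > 0)
    assignments = pd.Series(-1, index=M.index, name="cluster")
    if usable.sum() >= k:
        Z = (X[usable] - X[usable].mean(axis=1, keepdims=True)) / row_sd[
            usable, None
        ]
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = km.fit_predict(Z)
        # relabel clusters by decreasing size for stable downstream naming
        order = np.argsort(-np.bincount(labels, minlength=k), kind="stable")
        remap = np.empty(k, dtype=int)
        remap[order] = np.arange(k)
        assignments.loc[M.index[usable]] = remap[labels]
    centroids = (
        M[assignments >= 0]
        .groupby(assignments[assignments >= 0])
        .mean()
        .reindex(range(k))
    )
    centroids.index.name = "cluster"
    return ClusterResult(assignments=assignments, centroids=centroids, k=k)


def pattern_pi_contrast(
    result: ClusterResult, pi_table: pd.DataFrame
) -> pd.DataFrame:
    """Median and quartiles of pausing index per cluster per stage.

    ``pi_table`` is the long-format table from
    :func:`prophasetx.pausing.pausing_index_table`. Unassigned genes are
    excluded; empty clusters yield empty summaries (no rows).
    """
    df = pi_table.merge(
        result.assignments.rename("cluster"),
        left_on="gene_id",
        right_index=True,
        how="inner",
    )
    df = df[df["cluster"] >= 0]
    if df.empty:
        return pd.DataFrame(
            columns=["cluster", "stage", "n", "median_pi", "q1_pi", "q3_pi"]
        )
    out = (
        df.groupby(["cluster", "stage"])["pausing_index"]
        .agg(
            n="count",
            median_pi="median",
            q1_pi=lambda x: x.quantile(0.25),
            q3_pi=lambda x: x.quantile(0.75),
        )
        .reset_index()
    )
    return out


def concordance(
    x, y, pseudocount: float = 1.0, log_transform: bool = True
) -> tuple[float, float]:
    """OLS slope and Pearson r between two per-gene quantification vectors.

    Used to compare nascent transcription against mature mRNA abundance: the
    slope of log(mRNA) on log(nascent) measures the ratio of nascent to
    mature transcripts; values are log2-transformed with a pseudocount unless
    ``log_transform`` is False (pass pre-logged values then).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 genes")
    if log_transform:
        x = np.log2(x + pseudocount)
        y = np.log2(y + pseudocount)
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue)
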