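"""Per-gene window summaries: pausing index, post-PAS retention, metagenes.

The pause window is the first 250 bp downstream of the TSS (where
promoter-proximally paused Pol II accumulates), the gene body runs from there
to the annotated 3' end, and the post-PAS window covers the 5 kb downstream
of the 3' end. All windows follow the direction of transcription, so on the
minus strand the TSS is the gene's end coordinate and "downstream" runs
leftward. The pausing index is pause-window density over body density; the
retention index is body density over post-PAS density. Ratios with a zero
denominator are reported as missing (NaN), never as 0 or infinity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks import GenomicInterval, SignalTrack

__all__ = [
    "GeneWindows",
    "GeneSignalSummary",
    "gene_windows",
    "filter_eligible",
    "summarize_gene",
    "summarize_genes",
    "pausing_index_table",
    "scaled_metagene",
    "peak_centered_metaplot",
]

PAUSE_LEN = 250
POSTPAS_LEN = 5000
MIN_GENE_LEN = 500
MIN_NEIGHBOR_GAP = 5000


@dataclass(frozen=True)
class GeneWindows:
    pause: GenomicInterval
    body: GenomicInterval
    postpas: GenomicInterval | None
    clipped: bool


def gene_windows(
    gene: GenomicInterval,
    chrom_size: int,
    pause_len: int = PAUSE_LEN,
    postpas_len: int = POSTPAS_LEN,
) -> GeneWindows:
    """Strand-aware pause/body/post-PAS windows for one gene.

    Windows are clipped at chromosome ends (flagged); a post-PAS window
    clipped to nothing is returned as None. Genes no longer than the pause
    window have no body and raise ValueError (ineligible upstream).
    """
    if gene.strand not in ("+", "-"):
        raise ValueError(f"gene {gene.name or gene} needs a strand")
    if len(gene) <= pause_len:
        raise ValueError(
            f"gene {gene.name or gene} shorter than pause window ({pause_len} bp)"
        )
    c = gene.chrom
    if gene.strand == "+":
        pause = GenomicInterval(c, gene.start, gene.start + pause_len, "+")
        body = GenomicInterval(c, gene.start + pause_len, gene.end, "+")
        post_end = min(gene.end + postpas_len, chrom_size)
        clipped = post_end < gene.end + postpas_len
        post = (
            GenomicInterval(c, gene.end, post_end, "+") if post_end > gene.end else None
        )
    else:
        pause = GenomicInterval(c, gene.end - pause_len, gene.end, "-")
        body = GenomicInterval(c, gene.start, gene.end - pause_len, "-")
        post_start = max(gene.start - postpas_len, 0)
        clipped = post_start > gene.start - postpas_len
        post = (
            GenomicInterval(c, post_start, gene.start, "-")
            if post_start < gene.start
            else None
        )
    return GeneWindows(pause=pause, body=body, postpas=post, clipped=clipped)


def _tss(row) -> int:
    return int(row.start) if row.strand == "+" else int(row.end)


def _three_prime(row) -> int:
    return int(row.end) if row.strand == "+" else int(row.start)


def filter_eligible(
    genes: pd.DataFrame,
    min_length: int = MIN_GENE_LEN,
    min_neighbor_gap: int = MIN_NEIGHBOR_GAP,
) -> pd.DataFrame:
    """Genes longer than ``min_length`` whose 3' end is at least
    ``min_neighbor_gap`` bp from every other gene's TSS (same chromosome)."""
    if genes.empty:
        return genes.copy()
    keep = np.zeros(len(genes), dtype=bool)
    genes = genes.reset_index(drop=True)
    for chrom, grp in genes.groupby("chrom", sort=False):
        tss = np.array([_tss(r) for r in grp.itertuples()])
        order = np.argsort(tss)
        sorted_tss = tss[order]
        for local_i, row in enumerate(grp.itertuples()):
            if row.end - row.start <= min_length:
                continue
            end3 = _three_prime(row)
            # nearest TSS of any *other* gene on this chromosome
            pos = np.searchsorted(sorted_tss, end3)
            best = math.inf
            for j in (pos - 1, pos, pos + 1):
                if 0 <= j < len(sorted_tss):
                    orig = order[j]
                    if orig == local_i:
                        # the gene's own TSS: look one further out
                        for jj in (j - 1, j + 1):
                            if 0 <= jj < len(sorted_tss) and order[jj] != local_i:
                                best = min(best, abs(sorted_tss[jj] - end3))
                        continue
                    best = min(best, abs(sorted_tss[j] - end3))
            if best >= min_neighbor_gap:
                keep[row.Index] = True
    return genes[keep].copy()


@dataclass(frozen=True)
class GeneSignalSummary:
    """Window counts/densities and pausing/retention indices for one gene."""

    gene_id: str
    pause_count: float
    body_count: float
    postpas_count: float
    pause_density: float
    body_density: float
    postpas_density: float
    pausing_index: float  # NaN when body density is 0
    retention_index: float  # NaN when post-PAS density is 0
    eligible: bool = True
    clipped: bool = False


def _ratio(num_count: float, num_len: int, den_count: float, den_len: int) -> float:
    # density ratio expressed so a common track scale cancels exactly
    if den_count == 0 or den_len == 0 or num_len == 0:
        return float("nan")
    return (num_count * den_len) / (den_count * num_len)


def summarize_gene(
    tracks: Mapping[str, SignalTrack],
    gene: GenomicInterval,
    chrom_size: int,
    pause_len: int = PAUSE_LEN,
    postpas_len: int = POSTPAS_LEN,
    eligible: bool = True,
) -> GeneSignalSummary | None:
    """Windowed signal summary for one gene from its strand's track.

    Returns None for genes shorter than the pause window (no summary).
    Pausing and retention indices use raw (unscaled) window sums so that any
    global track rescaling cancels exactly.
    """
    try:
        wins = gene_windows(gene, chrom_size, pause_len, postpas_len)
    except ValueError:
        return None
    track = tracks[gene.strand]
    raw_pause = track._raw_count(wins.pause)
    raw_body = track._raw_count(wins.body)
    raw_post = track._raw_count(wins.postpas) if wins.postpas else 0.0
    post_len = len(wins.postpas) if wins.postpas else 0
    s = track.scale
    return GeneSignalSummary(
        gene_id=gene.name or f"{gene.chrom}:{gene.start}-{gene.end}",
        pause_count=raw_pause * s,
        body_count=raw_body * s,
        postpas_count=raw_post * s,
        pause_density=raw_pause * s / len(wins.pause),
        body_density=raw_body * s / len(wins.body),
        postpas_density=(raw_post * s / post_len) if post_len else float("nan"),
        pausing_index=_ratio(raw_pause, len(wins.pause), raw_body, len(wins.body)),
        retention_index=_ratio(raw_body, len(wins.body), raw_post, post_len),
        eligible=eligible,
        clipped=wins.clipped,
    )


def _gene_interval(row) -> GenomicInterval:
    return GenomicInterval(
        row.chrom, int(row.start), int(row.end), row.strand, str(row.name_)
    )


def _iter_gene_rows(genes: pd.DataFrame):
    df = genes.rename(columns={"name": "name_"})
    if "name_" not in df.columns:
        df = df.assign(name_=[f"gene{i}" for i in range(len(df))])
    return df.itertuples()


def summarize_genes(
    tracks: Mapping[str, SignalTrack],
    genes: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    pause_len: int = PAUSE_LEN,
    postpas_len: int = POSTPAS_LEN,
    eligible_only: bool = False,
) -> pd.DataFrame:
    """Summaries for all genes as a DataFrame (one row per summarizable gene)."""
    eligible_ids = set(
        filter_eligible(genes)["name"].astype(str)
        if "name" in genes.columns and not genes.empty
        else []
    )
    rows = []
    for row in _iter_gene_rows(genes):
        gene = _gene_interval(row)
        is_eligible = gene.name in eligible_ids
        if eligible_only and not is_eligible:
            continue
        summ = summarize_gene(
            tracks, gene, chrom_sizes[gene.chrom], pause_len, postpas_len,
            eligible=is_eligible,
        )
        if summ is not None:
            rows.append(summ.__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "pause_count", "body_count", "postpas_count",
            "pause_density", "body_density", "postpas_density",
            "pausing_index", "retention_index", "eligible", "clipped",
        ],
    )


def _chrom_class(chrom: str) -> str:
    base = chrom.removeprefix("chr")
    return {"X": "X", "Y": "Y"}.get(base, "autosome")


def pausing_index_table(
    stage_tracks: Mapping[str, Mapping[str, SignalTrack]],
    genes: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    eligible_only: bool = True,
    **window_kwargs,
) -> pd.DataFrame:
    """Long-format per-gene, per-stage summary table.

    Columns include the chromosome class (autosome/X/Y) so autosome-only
    comparisons and per-gene matched pairs across stages (the input to
    Wilcoxon matched-pairs tests) are a groupby away. Genes missing in one
    stage are excluded from pairing by the caller via pivot/dropna.
    """
    chrom_of = {}
    if "name" in genes.columns:
        chrom_of = dict(zip(genes["name"].astype(str), genes["chrom"]))
    frames = []
    for stage, tracks in stage_tracks.items():
        df = summarize_genes(
            tracks, genes, chrom_sizes, eligible_only=eligible_only, **window_kwargs
        )
        df.insert(1, "stage", stage)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["chrom_class"] = out["gene_id"].map(
        lambda g: _chrom_class(chrom_of.get(g, ""))
    )
    return out


def _gene_profile(
    tracks: Mapping[str, SignalTrack],
    row,
    body_bins: int,
    flank: int,
    flank_bins: int,
    chrom_size: int,
) -> np.ndarray | None:
    """Per-bin density: unscaled flanks around a body rescaled to body_bins."""
    gene = _gene_interval(row)
    track = tracks[gene.strand]
    if len(gene) < body_bins:
        return None
    if gene.strand == "+":
        up = (gene.start - flank, gene.start)
        down = (gene.end, gene.end + flank)
    else:
        up = (gene.end, gene.end + flank)
        down = (gene.start - flank, gene.start)
    for a, b in (up, down):
        if a < 0 or b > chrom_size:
            return None  # drop flank-clipped genes from the profile
    up_prof = track.binned(GenomicInterval(gene.chrom, *up), flank_bins)
    body_prof = track.binned(
        GenomicInterval(gene.chrom, gene.start, gene.end), body_bins
    )
    down_prof = track.binned(GenomicInterval(gene.chrom, *down), flank_bins)
    prof = np.concatenate([up_prof, body_prof, down_prof])
    if gene.strand == "-":
        prof = prof[::-1]
    return prof


def scaled_metagene(
    tracks: Mapping[str, SignalTrack],
    genes: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    n_sub: int = 1000,
    body_bins: int = 40,
    flank: int = 500,
    flank_bins: int = 10,
    subsample_frac: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Median metagene profile over random gene subsamples.

    Each gene body is rescaled to ``body_bins`` bins; ``flank`` bp on each
    side stay unscaled. For each of ``n_sub`` subsamples (drawn without
    replacement within each subsample), the per-bin mean density across the
    subsample's genes is computed; the profile is the per-bin median over
    subsamples, with a 5-95% envelope.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for row in _iter_gene_rows(genes.sort_values(list(genes.columns[:3]))):
        prof = _gene_profile(
            tracks, row, body_bins, flank, flank_bins, chrom_sizes[row.chrom]
        )
        if prof is not None:
            profiles.append(prof)
    if len(profiles) < 2:
        raise ValueError("need >= 2 usable genes for a metagene profile")
    mat = np.vstack(profiles)
    n_genes = len(mat)
    size = max(2, int(round(subsample_frac * n_genes)))
    if size > n_genes:
        warnings.warn(
            f"subsample size {size} > {n_genes} genes; reduced", stacklevel=2
        )
        size = n_genes
    sub_means = np.empty((n_sub, mat.shape[1]))
    for i in range(n_sub):
        idx = rng.choice(n_genes, size=size, replace=False)
        sub_means[i] = mat[idx].mean(axis=0)
    n_bins = mat.shape[1]
    labels = (
        ["upstream"] * flank_bins + ["body"] * body_bins + ["downstream"] * flank_bins
    )
    return pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "region": labels,
            "median": np.median(sub_means, axis=0),
            "lo": np.percentile(sub_means, 5, axis=0),
            "hi": np.percentile(sub_means, 95, axis=0),
        }
    )


def peak_centered_metaplot(
    track: SignalTrack,
    peaks: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    flank: int = 10_000,
    bins: int = 100,
    sort_by: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean signal profile around peak centers plus the per-peak bin matrix.

    ``sort_by`` (e.g. another stage's row sums) orders the matrix rows in
    decreasing order; peaks whose window would leave the chromosome are
    dropped (consistently with any provided ordering).
    """
    centers, keep_rows = [], []
    for i, row in enumerate(peaks.itertuples()):
        c = (int(row.start) + int(row.end)) // 2
        if c - flank >= 0 and c + flank <= chrom_sizes[row.chrom]:
            centers.append((row.chrom, c))
            keep_rows.append(i)
    if not centers:
        raise ValueError("no peaks with a full flank window")
    mat = np.vstack(
        [
            track.binned(GenomicInterval(chrom, c - flank, c + flank), bins)
            for chrom, c in centers
        ]
    )
    if sort_by is not None:
        order = np.argsort(-np.asarray(sort_by)[keep_rows], kind="stable")
        mat = mat[order]
    profile = pd.DataFrame(
        {
            "bin": np.arange(bins),
            "offset": np.linspace(-flank, flank, bins, endpoint=False) + flank / bins,
            "mean": mat.mean(axis=0),
        }
    )
    return profile, mat
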