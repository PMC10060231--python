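"""Synthetic genomes, nascent-signal tracks, peak sets, and run-on tables.

The generator emulates the shape of a stage-resolved nascent-transcription
study of meiotic prophase I: three stages (LZ, P, D) with planted
promoter-proximal pausing that relaxes across stages, a planted pachynema
(P) activity burst of 2.7x over LZ, accessible/TRE/DSB peak sets with a
planted degree of segregation between transcribed elements and DSB markers,
and run-on measurement tables calibrated by serial-dilution standards lying
on a planted line. Every planted parameter is recoverable by the downstream
modules, so the whole pipeline is testable without any external data.

Counts are independent Poisson draws per base deposited on the gene's strand
(nascent reads are represented as single-base polymerase positions); there
is no fragment-length, sequence, mappability, or GC model.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .tracks import SignalTrack, write_bed, write_bedgraph, write_chrom_sizes

__all__ = [
    "StageRates",
    "SimConfig",
    "generate_annotation",
    "simulate_stage_tracks",
    "simulate_runon_table",
    "simulate_peaks",
    "mixed_purity_matrix",
    "emit_all",
]

STAGES = ("LZ", "P", "D")


@dataclass(frozen=True)
class StageRates:
    """Planted Poisson rates (reads per base) for one stage's gene windows."""

    pause_rate: float
    body_rate: float
    postpas_rate: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


def _default_stage_params() -> dict[str, StageRates]:
    # Pausing index relaxes across prophase I (LZ 10 -> P 4 -> D 3) while
    # body transcription rises toward pachynema; retention indices ~4-5.
    return {
        "LZ": StageRates(pause_rate=0.20, body_rate=0.02, postpas_rate=0.004),
        "P": StageRates(pause_rate=0.20, body_rate=0.05, postpas_rate=0.012),
        "D": StageRates(pause_rate=0.12, body_rate=0.04, postpas_rate=0.010),
    }


def _default_activity() -> dict[str, float]:
    # Pachynema transcriptional burst: 2.7-fold over LZ; D back to baseline.
    return {"LZ": 1.0, "P": 2.7, "D": 1.0}


@dataclass(frozen=True)
class SimConfig:
    """All planted parameters for one synthetic dataset.

    A fixed seed makes every emitted artifact byte-identical across runs;
    independent sub-streams per operation keep the outputs of one operation
    stable when unrelated config fields change.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 400_000
    n_genes: int = 24
    gene_length_range: tuple[int, int] = (2_000, 6_000)
    intergenic_gap: int = 6_000
    frac_ineligible: float = 0.0
    ineligible_length: int = 400
    stage_params: Mapping[str, StageRates] = field(
        default_factory=_default_stage_params
    )
    activity: Mapping[str, float] = field(default_factory=_default_activity)
    background_rate: float = 0.0
    # run-on table
    purity_matrix: tuple[tuple[float, ...], ...] | None = None  # None -> identity
    sample_dna_ng: float = 500.0
    standard_dilutions: tuple[float, ...] = (500.0, 50.0, 5.0)
    n_standard_replicates: int = 2
    standard_slope: float = 20.0
    standard_intercept: float = 0.0
    standard_noise_sd: float = 0.0
    sample_noise_sd: float = 0.0
    # peak sets
    segregation: float = 0.9
    accessible_width: int = 400
    tre_width: int = 200
    dsb_width: int = 150
    n_distal_accessible: int = 12
    distal_tre_frac: float = 0.3
    n_dsb: int = 12

    def __post_init__(self) -> None:
        if self.purity_matrix is not None:
            for row in self.purity_matrix:
                if abs(sum(row) - 1.0) > 1e-9:
                    raise ValueError(f"purity row {row} does not sum to 1")
                if any(f < 0 for f in row):
                    raise ValueError(f"negative purity fraction in {row}")
        if not 0.0 <= self.segregation <= 1.0:
            raise ValueError("segregation must be in [0, 1]")
        if not 0.0 <= self.frac_ineligible <= 1.0:
            raise ValueError("frac_ineligible must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, reproducible sub-stream derived from the master seed."""
        key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


def _purity(cfg: SimConfig) -> np.ndarray:
    if cfg.purity_matrix is None:
        return np.eye(3)
    return np.asarray(cfg.purity_matrix, dtype=float)


def mixed_purity_matrix(
    n_samples: int, rng: np.random.Generator, concentration: float = 8.0
) -> np.ndarray:
    """Dirichlet stage compositions with a cycling dominant stage.

    Emulates sorted-but-impure cell fractions: each sample is enriched for
    one stage (Dirichlet alpha ``concentration`` on the dominant stage, 1
    elsewhere), cycling LZ, P, D so the composition matrix has full rank
    with near-certainty for n_samples >= 3.
    """
    alpha = np.ones((n_samples, 3))
    alpha[np.arange(n_samples), np.arange(n_samples) % 3] = concentration
    return np.vstack([rng.dirichlet(a) for a in alpha])


# ------------------------------------------------------------------ genomes

def generate_annotation(cfg: SimConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    """Non-overlapping gene annotation plus chromosome sizes.

    Genes are laid left to right with intergenic gaps of at least
    ``cfg.intergenic_gap`` (> 5 kb), so every full-length gene passes the
    downstream eligibility filters by construction; exactly
    ``ceil(frac_ineligible * n_genes)`` genes are emitted deliberately short
    (``ineligible_length`` bp <= 500) so they fail the length filter.
    """
    chrom_sizes = {
        f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)
    }
    if cfg.n_genes == 0:
        genes = pd.DataFrame(
            columns=["chrom", "start", "end", "name", "score", "strand"]
        )
        return genes, chrom_sizes
    rng = cfg.rng("annotation")
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    max_len = cfg.gene_length_range[1]
    needed = cfg.intergenic_gap + per_chrom * (max_len + cfg.intergenic_gap)
    if needed > cfg.chrom_length:
        raise ValueError(
            f"genome too small: {per_chrom} genes/chromosome need up to "
            f"{needed} bp but chromosomes are {cfg.chrom_length} bp"
        )
    n_bad = int(np.ceil(cfg.frac_ineligible * cfg.n_genes))
    bad_ids = set(range(cfg.n_genes - n_bad, cfg.n_genes))
    rows = []
    gid = 0
    for chrom in chrom_sizes:
        cursor = cfg.intergenic_gap
        for _ in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            if gid in bad_ids:
                length = cfg.ineligible_length
            else:
                length = int(rng.integers(*cfg.gene_length_range, endpoint=True))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                (chrom, cursor, cursor + length, f"gene{gid:04d}", 0, strand)
            )
            cursor += length + cfg.intergenic_gap
            gid += 1
    genes = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return genes, chrom_sizes


# ------------------------------------------------------------------- tracks

def simulate_stage_tracks(
    cfg: SimConfig,
    genes: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
) -> dict[str, dict[str, SignalTrack]]:
    """Per-stage, per-strand Poisson signal tracks.

    Per-base rate = window rate x stage activity on the gene's strand
    (pause window at the TSS-proximal 250 bp, body to the 3' end, post-PAS
    5 kb downstream), plus ``background_rate`` everywhere on both strands.
    """
    from .pausing import gene_windows  # local import avoids a cycle
    from .tracks import GenomicInterval

    out: dict[str, dict[str, SignalTrack]] = {}
    for stage in cfg.stage_params:
        rng = cfg.rng(f"tracks:{stage}")
        act = cfg.activity[stage]
        rates = cfg.stage_params[stage]
        dense = {
            strand: {c: np.full(n, float(cfg.background_rate)) for c, n in chrom_sizes.items()}
            for strand in ("+", "-")
        }
        for row in genes.itertuples():
            gene = GenomicInterval(
                row.chrom, int(row.start), int(row.end), row.strand, str(row.name)
            )
            try:
                wins = gene_windows(gene, chrom_sizes[gene.chrom])
            except ValueError:
                continue  # too short for a pause window: leave at background
            arr = dense[gene.strand][gene.chrom]
            arr[wins.pause.start : wins.pause.end] = rates.pause_rate
            arr[wins.body.start : wins.body.end] = rates.body_rate
            if wins.postpas is not None:
                arr[wins.postpas.start : wins.postpas.end] = rates.postpas_rate
        out[stage] = {}
        for strand in ("+", "-"):
            counts = {
                chrom: rng.poisson(rate_arr * act).astype(float)
                for chrom, rate_arr in dense[strand].items()
            }
            out[stage][strand] = SignalTrack.from_dense(
                counts, chrom_sizes, strand=strand
            )
    return out


# ------------------------------------------------------------- run-on table

def simulate_runon_table(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run-on sample table and serial-dilution standards table.

    Standards lie on the planted line ``cpm = m * dna_ng + b`` (optionally
    with Gaussian noise of sd ``standard_noise_sd``). Each sample's observed
    CPM is ``expected_cpm x (composition . activity) x (1 + eps)`` with
    ``eps ~ N(0, sample_noise_sd^2)``.
    """
    rng = cfg.rng("runon")
    m, b = cfg.standard_slope, cfg.standard_intercept
    std_rows = []
    for rep in range(cfg.n_standard_replicates):
        for x in cfg.standard_dilutions:
            y = m * x + b
            if cfg.standard_noise_sd > 0:
                y += rng.normal(0.0, cfg.standard_noise_sd)
            std_rows.append((f"std_r{rep + 1}_{x:g}ng", x, y))
    standards = pd.DataFrame(std_rows, columns=["sample", "dna_ng", "cpm"])

    purity = _purity(cfg)
    act = np.array([cfg.activity[s] for s in STAGES])
    rows = []
    for i, frac in enumerate(purity):
        expected = m * cfg.sample_dna_ng + b
        observed = expected * float(frac @ act)
        if cfg.sample_noise_sd > 0:
            observed *= 1.0 + rng.normal(0.0, cfg.sample_noise_sd)
        rows.append(
            (f"sample{i + 1:02d}", cfg.sample_dna_ng, observed, *frac)
        )
    samples = pd.DataFrame(
        rows, columns=["sample", "dna_ng", "cpm", "frac_LZ", "frac_P", "frac_D"]
    )
    return samples, standards


# -------------------------------------------------------------------- peaks

def simulate_peaks(
    cfg: SimConfig,
    genes: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Accessible peaks, transcribed-TRE peaks, and DSB-marker peaks.

    Accessible peaks sit at every gene TSS plus ``n_distal_accessible``
    distal sites. TREs mark all TSS peaks and a ``distal_tre_frac`` fraction
    of distal peaks. Each DSB peak is centered on an accessible peak: with
    probability ``segregation`` one drawn from the TRE-free peaks, otherwise
    from all accessible peaks — segregation=1 plants perfect exclusion,
    segregation=0 plants independence.
    """
    rng = cfg.rng("peaks")
    half_a = cfg.accessible_width // 2
    centers: list[tuple[str, int, bool]] = []  # (chrom, center, is_tre)
    for row in genes.itertuples():
        tss = int(row.start) if row.strand == "+" else int(row.end)
        tss = int(np.clip(tss, half_a, chrom_sizes[row.chrom] - half_a))
        centers.append((row.chrom, tss, True))
    chroms = list(chrom_sizes)
    placed = 0
    attempts = 0
    while placed < cfg.n_distal_accessible and attempts < 10_000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(half_a, chrom_sizes[chrom] - half_a))
        if all(
            c != chrom or abs(pos - p) >= cfg.accessible_width * 2
            for c, p, _ in centers
        ):
            centers.append((chrom, pos, rng.random() < cfg.distal_tre_frac))
            placed += 1
    centers.sort(key=lambda t: (t[0], t[1]))

    accessible = pd.DataFrame(
        [
            (c, p - half_a, p + half_a, f"acc{i:04d}")
            for i, (c, p, _) in enumerate(centers)
        ],
        columns=["chrom", "start", "end", "name"],
    )
    half_t = cfg.tre_width // 2
    tres = pd.DataFrame(
        [
            (c, p - half_t, p + half_t, f"tre{i:04d}")
            for i, (c, p, is_tre) in enumerate(centers)
            if is_tre
        ],
        columns=["chrom", "start", "end", "name"],
    )
    tre_free = [i for i, (_, _, is_tre) in enumerate(centers) if not is_tre]
    all_idx = list(range(len(centers)))
    half_d = cfg.dsb_width // 2
    dsb_rows = []
    for j in range(cfg.n_dsb):
        pool = tre_free if (tre_free and rng.random() < cfg.segregation) else all_idx
        c, p, _ = centers[pool[int(rng.integers(len(pool)))]]
        dsb_rows.append((c, p - half_d, p + half_d, f"dsb{j:04d}"))
    dsbs = pd.DataFrame(dsb_rows, columns=["chrom", "start", "end", "name"])
    for df in (accessible, tres, dsbs):
        df.sort_values(["chrom", "start"], inplace=True, ignore_index=True)
    return accessible, tres, dsbs


# ----------------------------------------------------------------- emission

def emit_all(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write every synthetic artifact to ``out_dir`` and return the paths.

    Formats: genes BED6, peaks BED (3+name), per-stage per-strand 4-column
    bedGraph (minus strand non-negative in ``*.minus.bedGraph``), chrom sizes
    as two-column TSV, run-on tables as CSV with header.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes, chrom_sizes = generate_annotation(cfg)
    tracks = simulate_stage_tracks(cfg, genes, chrom_sizes)
    samples, standards = simulate_runon_table(cfg)
    accessible, tres, dsbs = simulate_peaks(cfg, genes, chrom_sizes)

    paths: dict[str, Path] = {}

    def _save(key: str, name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        paths[key] = path

    _save("chrom_sizes", "genome.chrom.sizes",
          lambda p: write_chrom_sizes(chrom_sizes, p))
    _save("genes", "genes.bed", lambda p: write_bed(genes, p))
    for stage, by_strand in tracks.items():
        _save(f"track_{stage}_plus", f"{stage}.plus.bedGraph",
              lambda p, t=by_strand["+"]: write_bedgraph(t, p))
        _save(f"track_{stage}_minus", f"{stage}.minus.bedGraph",
              lambda p, t=by_strand["-"]: write_bedgraph(t, p))
    _save("runon_samples", "runon_samples.csv",
          lambda p: samples.to_csv(p, index=False))
    _save("runon_standards", "runon_standards.csv",
          lambda p: standards.to_csv(p, index=False))
    _save("peaks_accessible", "peaks_accessible.bed",
          lambda p: write_bed(accessible, p))
    _save("peaks_tre", "peaks_tre.bed", lambda p: write_bed(tres, p))
    _save("peaks_dsb", "peaks_dsb.bed", lambda p: write_bed(dsbs, p))
    return paths
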