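"""Genomic signal tracks and interval formats.

Nascent-transcription coverage is represented as run-length encoded,
strand-specific single-base signal (bedGraph semantics): sorted,
non-overlapping ``[start, end)`` intervals carrying a non-negative value per
base. All coordinates are 0-based, half-open. Minus-strand signal is stored
non-negative in its own track; rendering it below the axis is a display
convention, not a data property.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "SignalTrack",
    "TrackFormatError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "rpkm",
    "rpm",
    "frip",
    "merge_intervals",
]


class TrackFormatError(ValueError):
    """Malformed on-disk track/interval data (reports the offending line)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded and named."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand is not None and self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class SignalTrack:
    """Run-length encoded single-base signal over one genome.

    Parameters
    ----------
    chrom_sizes :
        Mapping of chromosome name to length in bp.
    strand :
        Label for the strand this track covers ("+", "-", or "." for
        unstranded signal such as accessibility).

    Notes
    -----
    Rescaling (normalization) is carried as a lazy scalar ``scale`` applied on
    read-out, so stored per-interval values are never mutated. Ratios formed
    within one track (pausing/retention indices) therefore cancel the scale
    algebraically and are bit-for-bit invariant under rescaling.
    """

    def __init__(self, chrom_sizes: Mapping[str, int], strand: str = ".") -> None:
        self.chrom_sizes = dict(chrom_sizes)
        self.strand = strand
        self.scale = 1.0
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------------ build
    def set_intervals(
        self,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
        values: np.ndarray,
    ) -> None:
        """Install the interval runs for one chromosome (replacing any)."""
        if chrom not in self.chrom_sizes:
            raise TrackFormatError(f"unknown chromosome {chrom!r}")
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if not (len(starts) == len(ends) == len(values)):
            raise ValueError("starts/ends/values length mismatch")
        if len(starts):
            if np.any(values < 0):
                raise TrackFormatError(f"negative signal value on {chrom}")
            if starts[0] < 0 or ends[-1] > self.chrom_sizes[chrom]:
                raise TrackFormatError(f"interval outside {chrom} bounds")
            if np.any(ends <= starts):
                raise TrackFormatError(f"empty or inverted interval on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise TrackFormatError(f"unsorted or overlapping intervals on {chrom}")
        self._starts[chrom] = starts
        self._ends[chrom] = ends
        self._values[chrom] = values

    @classmethod
    def from_dense(
        cls,
        dense: Mapping[str, np.ndarray],
        chrom_sizes: Mapping[str, int],
        strand: str = ".",
    ) -> "SignalTrack":
        """Build a track from per-base arrays, run-length encoding nonzero runs."""
        track = cls(chrom_sizes, strand=strand)
        for chrom, arr in dense.items():
            arr = np.asarray(arr)
            if len(arr) != chrom_sizes[chrom]:
                raise ValueError(f"dense array length != size of {chrom}")
            if len(arr) == 0:
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            values = arr[starts].astype(float)
            keep = values != 0
            track.set_intervals(chrom, starts[keep], ends[keep], values[keep])
        return track

    # ---------------------------------------------------------------- queries
    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, values) for one chromosome, values with scale applied."""
        s = self._starts.get(chrom, np.empty(0, dtype=np.int64))
        e = self._ends.get(chrom, np.empty(0, dtype=np.int64))
        v = self._values.get(chrom, np.empty(0))
        return s, e, v * self.scale

    def chroms(self) -> list[str]:
        return [c for c in self.chrom_sizes if c in self._starts]

    @property
    def library_size(self) -> float:
        """Total signal: sum over intervals of value x length."""
        return self._raw_library_size() * self.scale

    def _raw_library_size(self) -> float:
        total = 0.0
        for chrom in self._starts:
            total += float(
                np.dot(self._values[chrom], self._ends[chrom] - self._starts[chrom])
            )
        return total

    def _raw_count(self, iv: GenomicInterval) -> float:
        """Unscaled sum of value x overlap length within ``iv``."""
        if iv.chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.chrom_sizes[iv.chrom]:
            raise ValueError(f"window {iv} exceeds chromosome bounds")
        s = self._starts.get(iv.chrom)
        if s is None or len(s) == 0:
            return 0.0
        e = self._ends[iv.chrom]
        v = self._values[iv.chrom]
        lo = int(np.searchsorted(e, iv.start, side="right"))
        hi = int(np.searchsorted(s, iv.end, side="left"))
        if hi <= lo:
            return 0.0
        overlap = np.minimum(e[lo:hi], iv.end) - np.maximum(s[lo:hi], iv.start)
        return float(np.dot(v[lo:hi], overlap))

    def count(self, iv: GenomicInterval) -> float:
        """Signal within ``iv`` (scale applied)."""
        return self._raw_count(iv) * self.scale

    def density(self, iv: GenomicInterval) -> float:
        """Signal per bp within ``iv``. Zero-length windows are an error."""
        if len(iv) == 0:
            raise ValueError("zero-length window")
        return self.count(iv) / len(iv)

    def binned(self, iv: GenomicInterval, n_bins: int) -> np.ndarray:
        """Per-bin mean density across ``iv`` split into ``n_bins`` equal parts."""
        edges = np.linspace(iv.start, iv.end, n_bins + 1).round().astype(int)
        out = np.empty(n_bins)
        for i in range(n_bins):
            a, b = int(edges[i]), int(edges[i + 1])
            if b <= a:  # degenerate bin when window shorter than n_bins
                b = min(a + 1, iv.end)
                a = b - 1
            out[i] = self.density(GenomicInterval(iv.chrom, a, b))
        return out

    # ------------------------------------------------------------- operations
    def rescaled(self, factor: float) -> "SignalTrack":
        """Return a view-like copy with all values multiplied by ``factor``."""
        if not factor > 0:
            raise ValueError(f"scale factor must be positive, got {factor}")
        out = SignalTrack(self.chrom_sizes, strand=self.strand)
        out._starts = self._starts
        out._ends = self._ends
        out._values = self._values
        out.scale = self.scale * factor
        return out

    def __add__(self, other: "SignalTrack") -> "SignalTrack":
        """Base-wise sum of two tracks on the same genome (strands combined)."""
        if self.chrom_sizes != other.chrom_sizes:
            raise ValueError("tracks are on different genomes")
        dense = {}
        for chrom, size in self.chrom_sizes.items():
            arr = np.zeros(size)
            for tr in (self, other):
                s, e, v = tr.intervals(chrom)
                for a, b, val in zip(s, e, v):
                    arr[a:b] += val
            dense[chrom] = arr
        return SignalTrack.from_dense(dense, self.chrom_sizes, strand=".")


# ------------------------------------------------------------------- file IO

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise TrackFormatError(f"{path}:{lineno}: expected 'chrom\\tsize'")
        sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{n}\n" for c, n in sizes.items()))


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3/BED6 file into a DataFrame (columns named, 0-based)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_BED_COLS[:3])
    ncol = min(df.shape[1], 6)
    df = df.iloc[:, :ncol]
    df.columns = _BED_COLS[:ncol]
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise TrackFormatError(f"{path}:{bad[0] + 1}: end <= start")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(
    path: str | Path, chrom_sizes: Mapping[str, int], strand: str = "."
) -> SignalTrack:
    """Read a 4-column bedGraph; intervals must be sorted and non-overlapping."""
    track = SignalTrack(chrom_sizes, strand=strand)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"], dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return track
    if df.empty:
        return track
    for chrom, grp in df.groupby("chrom", sort=False):
        if chrom not in chrom_sizes:
            raise TrackFormatError(
                f"{path}:{grp.index[0] + 1}: unknown chromosome {chrom!r}"
            )
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        bad = np.flatnonzero(starts[1:] < ends[:-1])
        if len(bad):
            raise TrackFormatError(
                f"{path}:{grp.index[bad[0] + 1] + 1}: unsorted or overlapping intervals"
            )
        try:
            track.set_intervals(chrom, starts, ends, grp["value"].to_numpy(float))
        except TrackFormatError as err:
            raise TrackFormatError(f"{path}:{grp.index[0] + 1}: {err}") from err
    return track


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            s, e, v = track.intervals(chrom)
            for a, b, val in zip(s, e, v):
                fh.write(f"{chrom}\t{a}\t{b}\t{val:.10g}\n")


# ------------------------------------------------------------- normalization

def rpkm(counts, lengths_bp, library_size: float):
    """Reads per kilobase per million mapped reads."""
    counts = np.asarray(counts, dtype=float)
    lengths_kb = np.asarray(lengths_bp, dtype=float) / 1e3
    return counts / lengths_kb / (library_size / 1e6)


def rpm(counts, library_size: float):
    """Reads per million mapped reads (no length term)."""
    return np.asarray(counts, dtype=float) / (library_size / 1e6)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping intervals, per chromosome."""
    out = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def frip(track: SignalTrack, peaks: pd.DataFrame) -> float:
    """Fraction of signal inside the union of ``peaks`` (FRiP), in [0, 1]."""
    total = track.library_size
    if total == 0:
        raise ValueError("empty track: FRiP undefined")
    if peaks.empty:
        return 0.0
    merged = merge_intervals(peaks)
    inside = sum(
        track.count(GenomicInterval(row.chrom, int(row.start), int(row.end)))
        for row in merged.itertuples()
        if row.chrom in track.chrom_sizes
    )
    return inside / total
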