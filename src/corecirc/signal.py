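"""Normalized read densities and summit-centered binned signal matrices.

Density is reported in rpm/bp: reads per million mapped reads per base
pair. Reads are extended 3'-ward from their 5' end to at least the given
extension length (200 bp by default, the conventional ChIP fragment size),
coverage is accumulated as exact integer per-base counts, and the count is
normalized by region length and library size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak


class FragmentTrack:
    """Aligned fragments of one library plus its total mapped read count.

    Fragments shorter than the extension are extended 3'-ward from their 5'
    end on their recorded strand; unstranded fragments extend rightward.
    Fragments are held as per-chromosome coordinate arrays; extended
    cumulative coverage is cached per (chromosome, extension), so repeated
    density queries against the same track are cheap.
    """

    def __init__(
        self,
        fragments: list[GenomicInterval] | None,
        total_mapped: int,
        label: str = "",
        _by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    ):
        if _by_chrom is not None:
            self._by_chrom = _by_chrom
        else:
            grouped: dict[str, list[tuple[int, int, bool]]] = {}
            for f in fragments or []:
                grouped.setdefault(f.chrom, []).append(
                    (f.start, f.end, f.strand == "-")
                )
            self._by_chrom = {
                c: (
                    np.array([t[0] for t in rows], dtype=np.int64),
                    np.array([t[1] for t in rows], dtype=np.int64),
                    np.array([t[2] for t in rows], dtype=bool),
                )
                for c, rows in grouped.items()
            }
        self.n_fragments = sum(len(v[0]) for v in self._by_chrom.values())
        if total_mapped < self.n_fragments:
            raise ValueError(
                f"total_mapped ({total_mapped}) < number of fragments "
                f"({self.n_fragments}) for track {label!r}"
            )
        self.total_mapped = int(total_mapped)
        self.label = label
        self._cum_cache: dict[tuple[str, int], np.ndarray] = {}

    @classmethod
    def from_bed(
        cls, path: str | Path, total_mapped: int, label: str = ""
    ) -> "FragmentTrack":
        """Load a BED of fragments (cols: chrom, start, end[, name, score, strand])."""
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                usecols=[0, 1, 2, 5],
                names=["chrom", "start", "end", "strand"],
                dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
            )
        except ValueError:  # strandless 3-column BED
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                usecols=[0, 1, 2],
                names=["chrom", "start", "end"],
                dtype={"chrom": str, "start": np.int64, "end": np.int64},
            )
            df["strand"] = "."
        by_chrom = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            by_chrom[str(chrom)] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                (sub["strand"] == "-").to_numpy(),
            )
        return cls(None, total_mapped, label or Path(path).stem, _by_chrom=by_chrom)

    def _cumulative_coverage(self, chrom: str, extension: int) -> np.ndarray:
        """cum[i] = total extended-read coverage of bases [0, i)."""
        key = (chrom, extension)
        if key not in self._cum_cache:
            if chrom not in self._by_chrom:
                cum = np.zeros(1, dtype=np.int64)
            else:
                starts, ends, minus = self._by_chrom[chrom]
                lengths = np.maximum(ends - starts, extension)
                ext_s = np.where(minus, ends - lengths, starts)
                ext_e = np.where(minus, ends, starts + lengths)
                ext_s = np.maximum(ext_s, 0)
                n = int(ext_e.max())
                diff = np.zeros(n + 1, dtype=np.int64)
                np.add.at(diff, ext_s, 1)
                np.add.at(diff, ext_e, -1)
                coverage = np.cumsum(diff)  # per-base counts for bases [0, n]
                cum = np.concatenate([[0], np.cumsum(coverage)])
            self._cum_cache[key] = cum
        return self._cum_cache[key]

    def coverage_sum(self, region: GenomicInterval, extension: int = 200) -> int:
        """Exact integer sum of extended-read coverage over the region."""
        cum = self._cumulative_coverage(region.chrom, extension)
        top = len(cum) - 1
        a = min(max(region.start, 0), top)
        b = min(max(region.end, 0), top)
        return int(cum[b] - cum[a])


def pool_tracks(tracks: list[FragmentTrack], label: str = "pooled") -> FragmentTrack:
    """Concatenate fragment sets; total_mapped is the sum of the libraries."""
    by_chrom: dict[str, list] = {}
    for t in tracks:
        for chrom, (s, e, m) in t._by_chrom.items():
            by_chrom.setdefault(chrom, []).append((s, e, m))
    merged = {
        c: (
            np.concatenate([x[0] for x in parts]),
            np.concatenate([x[1] for x in parts]),
            np.concatenate([x[2] for x in parts]),
        )
        for c, parts in by_chrom.items()
    }
    return FragmentTrack(
        None,
        sum(t.total_mapped for t in tracks),
        label,
        _by_chrom=merged,
    )


def region_density(
    track: FragmentTrack, region: GenomicInterval, extension: int = 200
) -> float:
    """rpm/bp density of a region: coverage / length / (total_mapped / 1e6)."""
    if track.total_mapped == 0:
        raise ValueError(f"track {track.label!r} has zero total mapped reads")
    if extension < 0:
        raise ValueError("extension must be non-negative")
    cov = track.coverage_sum(region, extension)
    return cov / len(region) / (track.total_mapped / 1e6)


@dataclass
class SignalMatrix:
    """Rows of peak identifiers x columns of binned rpm/bp densities."""

    row_ids: list[str]
    bin_width: int
    window: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.window % self.bin_width != 0:
            raise ValueError("window must be divisible by bin_width")
        ncols = self.window // self.bin_width
        if self.values.shape != (len(self.row_ids), ncols):
            raise ValueError(
                f"matrix shape {self.values.shape} != ({len(self.row_ids)}, {ncols})"
            )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.row_ids)
        df.columns = [f"bin_{j + 1}" for j in range(df.shape[1])]
        df.index.name = "peak_id"
        df.to_csv(path, sep="\t", float_format="%.6g")


def summit_matrix(
    peaks: list[Peak],
    track: FragmentTrack,
    window: int = 10_000,
    bin_width: int = 10,
    extension: int = 200,
) -> SignalMatrix:
    """Binned rpm/bp densities in a window centered on each peak summit.

    Row i, column j holds the density of
    ``[summit - window/2 + j*bin_width, summit - window/2 + (j+1)*bin_width)``.
    Bins running off a chromosome end are zero-filled.
    """
    if window % bin_width != 0:
        raise ValueError("window must be divisible by bin_width")
    if track.total_mapped == 0:
        raise ValueError(f"track {track.label!r} has zero total mapped reads")
    ncols = window // bin_width
    half = window // 2
    norm = bin_width * (track.total_mapped / 1e6)
    values = np.zeros((len(peaks), ncols), dtype=float)
    for i, p in enumerate(peaks):
        cum = track._cumulative_coverage(p.interval.chrom, extension)
        top = len(cum) - 1
        edges = p.summit - half + np.arange(ncols + 1, dtype=np.int64) * bin_width
        clipped = np.clip(edges, 0, top)
        sums = cum[clipped[1:]] - cum[clipped[:-1]]
        values[i] = sums / norm
    return SignalMatrix(
        row_ids=[p.name for p in peaks], bin_width=bin_width, window=window, values=values
    )
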