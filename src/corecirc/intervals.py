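"""Genomic coordinate primitives and interval algebra.

All coordinates are 0-based half-open (BED convention). Conversion to and
from 1-based formats happens only at parse/serialize boundaries. Strand is
carried on intervals but ignored by the interval algebra here; only motif
scanning is strand-aware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class ValidationError(ValueError):
    """A genomic record violates a coordinate or field invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open span ``[start, end)`` on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start : int
        0-based inclusive start, ``>= 0``.
    end : int
        0-based exclusive end, ``> start``.
    strand : str
        One of ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval has empty chromosome name")
        if self.start < 0:
            raise ValidationError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValidationError(f"end <= start in {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff ``other`` lies entirely within this span."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance(self, other: "GenomicInterval") -> float:
        """Gap in bases between closest ends; 0 if overlapping; inf across chromosomes."""
        if self.chrom != other.chrom:
            return math.inf
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus a summit position and a signal score."""

    interval: GenomicInterval
    summit: int
    signal: float
    name: str = "."
    source: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside {self.interval} (peak {self.name})"
            )
        if self.signal < 0:
            raise ValidationError(f"negative signal for peak {self.name}")


@dataclass(frozen=True)
class TSSRecord:
    """One transcript's transcription start site.

    A gene may contribute several records (one per transcript isoform);
    gene-level rules take "any TSS". ``is_tf`` flags genes with a matrix in
    the motif database.
    """

    gene_id: str
    gene_symbol: str
    tss: GenomicInterval
    is_tf: bool = False

    def __post_init__(self) -> None:
        if len(self.tss) != 1:
            raise ValidationError(f"TSS of {self.gene_id} is not a length-1 interval")

    @property
    def position(self) -> int:
        return self.tss.start


def merge_intervals(
    intervals: list[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is at most ``gap`` bases.

    Intervals may be unsorted and span several chromosomes. Two intervals
    with ``next.start - prev.end <= gap`` merge; with ``gap = 0`` this also
    merges half-open adjacency (``end == next.start``, zero intervening
    bases). Returns sorted intervals with pairwise gaps ``> gap``; strand is
    dropped (merged spans are unstranded).
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    if not intervals:
        return []
    merged: list[GenomicInterval] = []
    cur = None
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if cur is not None and iv.chrom == cur.chrom and iv.start - cur.end <= gap:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
        else:
            if cur is not None:
                merged.append(cur)
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    merged.append(cur)
    return merged


def nearest_distance(
    query: GenomicInterval, targets: list[GenomicInterval]
) -> tuple[float, int | None]:
    """Distance from ``query`` to the nearest target interval.

    Returns ``(distance, index)``: 0 if overlapping, else bases between the
    closest ends, ``(inf, None)`` if no target shares the chromosome. Ties
    broken by smaller target start, then input order.
    """
    best: float = math.inf
    best_idx: int | None = None
    best_start: int | None = None
    for i, t in enumerate(targets):
        d = query.distance(t)
        if d < best or (d == best and best_start is not None and t.start < best_start):
            best, best_idx, best_start = d, i, t.start
    if best_idx is None or math.isinf(best):
        return math.inf, None
    return best, best_idx
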