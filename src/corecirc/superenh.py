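"""ROSE-style super-enhancer identification and enhancer-gene assignment.

H3K27ac peaks pooled across cell lines are stitched into enhancer regions
(peaks within 1638 bp merge), excluding peaks lying entirely within
2500 bp of a transcription start site. Regions are ranked by total
stitched signal (rpm/bp density x length) and the rank-vs-signal curve,
scaled to the unit square, is cut where its discrete slope first exceeds 1
(the ROSE tangent rule); regions above the cutoff are super-enhancers.
Super-enhancers are assigned to genes whose TSS overlaps them, lies within
a proximal window, or is the single closest TSS. Nucleosome-free regions
are merged ATAC peaks fully contained in a super-enhancer of an active
gene; they are the substrate for motif scanning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .intervals import GenomicInterval, Peak, TSSRecord, merge_intervals, nearest_distance
from .signal import FragmentTrack, region_density

STITCH_DISTANCE = 1638
TSS_EXCLUSION = 2500
ACTIVE_GENE_WINDOW = 1000
PROXIMAL_WINDOW = 50_000


@dataclass(frozen=True)
class StitchedRegion:
    interval: GenomicInterval
    constituents: tuple[GenomicInterval, ...]
    density_signal: float = 0.0  # rpm/bp, control-subtracted and floored at 0
    total_signal: float = 0.0  # density x length, the ranking score
    rank: int = 0
    is_super: bool = False
    name: str = ""


@dataclass(frozen=True)
class GeneAssignment:
    se_id: str
    gene_id: str
    relation: str  # overlapping | proximal | closest
    distance: float


@dataclass(frozen=True)
class NucleosomeFreeRegion:
    interval: GenomicInterval
    se_id: str


def active_genes(
    tss: list[TSSRecord],
    h3k27ac_peaksets: dict[str, list[Peak]],
    window: int = ACTIVE_GENE_WINDOW,
) -> set[str]:
    """Genes with a TSS within ``window`` bp of an H3K27ac peak in any line.

    Any transcript TSS of the gene qualifying in any single cell line is
    sufficient. Returns gene_ids.
    """
    peaks_by_chrom: dict[str, list[GenomicInterval]] = {}
    for peaks in h3k27ac_peaksets.values():
        for p in peaks:
            peaks_by_chrom.setdefault(p.interval.chrom, []).append(p.interval)
    active: set[str] = set()
    for rec in tss:
        if rec.gene_id in active:
            continue
        targets = peaks_by_chrom.get(rec.tss.chrom, [])
        d, _ = nearest_distance(rec.tss, targets)
        if d <= window:
            active.add(rec.gene_id)
    return active


def stitch_enhancers(
    h3k27ac_peaksets: dict[str, list[Peak]],
    tss: list[TSSRecord],
    stitch: int = STITCH_DISTANCE,
    tss_exclusion: int = TSS_EXCLUSION,
) -> list[StitchedRegion]:
    """Pool peaks across lines, drop promoter-proximal peaks, stitch the rest.

    A peak is removed when its interval lies entirely within the zone
    ``[tss - tss_exclusion, tss + tss_exclusion + 1)`` of any TSS (whole-peak
    containment; partially overlapping peaks are kept intact). Survivors are
    merged with gap = ``stitch``.
    """
    zones_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rec in tss:
        zones_by_chrom.setdefault(rec.tss.chrom, []).append(
            (max(rec.position - tss_exclusion, 0), rec.position + tss_exclusion + 1)
        )
    for zones in zones_by_chrom.values():
        zones.sort()

    def excluded(iv: GenomicInterval) -> bool:
        for zs, ze in zones_by_chrom.get(iv.chrom, []):
            if zs <= iv.start and iv.end <= ze:
                return True
        return False

    survivors = [
        p.interval
        for peaks in h3k27ac_peaksets.values()
        for p in peaks
        if not excluded(p.interval)
    ]
    merged = merge_intervals(survivors, gap=stitch)
    regions = []
    for i, iv in enumerate(merged):
        members = tuple(s for s in survivors if iv.contains(s))
        regions.append(
            StitchedRegion(interval=iv, constituents=members, name=f"stitched_{i + 1}")
        )
    return regions


def score_and_rank(
    regions: list[StitchedRegion],
    track: FragmentTrack,
    control: FragmentTrack | None = None,
    extension: int = 200,
    score_mode: str = "total",
) -> list[StitchedRegion]:
    """Attach rpm/bp density (optionally control-subtracted) and rank.

    The ranking score is density x region length (total stitched signal;
    ``score_mode='mean'`` ranks by density alone). Rank 1 is the largest
    score; ties break by longer region, then coordinate order.
    """
    if not regions:
        raise ValueError("no regions to score")
    if score_mode not in ("total", "mean"):
        raise ValueError(f"unknown score_mode {score_mode!r}")
    scored = []
    for r in regions:
        d = region_density(track, r.interval, extension)
        if control is not None:
            d -= region_density(control, r.interval, extension)
        d = max(d, 0.0)
        total = d * len(r.interval) if score_mode == "total" else d
        scored.append(replace(r, density_signal=d, total_signal=total))
    order = sorted(
        range(len(scored)),
        key=lambda i: (
            -scored[i].total_signal,
            -len(scored[i].interval),
            scored[i].interval.chrom,
            scored[i].interval.start,
        ),
    )
    ranked = [None] * len(scored)
    for rank, i in enumerate(order, start=1):
        ranked[rank - 1] = replace(scored[i], rank=rank)
    return ranked


def super_cutoff(ranked: list[StitchedRegion]) -> tuple[float, list[StitchedRegion]]:
    """Flag super-enhancers by the scaled tangent-slope-1 elbow rule.

    Signals are sorted ascending; rank position and signal are each scaled
    to [0, 1]. The cutoff is the signal at the left endpoint of the first
    consecutive-point segment whose slope exceeds 1; every region with
    signal >= cutoff is flagged. With all signals equal (degenerate curve)
    no region is flagged and a warning is issued.
    """
    if len(ranked) < 2:
        raise ValueError("need at least 2 regions for a cutoff")
    sig = sorted(r.total_signal for r in ranked)
    smin, smax = sig[0], sig[-1]
    if smax == smin:
        warnings.warn("all region signals equal; no super-enhancers called")
        return float("inf"), [replace(r, is_super=False) for r in ranked]
    n = len(sig)
    cutoff = float("inf")
    for i in range(n - 1):
        dy = (sig[i + 1] - sig[i]) / (smax - smin)
        dx = 1.0 / (n - 1)
        if dy / dx > 1.0:
            cutoff = sig[i]
            break
    flagged = [replace(r, is_super=r.total_signal >= cutoff) for r in ranked]
    return cutoff, flagged


def assign_to_genes(
    superenhancers: list[StitchedRegion],
    tss: list[TSSRecord],
    proximal_window: int = PROXIMAL_WINDOW,
) -> list[GeneAssignment]:
    """Assign each SE to overlapping, proximal (<= window) and closest genes.

    Duplicate gene hits collapse to the strongest relation
    (overlapping > proximal > closest). Gene-to-SE distance is the minimum
    over the gene's transcript TSSs.
    """
    strength = {"overlapping": 0, "proximal": 1, "closest": 2}
    out: list[GeneAssignment] = []
    for se in superenhancers:
        per_gene: dict[str, tuple[float, str]] = {}
        for rec in tss:
            d = se.interval.distance(rec.tss)
            if d == float("inf"):
                continue
            prev = per_gene.get(rec.gene_id)
            if prev is None or d < prev[0]:
                per_gene[rec.gene_id] = (d, rec.gene_symbol)
        if not per_gene:
            continue
        assignments: dict[str, GeneAssignment] = {}
        closest_gene = min(per_gene, key=lambda g: (per_gene[g][0], g))
        for gene_id, (d, _) in per_gene.items():
            if d == 0:
                rel = "overlapping"
            elif d <= proximal_window:
                rel = "proximal"
            elif gene_id == closest_gene:
                rel = "closest"
            else:
                continue
            cur = assignments.get(gene_id)
            if cur is None or strength[rel] < strength[cur.relation]:
                assignments[gene_id] = GeneAssignment(se.name, gene_id, rel, d)
        out.extend(assignments[g] for g in sorted(assignments))
    return out


def nucleosome_free_regions(
    atac_peaksets: dict[str, list[Peak]],
    superenhancers: list[StitchedRegion],
    active_gene_ids: set[str],
    assignments: list[GeneAssignment],
) -> list[NucleosomeFreeRegion]:
    """Merged ATAC peaks fully contained in an SE assigned to an active gene.

    ATAC peaks from all lines are pooled and merged (gap 0); a merged open
    region is kept iff it is contained (not merely overlapping) in a
    super-enhancer that is assigned to at least one active gene.
    """
    merged = merge_intervals(
        [p.interval for peaks in atac_peaksets.values() for p in peaks], gap=0
    )
    active_ses = {
        a.se_id for a in assignments if a.gene_id in active_gene_ids
    }
    ses = [se for se in superenhancers if se.name in active_ses]
    out = []
    for iv in merged:
        for se in ses:
            if se.interval.contains(iv):
                out.append(NucleosomeFreeRegion(iv, se.name))
                break
    return out
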