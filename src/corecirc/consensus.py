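"""Cross-cell-line consensus peaks and chromatin-state clustering.

A consensus peak is a binding site supported by overlapping peaks in at
least ``min_support`` of the supplied cell lines (3 of 4 in the reference
setting), represented by the union span of its members and centered on the
summit of the strongest member peak. Summit-centered multi-mark signal
matrices over consensus peaks are clustered hierarchically (Euclidean
distance, Ward-D2 linkage) into k chromatin states; with the three marks
H3K27ac / H3K4me1 / H3K4me3 and k = 3 these separate enhancer-like,
promoter-like and low-signal sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .intervals import GenomicInterval, Peak
from .signal import FragmentTrack, SignalMatrix, summit_matrix

CLUSTERING_MARKS = ("H3K27ac", "H3K4me1", "H3K4me3")


@dataclass(frozen=True)
class ConsensusPeak:
    """A merged cross-line binding site."""

    interval: GenomicInterval
    summit: int
    support: int
    members: tuple[Peak, ...]
    name: str = ""


@dataclass(frozen=True)
class StateAssignment:
    peak_id: str
    cluster_label: int
    mark_means: dict[str, float]


def consensus_peaks(
    peaksets: dict[str, list[Peak]], min_support: int = 3
) -> list[ConsensusPeak]:
    """Group overlapping peaks across cell lines; keep well-supported groups.

    Peaks overlapping by >= 1 bp are grouped transitively (a chain A-B-C is
    one group). Groups containing peaks from at least ``min_support``
    distinct cell lines are kept. The consensus interval is the union span
    of the members; the representative summit is the summit of the member
    with the highest signal (ties -> leftmost summit).
    """
    if min_support > len(peaksets):
        raise ValueError(
            f"min_support {min_support} exceeds number of peaksets {len(peaksets)}"
        )
    tagged = [
        (p, line) for line in sorted(peaksets) for p in peaksets[line]
    ]
    tagged.sort(key=lambda t: (t[0].interval.chrom, t[0].interval.start, t[0].interval.end))
    out: list[ConsensusPeak] = []
    group: list[tuple[Peak, str]] = []
    group_end = -1
    group_chrom = None

    def flush() -> None:
        lines = {line for _, line in group}
        if len(lines) < min_support:
            return
        members = tuple(p for p, _ in group)
        start = min(p.interval.start for p in members)
        end = max(p.interval.end for p in members)
        best = max(members, key=lambda p: (p.signal, -p.summit))
        out.append(
            ConsensusPeak(
                interval=GenomicInterval(group_chrom, start, end),
                summit=best.summit,
                support=len(lines),
                members=members,
            )
        )

    for p, line in tagged:
        iv = p.interval
        if group and iv.chrom == group_chrom and iv.start < group_end:
            group.append((p, line))
            group_end = max(group_end, iv.end)
        else:
            if group:
                flush()
            group = [(p, line)]
            group_chrom, group_end = iv.chrom, iv.end
    if group:
        flush()
    return [
        ConsensusPeak(c.interval, c.summit, c.support, c.members, name=f"consensus_{i + 1}")
        for i, c in enumerate(out)
    ]


def _as_peak(c: ConsensusPeak) -> Peak:
    return Peak(c.interval, c.summit, 0.0, name=c.name)


def state_matrix(
    consensus: list[ConsensusPeak],
    tracks: dict[str, dict[str, FragmentTrack]],
    window: int = 10_000,
    bin_width: int = 10,
    required_marks: tuple[str, ...] = CLUSTERING_MARKS,
) -> dict[str, SignalMatrix]:
    """Per-mark summit-centered matrices, averaged across cell lines.

    ``tracks`` maps mark -> {cell line -> FragmentTrack}. Rows are aligned
    across marks in consensus order. The clustering marks must be present;
    extra marks (ATAC, TF ChIP) are carried for display.
    """
    missing = [m for m in required_marks if m not in tracks]
    if missing:
        raise ValueError(f"missing clustering marks: {missing}")
    peaks = [_as_peak(c) for c in consensus]
    out: dict[str, SignalMatrix] = {}
    for mark in tracks:
        per_line = [
            summit_matrix(peaks, t, window=window, bin_width=bin_width)
            for _, t in sorted(tracks[mark].items())
        ]
        values = np.mean([m.values for m in per_line], axis=0)
        out[mark] = SignalMatrix(
            row_ids=[p.name for p in peaks],
            bin_width=bin_width,
            window=window,
            values=values,
        )
    return out


def cluster_states(
    matrices: dict[str, SignalMatrix],
    k: int = 3,
    scale: bool = True,
    marks: tuple[str, ...] = CLUSTERING_MARKS,
) -> list[StateAssignment]:
    """Ward-D2 hierarchical clustering of concatenated mark profiles.

    Features are the concatenated bin vectors of the clustering marks,
    z-scaled per mark by default so no single mark dominates the Euclidean
    distance (``scale=False`` clusters raw densities). The tree is cut into
    k clusters and labels are renumbered 1..k by decreasing cluster mean
    H3K27ac signal, making labels deterministic.
    """
    mats = [matrices[m] for m in marks]
    row_ids = mats[0].row_ids
    for m in mats[1:]:
        if m.row_ids != row_ids:
            raise ValueError("matrices are not row-aligned")
    n = len(row_ids)
    if n < k:
        raise ValueError(f"cannot cut {n} rows into {k} clusters")
    blocks = []
    for m in mats:
        v = m.values
        if scale:
            sd = v.std()
            v = (v - v.mean()) / sd if sd > 0 else v - v.mean()
        blocks.append(v)
    features = np.hstack(blocks)
    if n == k:
        labels = np.arange(1, n + 1)
    else:
        Z = linkage(features, method="ward")  # Ward-D2 on Euclidean distances
        labels = fcluster(Z, t=k, criterion="maxclust")
    # renumber by decreasing mean H3K27ac (raw, not scaled)
    k27 = matrices[marks[0]].values.mean(axis=1)
    order = sorted(
        set(labels), key=lambda c: (-float(k27[labels == c].mean()), c)
    )
    relabel = {old: new for new, old in enumerate(order, start=1)}
    out = []
    for i, rid in enumerate(row_ids):
        means = {m: float(matrices[m].values[i].mean()) for m in marks}
        out.append(StateAssignment(rid, relabel[labels[i]], means))
    return out
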