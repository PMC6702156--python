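"""Differential-expression filtering, peak-distance gene categories, and
effect-size comparison between categories.

Knockdown-responsive genes (|log2FC| > 0.6, adjusted p < 1e-10 by default)
are categorized by the distance from their closest TSS to the nearest TF
consensus peak: Promoter (< 10 kb), Enhancer (10-400 kb, both ends
inclusive so the partition is total), Distal (> 400 kb), or Unassigned
when no peak shares a chromosome. Category effect sizes are compared with
Welch's unequal-variance t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConsensusPeak
from .intervals import TSSRecord, nearest_distance

LFC_CUTOFF = 0.6
PADJ_CUTOFF = 1e-10
PROMOTER_MAX = 10_000
ENHANCER_MAX = 400_000


@dataclass(frozen=True)
class GeneCategory:
    gene_id: str
    distance_bp: float
    category: str  # Promoter | Enhancer | Distal | Unassigned


def filter_de(
    records: pd.DataFrame,
    lfc_cutoff: float = LFC_CUTOFF,
    padj_cutoff: float = PADJ_CUTOFF,
) -> tuple[set[str], set[str]]:
    """Split DE records into (up, down) gene-id sets by strict cutoffs.

    Kept iff ``|log2fc| > lfc_cutoff`` and ``padj < padj_cutoff`` (both
    strict; log2FC 0.6 = 1.5-fold is the boundary and is excluded).
    Non-finite rows are skipped with a warning.
    """
    up: set[str] = set()
    down: set[str] = set()
    for row in records.itertuples(index=False):
        lfc, padj = float(row.log2fc), float(row.padj)
        if not (math.isfinite(lfc) and math.isfinite(padj)):
            warnings.warn(f"skipping non-finite DE record for {row.gene_id}")
            continue
        if abs(lfc) > lfc_cutoff and padj < padj_cutoff:
            (up if lfc > 0 else down).add(str(row.gene_id))
    return up, down


def categorize_by_peak_distance(
    tss: list[TSSRecord],
    peaks: list[ConsensusPeak],
    gene_ids: set[str] | None = None,
    promoter_max: int = PROMOTER_MAX,
    enhancer_max: int = ENHANCER_MAX,
) -> list[GeneCategory]:
    """Distance-based category of each gene relative to TF consensus peaks.

    Gene distance = min over its transcript TSSs of the nearest-peak
    distance. Promoter: d < promoter_max; Enhancer: promoter_max <= d <=
    enhancer_max; Distal: d > enhancer_max; Unassigned: no peak on the
    gene's chromosome(s).
    """
    by_chrom: dict[str, list] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p.interval)
    best: dict[str, float] = {}
    for rec in tss:
        if gene_ids is not None and rec.gene_id not in gene_ids:
            continue
        d, _ = nearest_distance(rec.tss, by_chrom.get(rec.tss.chrom, []))
        if d < best.get(rec.gene_id, math.inf):
            best[rec.gene_id] = d
        best.setdefault(rec.gene_id, d)
    out = []
    for gid in sorted(best):
        d = best[gid]
        if math.isinf(d):
            cat = "Unassigned"
        elif d < promoter_max:
            cat = "Promoter"
        elif d <= enhancer_max:
            cat = "Enhancer"
        else:
            cat = "Distal"
        out.append(GeneCategory(gid, d, cat))
    return out


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, two-sided p, Welch df).

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with the
    Welch-Satterthwaite degrees of freedom; p from the t distribution.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    if a.var(ddof=1) == 0 or b.var(ddof=1) == 0:
        raise ValueError("degenerate group with zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(res.df)
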