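"""Brute-force reference implementations, independent of the package's
algorithms, used to freeze expected values and cross-check operations."""

from __future__ import annotations

import itertools
import math

import numpy as np

from corecirc.intervals import GenomicInterval


def merge_oracle(intervals, gap):
    """Union-find over all pairs with distance <= gap (O(n^2))."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom == b.chrom and a.distance(b) <= gap:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(intervals[i])
    spans = [
        GenomicInterval(
            c[0].chrom, min(x.start for x in c), max(x.end for x in c)
        )
        for c in comps.values()
    ]
    return sorted(spans, key=lambda x: (x.chrom, x.start))


def nearest_oracle(query, targets):
    """Exhaustive O(n) scan with the stated tie-breaks."""
    best, best_i = math.inf, None
    for i, t in enumerate(targets):
        d = query.distance(t)
        if d < best or (
            d == best and best_i is not None and t.start < targets[best_i].start
        ):
            best, best_i = d, i
    return (best, best_i) if best != math.inf else (math.inf, None)


def density_oracle(fragments, total_mapped, region, extension=200):
    """Naive per-base loop: extend each fragment, count overlaps base by base."""
    cov = 0
    for f in fragments:
        length = max(f.end - f.start, extension)
        if f.strand == "-":
            s, e = f.end - length, f.end
        else:
            s, e = f.start, f.start + length
        s = max(s, 0)
        if f.chrom != region.chrom:
            continue
        for base in range(region.start, region.end):
            if s <= base < e:
                cov += 1
    return cov / (region.end - region.start) / (total_mapped / 1e6)


def pwm_scan_oracle(seq, qpwm):
    """Integer window scores at every offset, both strands, by explicit loops.

    Returns [(offset, strand, score)] for windows without N.
    """
    comp = {0: 3, 1: 2, 2: 1, 3: 0}
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = qpwm.shape[1]
    out = []
    codes = [code.get(b.upper(), 4) for b in seq]
    for i in range(len(seq) - L + 1):
        window = codes[i : i + L]
        if 4 in window:
            continue
        fwd = sum(qpwm[window[j], j] for j in range(L))
        rc = [comp[b] for b in reversed(window)]
        rev = sum(qpwm[rc[j], j] for j in range(L))
        out.append((i, "+", int(fwd)))
        out.append((i, "-", int(rev)))
    return out


def pvalue_enumeration_oracle(qpwm, background, score_int):
    """P(Score >= s) by exhaustive enumeration of all 4^L sequences."""
    L = qpwm.shape[1]
    total = 0.0
    for word in itertools.product(range(4), repeat=L):
        s = sum(int(qpwm[b, j]) for j, b in enumerate(word))
        if s >= score_int:
            p = 1.0
            for b in word:
                p *= background[b]
            total += p
    return total


def bh_oracle(pvals):
    """Step-up BH by the textbook definition q_(i) = min_{j>=i} m p_(j)/j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        q[i] = min(
            min(m * pvals[order[j - 1]] / j for j in range(rank_pos, m + 1)), 1.0
        )
    return q


def cutoff_oracle(signals):
    """Scan every candidate rank of the scaled curve for the first slope > 1."""
    sig = sorted(signals)
    n = len(sig)
    smin, smax = sig[0], sig[-1]
    if smax == smin:
        return math.inf
    for i in range(n - 1):
        slope = ((sig[i + 1] - sig[i]) / (smax - smin)) * (n - 1)
        if slope > 1.0:
            return sig[i]
    return math.inf


def degree_oracle(edges, nodes):
    """Total degree per node by direct scanning of the edge list."""
    out = {}
    for t in nodes:
        regulators = {a for a, b in edges if b == t}
        targets = {b for a, b in edges if a == t}
        out[t] = len(regulators) + len(targets)
    return out


def welch_oracle(a, b):
    """Closed-form Welch statistic and Welch-Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


def pvalue_enumeration_vec(qpwm, background):
    """Exact null distribution by direct enumeration of all 4^L words,
    vectorized over the word table; returns (scores, probs) arrays."""
    L = qpwm.shape[1]
    words = np.stack(
        np.meshgrid(*[np.arange(4)] * L, indexing="ij"), axis=-1
    ).reshape(-1, L)
    scores = np.zeros(len(words), dtype=np.int64)
    probs = np.ones(len(words))
    for j in range(L):
        scores += qpwm[words[:, j], j]
        probs *= np.asarray(background)[words[:, j]]
    return scores, probs


def tail_from_enumeration(scores, probs, s):
    return float(probs[scores >= s].sum())
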