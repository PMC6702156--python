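"""PWM motif scanning with exact null p-values and BH control.

A position frequency matrix is converted to a log-odds PWM against a
background base composition with a pseudocount. Scores are rounded to a
fixed grid (1e-3 bits by default) and the exact distribution of the total
score under independent background-distributed bases is computed by
column-wise convolution over that grid, giving an exact tail probability
p(s) = P(Score >= s) for every attainable score — the same construction
FIMO uses. Both strands are scanned; hits are filtered by
Benjamini-Hochberg q-value, with every scanned window (not only emitted
hits) counted as a test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .intervals import GenomicInterval

SCORE_GRANULARITY = 1e-3  # bits per grid unit for the convolution
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
UNIFORM_BACKGROUND = np.full(4, 0.25)


def pfm_to_pwm(
    counts: np.ndarray, background: np.ndarray, pseudocount: float = 0.1
) -> np.ndarray:
    """Log2-odds PWM from a 4 x L count matrix.

    ``pwm[b, i] = log2(((counts[b,i] + pc*background[b]) / (colsum_i + pc))
    / background[b])``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = np.asarray(counts, dtype=float)
    background = np.asarray(background, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("counts must be a 4 x L matrix (A,C,G,T rows)")
    if np.any(background <= 0):
        raise ValueError("background frequencies must be positive")
    colsum = counts.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("zero column sum in count matrix")
    freq = (counts + pseudocount * background[:, None]) / (colsum + pseudocount)
    return np.log2(freq / background[:, None])


@dataclass
class MotifModel:
    """A TF's count matrix, derived log-odds PWM, and exact null distribution."""

    tf_name: str
    counts: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.1
    granularity: float = SCORE_GRANULARITY

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background must sum to 1")
        self.pwm = pfm_to_pwm(self.counts, self.background, self.pseudocount)
        # integer score grid: all scoring and p-values use these units so
        # the scanner and the null distribution agree exactly
        self.qpwm = np.rint(self.pwm / self.granularity).astype(np.int64)
        self._tail: np.ndarray | None = None
        self._tail_min: int = 0

    @property
    def length(self) -> int:
        return self.pwm.shape[1]

    def _null_tail(self) -> tuple[np.ndarray, int]:
        """Exact tail P(Score_int >= k) by column-wise convolution."""
        if self._tail is None:
            dist = np.array([1.0])  # P(partial sum = cur_offset + index)
            cur_offset = 0
            for i in range(self.length):
                col = self.qpwm[:, i]
                clo, chi = int(col.min()), int(col.max())
                new = np.zeros(len(dist) + (chi - clo))
                for b in range(4):
                    new[col[b] - clo : col[b] - clo + len(dist)] += (
                        self.background[b] * dist
                    )
                dist = new
                cur_offset += clo
            tail = np.cumsum(dist[::-1])[::-1]
            self._tail = tail
            self._tail_min = cur_offset
        return self._tail, self._tail_min

    def pvalue_int(self, score_int: int) -> float:
        tail, lo = self._null_tail()
        idx = score_int - lo
        if idx <= 0:
            return 1.0
        if idx >= len(tail):
            return float(tail[-1])  # above max attainable: smallest tail mass
        return float(tail[idx])

    def pvalue(self, score_bits: float) -> float:
        """Exact P(Score >= s) under the background, s in bits."""
        return self.pvalue_int(int(np.rint(score_bits / self.granularity)))

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.counts, axis=0))


def exact_score_pvalue(motif: MotifModel):
    """Return the exact score -> tail-probability function of a motif."""
    return motif.pvalue


@dataclass(frozen=True)
class MotifHit:
    tf_name: str
    interval: GenomicInterval
    strand: str
    score: float  # log-odds, bits
    p_value: float
    q_value: float = float("nan")


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (incl. N) -> 4."""
    lut = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, qpwm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores of all windows plus a validity mask (no N)."""
    L = qpwm.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    scores = np.zeros(n, dtype=np.int64)
    # column 4 scores 0 but such windows are masked out
    lut = np.vstack([qpwm, np.zeros((1, L), dtype=np.int64)])
    is_n = codes == 4
    bad = np.zeros(n, dtype=np.int64)
    for j in range(L):
        scores += lut[codes[j : j + n], j]
        bad += is_n[j : j + n]
    return scores, bad == 0


def scan_sequence(
    seq: str,
    motif: MotifModel,
    p_threshold: float = 1e-4,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan both strands of a sequence for motif occurrences.

    The reverse strand is scanned via the reverse complement of each
    window; positions are reported on the forward coordinate system
    (genomic coordinates if ``chrom``/``offset`` are given). Windows
    containing N are skipped. A hit is emitted where the exact p-value of
    its score is <= ``p_threshold``. q-values are left unset here.
    """
    hits, _ = _scan_counted(seq, motif, p_threshold, chrom, offset)
    return hits


def _scan_counted(
    seq: str, motif: MotifModel, p_threshold: float, chrom: str, offset: int
) -> tuple[list[MotifHit], int]:
    """Scan and also report the number of windows tested (both strands)."""
    codes = encode_sequence(seq)
    L = motif.length
    if len(codes) < L:
        return [], 0
    # reverse-complement PWM: complement rows, reverse columns
    rc_qpwm = motif.qpwm[::-1, ::-1]
    hits: list[MotifHit] = []
    n_tests = 0
    for strand, q in (("+", motif.qpwm), ("-", rc_qpwm)):
        scores, valid = _window_scores(codes, q)
        n_tests += int(valid.sum())
        for i in np.nonzero(valid)[0]:
            p = motif.pvalue_int(int(scores[i]))
            if p <= p_threshold:
                iv = GenomicInterval(chrom, offset + int(i), offset + int(i) + L, strand)
                hits.append(
                    MotifHit(
                        motif.tf_name,
                        iv,
                        strand,
                        float(scores[i]) * motif.granularity,
                        p,
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits, n_tests


def bh_qvalues(p_values, n_tests: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order preserved on return.

    ``n_tests`` sets the family size m explicitly (>= len(p_values)); this
    lets callers count tests that did not pass a pre-filter. Hand-rolled
    because statsmodels' fdr_bh has no external-m parameter; cross-checked
    against it in the tests for the m == len case.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p) if n_tests is None else int(n_tests)
    if m < len(p):
        raise ValueError("n_tests must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, len(p) + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def estimate_background(sequences: list[str]) -> np.ndarray:
    """Pooled mononucleotide frequencies (N excluded) of a sequence set."""
    counts = np.zeros(4)
    for s in sequences:
        codes = encode_sequence(s)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return UNIFORM_BACKGROUND.copy()
    return counts / counts.sum()


def scan_nfrs(
    nfrs,
    genome,
    motif_db: list[MotifModel] | dict[str, np.ndarray],
    q_threshold: float = 1e-5,
    background: np.ndarray | None = None,
    fdr_scope: str = "per-tf",
    pseudocount: float = 0.1,
) -> dict[str, list[tuple[int, MotifHit]]]:
    """Scan nucleosome-free regions with every motif; BH-filter hits.

    Parameters
    ----------
    nfrs : list of NucleosomeFreeRegion (or objects with ``.interval``)
    genome : pyfaidx.Fasta or mapping chrom -> sequence string
    motif_db : MotifModels, or raw ``{tf: 4 x L counts}`` (converted using
        the estimated background)
    q_threshold : keep hits with BH q <= this (1e-5 in the reference run)
    background : base composition; default estimated from the NFR
        sequences themselves (pooled mononucleotide frequencies)
    fdr_scope : 'per-tf' (one BH family per motif, the scanner default) or
        'global' (one family across all motifs)

    Returns ``{tf_name: [(nfr_index, MotifHit), ...]}`` with q-values set.
    Every scanned window counts as a test in the BH family.
    """
    if fdr_scope not in ("per-tf", "global"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    seqs = []
    for nfr in nfrs:
        iv = nfr.interval
        try:
            chrom_seq = genome[iv.chrom]
        except KeyError as exc:
            raise ValueError(f"NFR {iv} not resolvable in genome") from exc
        s = str(chrom_seq[iv.start : iv.end])
        if len(s) != len(iv):
            raise ValueError(f"NFR {iv} outside FASTA bounds")
        seqs.append(s)
    if background is None:
        background = estimate_background(seqs)
    if isinstance(motif_db, dict):
        motifs = [
            MotifModel(tf, counts, background, pseudocount)
            for tf, counts in sorted(motif_db.items())
        ]
    else:
        motifs = list(motif_db)

    raw: dict[str, list[tuple[int, MotifHit]]] = {}
    tests: dict[str, int] = {}
    for motif in motifs:
        per_tf: list[tuple[int, MotifHit]] = []
        m_tests = 0
        for idx, (nfr, seq) in enumerate(zip(nfrs, seqs)):
            iv = nfr.interval
            hits, n = _scan_counted(seq, motif, q_threshold, iv.chrom, iv.start)
            m_tests += n
            per_tf.extend((idx, h) for h in hits)
        raw[motif.tf_name] = per_tf
        tests[motif.tf_name] = m_tests

    out: dict[str, list[tuple[int, MotifHit]]] = {}
    if fdr_scope == "per-tf":
        families = [([tf], raw[tf], tests[tf]) for tf in raw]
    else:
        pooled = [(tf, idx, h) for tf in raw for idx, h in raw[tf]]
        families = [
            (list(raw), [(idx, h) for _, idx, h in pooled], sum(tests.values()))
        ]
        # keep tf association by re-tagging below via h.tf_name
    for _, items, m in families:
        if not items:
            continue
        q = bh_qvalues([h.p_value for _, h in items], n_tests=max(m, len(items)))
        for (idx, h), qv in zip(items, q):
            if qv <= q_threshold:
                kept = MotifHit(h.tf_name, h.interval, h.strand, h.score, h.p_value, float(qv))
                out.setdefault(h.tf_name, []).append((idx, kept))
    for tf in out:
        out[tf].sort(key=lambda t: (t[0], t[1].interval.start, t[1].strand))
    return out
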