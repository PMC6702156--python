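"""Seeded synthetic epigenomic landscapes with machine-readable ground truth.

The generator emulates the inputs the pipeline consumes — genome FASTA,
TSS annotation, JASPAR motif matrices, per-cell-line peak calls for
H3K27ac / H3K4me1 / H3K4me3 / ATAC / TF ChIP, fragment BEDs with library
sizes, and a differential-expression table — with the statistical
structure the analysis assumes:

* a planted TF regulatory network with a designated master regulator,
  realized by writing each regulator's consensus motif into a
  nucleosome-free region inside a super-enhancer of the target TF gene;
* a hockey-stick enhancer signal law (log-normal body of typical
  enhancers, planted super-enhancers in the far upper tail);
* three chromatin-state archetypes of TF binding sites (enhancer-like,
  promoter-like, low-signal) realized in the histone-mark fragments;
* knockdown DE effects for TF-bound genes, with the bound site at
  promoter, enhancer or distal range so every distance category is
  populated.

Every pseudo-random stream is derived from (seed, stream label), so the
same seed yields byte-identical output trees and adding a track never
perturbs the others.

The generated peak files contain calls only at planted loci; chromatin
signal at TF binding sites that is deliberately left uncalled (the state
archetypes) mimics sub-threshold enhancers and keeps the enhancer ranking
controlled by the planted signal law.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cc_io
from .intervals import GenomicInterval, Peak, TSSRecord
from .network import RegulatoryEdge, total_degrees
from .signal import SignalMatrix

READ_LENGTH = 50
PEAK_WIDTH = 300

# per-state mean reads per peak per cell line; keys are pipeline marks.
# Mean H3K27ac decreases 1 -> 3 so cluster renumbering is unambiguous.
STATE_ARCHETYPES = {
    1: {"H3K27ac": 400, "H3K4me1": 350, "H3K4me3": 15, "ATAC": 150, "TF": 200},
    2: {"H3K27ac": 250, "H3K4me1": 15, "H3K4me3": 350, "ATAC": 150, "TF": 200},
    3: {"H3K27ac": 8, "H3K4me1": 8, "H3K4me3": 8, "ATAC": 30, "TF": 200},
}


@dataclass
class SynthConfig:
    """All knobs of the generator; defaults are the small-fixture conditions."""

    seed: int = 0
    chrom_name: str = "chr1"
    chrom_length: int = 2_000_000
    n_tfs: int = 8
    n_null_active: int = 8
    n_distal: int = 4
    n_null_inactive: int = 4
    n_cell_lines: int = 4
    block_size: int = 120_000
    gc: float = 0.41
    motif_length: int = 18
    motif_total_count: int = 200
    planted_network: dict[str, list[str]] | None = None
    master: str = "TF01"
    n_state_peaks_per_state: int = 15
    n_low_support_peaks: int = 3
    # signal model (reads per peak per line unless noted)
    se_constituent_reads: float = 500.0
    promoter_reads: float = 80.0
    atac_nfr_reads: float = 200.0
    bg_enhancer_logmean: float = 3.0  # log-normal body of typical enhancers
    bg_enhancer_logsd: float = 0.4
    background_reads: int = 4000  # uniform reads per track
    total_mapped: int = 1_000_000
    # DE model: knockdown of the master shifts bound genes down
    target_lfc_mean: float = -1.5
    target_lfc_sd: float = 0.3
    category_effect: float = 0.8  # enhancer-bound genes shift further down
    null_lfc_sd: float = 0.2

    @property
    def n_genes(self) -> int:
        return 3 * self.n_tfs + self.n_null_active + self.n_distal + self.n_null_inactive

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i + 1:02d}" for i in range(self.n_tfs)]

    def network(self) -> dict[str, list[str]]:
        """Planted edges; defaults to a master-regulator clique-like wiring.

        The master regulates every TF (itself included), every TF regulates
        the master, and the non-master TFs form a ring — the master's total
        degree strictly exceeds every other TF's.
        """
        if self.planted_network is not None:
            return {k: sorted(v) for k, v in sorted(self.planted_network.items())}
        tfs = self.tf_names
        m = self.master
        others = [t for t in tfs if t != m]
        net: dict[str, set[str]] = {t: set() for t in tfs}
        net[m].update(tfs)  # master -> all, incl. autoregulation
        for t in others:
            net[t].add(m)
        for i, t in enumerate(others):
            net[t].add(others[(i + 1) % len(others)])
        return {k: sorted(v) for k, v in net.items()}


def make_fixture(name: str = "small") -> SynthConfig:
    """Preset configurations: 'small' (2 Mb, 40 genes, 8 TFs) or 'medium'
    (10 Mb, 300 genes, 25 TFs, echoing the scale of the reference study)."""
    if name == "small":
        return SynthConfig()
    if name == "medium":
        return SynthConfig(
            chrom_length=10_000_000,
            n_tfs=25,
            n_null_active=200,
            n_distal=10,
            n_null_inactive=15,
            n_state_peaks_per_state=30,
            n_low_support_peaks=5,
        )
    raise ValueError(f"unknown fixture {name!r}")


@dataclass
class GroundTruth:
    """What was planted, for comparison with pipeline output."""

    master: str
    edges: list[tuple[str, str]]
    total_degree: dict[str, int]
    se_intervals: list[tuple[str, int, int]]
    nfr_intervals: list[tuple[str, int, int]]
    state_labels: list[dict]  # [{"summit": pos, "state": k}] in genomic order
    de_targets: dict[str, dict]  # gene_id -> {category, log2fc}
    gene_categories: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "master": self.master,
            "edges": [list(e) for e in self.edges],
            "total_degree": self.total_degree,
            "se_intervals": [list(x) for x in self.se_intervals],
            "nfr_intervals": [list(x) for x in self.nfr_intervals],
            "state_labels": self.state_labels,
            "de_targets": self.de_targets,
            "gene_categories": self.gene_categories,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            master=obj["master"],
            edges=[tuple(e) for e in obj["edges"]],
            total_degree=obj["total_degree"],
            se_intervals=[tuple(x) for x in obj["se_intervals"]],
            nfr_intervals=[tuple(x) for x in obj["nfr_intervals"]],
            state_labels=obj["state_labels"],
            de_targets=obj["de_targets"],
            gene_categories=obj["gene_categories"],
        )


def _rng(seed: int, label: str) -> np.random.Generator:
    """One independent stream per (seed, label)."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))
    )


@dataclass
class _Layout:
    """Deterministic genomic coordinates of every planted element."""

    cfg: SynthConfig
    tf_tss: dict[str, int] = field(default_factory=dict)
    prom_gene_tss: dict[str, int] = field(default_factory=dict)
    enh_gene_tss: dict[str, int] = field(default_factory=dict)
    null_active_tss: dict[str, int] = field(default_factory=dict)
    distal_tss: dict[str, int] = field(default_factory=dict)
    null_inactive_tss: dict[str, int] = field(default_factory=dict)
    se_constituents: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    nfr_zones: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    bg_enhancers: list[tuple[int, int]] = field(default_factory=list)
    category_peaks: list[int] = field(default_factory=list)  # summit centers
    state_peaks: list[tuple[int, int]] = field(default_factory=list)  # (center, state)
    low_support_peaks: list[int] = field(default_factory=list)


def _build_layout(cfg: SynthConfig) -> _Layout:
    lay = _Layout(cfg)
    gid = iter(range(1, cfg.n_genes + 1))
    for i, tf in enumerate(cfg.tf_names):
        b = i * cfg.block_size
        lay.tf_tss[tf] = b + 10_000
        lay.se_constituents[tf] = [
            (b + 16_000, b + 18_000),
            (b + 19_000, b + 21_000),
            (b + 22_000, b + 24_000),
        ]
        lay.nfr_zones[tf] = [(b + 16_650, b + 17_350), (b + 22_650, b + 23_350)]
        lay.prom_gene_tss[f"PROMG{i + 1:02d}"] = b + 50_000
        lay.category_peaks.append(b + 52_150)  # summit; peak [52000, 52300)
        lay.enh_gene_tss[f"ENHG{i + 1:02d}"] = b + 80_000
        lay.bg_enhancers.append((b + 65_000, b + 66_200))
    blocks_end = cfg.n_tfs * cfg.block_size
    nulls_per_block = -(-cfg.n_null_active // cfg.n_tfs)
    for j in range(cfg.n_null_active):
        blk, off = divmod(j, nulls_per_block)
        lay.null_active_tss[f"NULLA{j + 1:03d}"] = (
            blk * cfg.block_size + 95_000 + off * 2_000
        )
    state_start = blocks_end + 10_000
    spacing = 11_000
    n_state = 3 * cfg.n_state_peaks_per_state
    for j in range(n_state):
        lay.state_peaks.append((state_start + j * spacing + 150, (j % 3) + 1))
    low_start = state_start + n_state * spacing + 6_000
    for j in range(cfg.n_low_support_peaks):
        lay.low_support_peaks.append(low_start + j * 6_000 + 150)
    desert = low_start + cfg.n_low_support_peaks * 6_000 + 10_000
    for j in range(cfg.n_null_inactive):
        lay.null_inactive_tss[f"NULLI{j + 1:03d}"] = desert + j * 5_000
    bg2 = desert + cfg.n_null_inactive * 5_000 + 10_000
    for j in range(max(cfg.n_tfs, 8)):
        lay.bg_enhancers.append((bg2 + j * 5_000, bg2 + j * 5_000 + 1_200))
    last_peak = max(
        [c for c, _ in lay.state_peaks] + lay.low_support_peaks + lay.category_peaks
    )
    distal_start = last_peak + 420_000
    for j in range(cfg.n_distal):
        lay.distal_tss[f"DISTG{j + 1:02d}"] = distal_start + j * 20_000
    needed = distal_start + cfg.n_distal * 20_000 + 10_000
    if needed > cfg.chrom_length:
        raise ValueError(
            f"layout needs {needed} bp but chrom_length is {cfg.chrom_length}"
        )
    return lay


def _make_motifs(cfg: SynthConfig) -> dict[str, str]:
    """High-information consensus sequences, pairwise Hamming distance >= 6."""
    rng = _rng(cfg.seed, "motifs")
    bases = np.array(list("ACGT"))
    consensi: dict[str, str] = {}
    for tf in cfg.tf_names:
        while True:
            cand = "".join(rng.choice(bases, size=cfg.motif_length))
            if all(
                sum(a != b for a, b in zip(cand, other)) >= 6
                for other in consensi.values()
            ):
                consensi[tf] = cand
                break
    return consensi


def _consensus_to_counts(consensus: str, total: int) -> np.ndarray:
    counts = np.ones((4, len(consensus)))
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, b in enumerate(consensus):
        counts[idx[b], i] = total - 3
    return counts


def _peak_reads(
    rng: np.random.Generator, center: int, mean_reads: float, chrom_length: int
) -> list[tuple[int, int, str]]:
    """Read 5'-start intervals around a binding site (Poisson count)."""
    n = rng.poisson(mean_reads)
    centers = np.rint(rng.normal(center, 120, size=n)).astype(int)
    strands = rng.choice(["+", "-"], size=n)
    out = []
    for c, s in zip(centers, strands):
        start = int(np.clip(c - READ_LENGTH // 2, 0, chrom_length - READ_LENGTH))
        out.append((start, start + READ_LENGTH, str(s)))
    return out


@dataclass
class SyntheticBundle:
    """Paths of everything written plus the parsed ground truth."""

    outdir: Path
    config: SynthConfig
    truth: GroundTruth
    genome_fasta: Path
    tss_table: Path
    motifs: Path
    de_table: Path
    peaks: dict[str, dict[str, Path]]
    fragments: dict[str, dict[str, tuple[Path, Path]]]
    run_config: Path


def generate(cfg: SynthConfig, outdir: str | Path) -> SyntheticBundle:
    """Write a complete synthetic input bundle and its ground truth."""
    outdir = Path(outdir)
    lay = _build_layout(cfg)  # raises before any file is written
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "peaks").mkdir(exist_ok=True)
    (outdir / "fragments").mkdir(exist_ok=True)
    lines = [f"L{i + 1}" for i in range(cfg.n_cell_lines)]
    chrom, clen = cfg.chrom_name, cfg.chrom_length

    # ---- genome with planted motifs -------------------------------------
    rng = _rng(cfg.seed, "genome")
    p = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=clen, p=p)
    consensi = _make_motifs(cfg)
    network = cfg.network()
    edges = sorted((a, b) for a, targets in network.items() for b in targets)
    plant_positions: dict[tuple[str, str], int] = {}
    for target in cfg.tf_names:
        sources = sorted(a for a, b in edges if b == target)
        zones = lay.nfr_zones[target]
        for slot, source in enumerate(sources):
            zone = zones[slot % len(zones)]
            zc = (zone[0] + zone[1]) // 2
            pos = zc - 300 + (slot // len(zones)) * 40
            motif = consensi[source]
            seq[pos : pos + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)
            plant_positions[(source, target)] = pos
    genome_fasta = outdir / "genome.fa"
    with open(genome_fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        raw = seq.tobytes().decode("ascii")
        for i in range(0, clen, 80):
            fh.write(raw[i : i + 80] + "\n")

    # ---- motif database --------------------------------------------------
    pfms = {
        tf: _consensus_to_counts(consensi[tf], cfg.motif_total_count)
        for tf in cfg.tf_names
    }
    motifs_path = outdir / "motifs.jaspar"
    cc_io.write_jaspar_pfms(motifs_path, pfms)

    # ---- TSS annotation --------------------------------------------------
    tss_records: list[TSSRecord] = []

    def add_gene(symbol: str, pos: int, is_tf: bool) -> None:
        gid = f"G{len(tss_records) + 1:04d}"
        tss_records.append(
            TSSRecord(gid, symbol, GenomicInterval(chrom, pos, pos + 1, "+"), is_tf)
        )

    for tf in cfg.tf_names:
        add_gene(tf, lay.tf_tss[tf], True)
    for sym, pos in lay.prom_gene_tss.items():
        add_gene(sym, pos, False)
    for sym, pos in lay.enh_gene_tss.items():
        add_gene(sym, pos, False)
    for sym, pos in lay.null_active_tss.items():
        add_gene(sym, pos, False)
    for sym, pos in lay.distal_tss.items():
        add_gene(sym, pos, False)
    for sym, pos in lay.null_inactive_tss.items():
        add_gene(sym, pos, False)
    tss_path = outdir / "tss.tsv"
    cc_io.write_tss_table(tss_path, tss_records)
    symbol_to_gid = {r.gene_symbol: r.gene_id for r in tss_records}

    inactive = set(lay.null_inactive_tss)
    active_tss = [r for r in tss_records if r.gene_symbol not in inactive]

    # ---- per-line peak calls and fragments -------------------------------
    # support pattern for TF peaks: every 7th state peak is in 3 lines only
    state_support = {
        j: lines[:3] if j % 7 == 3 else lines
        for j in range(len(lay.state_peaks))
    }
    bg_strengths = _rng(cfg.seed, "bg-signal").lognormal(
        cfg.bg_enhancer_logmean, cfg.bg_enhancer_logsd, size=len(lay.bg_enhancers)
    )

    peak_paths: dict[str, dict[str, Path]] = {}
    frag_paths: dict[str, dict[str, tuple[Path, Path]]] = {}
    se_spans: dict[str, tuple[int, int]] = {}
    nfr_spans: dict[str, list[tuple[int, int]]] = {tf: [] for tf in cfg.tf_names}

    state_means = {
        mark: {k: STATE_ARCHETYPES[k][mark] for k in STATE_ARCHETYPES}
        for mark in ("H3K27ac", "H3K4me1", "H3K4me3", "ATAC", "TF")
    }

    for mark in ("H3K27ac", "H3K4me1", "H3K4me3", "ATAC", "TF"):
        peak_paths[mark] = {}
        frag_paths[mark] = {}
        for line in lines:
            rng = _rng(cfg.seed, f"{mark}:{line}")
            peaks: list[Peak] = []
            reads: list[tuple[int, int, str]] = []

            def call_peak(start: int, end: int, signal: float, jitter: int = 30) -> None:
                js = int(rng.integers(-jitter, jitter + 1))
                je = int(rng.integers(-jitter, jitter + 1))
                s, e = max(start + js, 0), min(end + je, clen)
                peaks.append(
                    Peak(
                        GenomicInterval(chrom, s, e),
                        (s + e) // 2,
                        float(f"{signal:.4g}"),
                        name=f"{mark}_{line}_{len(peaks) + 1}",
                        source=line,
                    )
                )

            def site_reads(center: int, mean: float) -> float:
                got = _peak_reads(rng, center, mean, clen)
                reads.extend(got)
                return float(len(got))

            if mark == "H3K27ac":
                for r in active_tss:
                    n = site_reads(r.position, cfg.promoter_reads)
                    call_peak(r.position - 200, r.position + 200, n, jitter=20)
                for tf in cfg.tf_names:
                    for s, e in lay.se_constituents[tf]:
                        n = site_reads((s + e) // 2, cfg.se_constituent_reads)
                        call_peak(s, e, n, jitter=50)
                for (s, e), strength in zip(lay.bg_enhancers, bg_strengths):
                    n = site_reads((s + e) // 2, strength)
                    call_peak(s, e, n, jitter=30)
                for j, (c, st) in enumerate(lay.state_peaks):
                    site_reads(c, state_means[mark][st])  # signal, no call
                for c in lay.low_support_peaks:
                    site_reads(c, state_means[mark][1])
                for c in lay.category_peaks:
                    site_reads(c, state_means[mark][2])
            elif mark == "H3K4me1":
                for tf in cfg.tf_names:
                    for s, e in lay.se_constituents[tf]:
                        n = site_reads((s + e) // 2, 200.0)
                        call_peak(s, e, n, jitter=50)
                for j, (c, st) in enumerate(lay.state_peaks):
                    site_reads(c, state_means[mark][st])
                for c in lay.low_support_peaks:
                    site_reads(c, state_means[mark][1])
                for c in lay.category_peaks:
                    site_reads(c, state_means[mark][2])
            elif mark == "H3K4me3":
                for r in active_tss:
                    n = site_reads(r.position, 150.0)
                    call_peak(r.position - 300, r.position + 300, n, jitter=20)
                for j, (c, st) in enumerate(lay.state_peaks):
                    site_reads(c, state_means[mark][st])
                for c in lay.low_support_peaks:
                    site_reads(c, state_means[mark][1])
                for c in lay.category_peaks:
                    site_reads(c, state_means[mark][2])
            elif mark == "ATAC":
                for tf in cfg.tf_names:
                    for s, e in lay.nfr_zones[tf]:
                        n = site_reads((s + e) // 2, cfg.atac_nfr_reads)
                        call_peak(s, e, n, jitter=30)
                for j, (c, st) in enumerate(lay.state_peaks):
                    site_reads(c, state_means[mark][st])
                for c in lay.category_peaks:
                    site_reads(c, state_means[mark][2])
            else:  # TF ChIP
                for j, (c, st) in enumerate(lay.state_peaks):
                    n = site_reads(c, state_means[mark][st])
                    if line in state_support[j]:
                        call_peak(c - PEAK_WIDTH // 2, c + PEAK_WIDTH // 2, n)
                for c in lay.category_peaks:
                    n = site_reads(c, state_means[mark][2])
                    call_peak(c - PEAK_WIDTH // 2, c + PEAK_WIDTH // 2, n)
                for c in lay.low_support_peaks:
                    n = site_reads(c, state_means[mark][1])
                    if line in lines[:2]:  # support 2: below consensus threshold
                        call_peak(c - PEAK_WIDTH // 2, c + PEAK_WIDTH // 2, n)

            # uniform background reads
            n_bg = int(rng.poisson(cfg.background_reads))
            starts = rng.integers(0, clen - READ_LENGTH, size=n_bg)
            strands = rng.choice(["+", "-"], size=n_bg)
            reads.extend(
                (int(s), int(s) + READ_LENGTH, str(st)) for s, st in zip(starts, strands)
            )
            reads.sort()

            ppath = outdir / "peaks" / f"{mark}.{line}.narrowPeak"
            cc_io.write_narrowpeak(ppath, peaks)
            peak_paths[mark][line] = ppath
            bpath = outdir / "fragments" / f"{mark}.{line}.bed"
            tpath = outdir / "fragments" / f"{mark}.{line}.total.json"
            with open(bpath, "w") as fh:
                for i, (s, e, st) in enumerate(reads):
                    fh.write(f"{chrom}\t{s}\t{e}\tr{i + 1}\t0\t{st}\n")
            cc_io.write_total_mapped(tpath, cfg.total_mapped)
            frag_paths[mark][line] = (bpath, tpath)

            if mark == "H3K27ac":
                for tf in cfg.tf_names:
                    cs = lay.se_constituents[tf]
                    lo = min(
                        p.interval.start
                        for p in peaks
                        if cs[0][0] - 100 <= p.interval.start <= cs[0][0] + 100
                    )
                    hi = max(
                        p.interval.end
                        for p in peaks
                        if cs[-1][1] - 100 <= p.interval.end <= cs[-1][1] + 100
                    )
                    cur = se_spans.get(tf, (lo, hi))
                    se_spans[tf] = (min(cur[0], lo), max(cur[1], hi))
            if mark == "ATAC":
                for tf in cfg.tf_names:
                    spans = []
                    for s, e in lay.nfr_zones[tf]:
                        members = [
                            p.interval
                            for p in peaks
                            if s - 100 <= p.interval.start <= s + 100
                        ]
                        spans.append(
                            (min(m.start for m in members), max(m.end for m in members))
                        )
                    prev = nfr_spans[tf]
                    if prev:
                        nfr_spans[tf] = [
                            (min(a[0], b[0]), max(a[1], b[1]))
                            for a, b in zip(prev, spans)
                        ]
                    else:
                        nfr_spans[tf] = spans

    # ---- DE table --------------------------------------------------------
    rng = _rng(cfg.seed, "de")
    de_rows = []
    de_targets: dict[str, dict] = {}
    gene_categories: dict[str, str] = {}
    half = cfg.category_effect / 2.0
    cat_mu = {
        "Promoter": cfg.target_lfc_mean + half,
        "Enhancer": cfg.target_lfc_mean - half,
        "Distal": cfg.target_lfc_mean,
    }
    target_groups = [
        ("Promoter", sorted(lay.prom_gene_tss)),
        ("Enhancer", sorted(lay.enh_gene_tss)),
        ("Distal", sorted(lay.distal_tss)),
    ]
    target_syms = {s for _, syms in target_groups for s in syms}
    for cat, syms in target_groups:
        for sym in syms:
            gid = symbol_to_gid[sym]
            # clamp so every planted target clears the 1.5-fold (|log2FC|>0.6)
            # selection cutoff with margin; nulls stay centered at zero
            lfc = min(float(rng.normal(cat_mu[cat], cfg.target_lfc_sd)), -0.8)
            padj = float(10.0 ** -rng.uniform(12, 18))
            tag = "metabolism" if int(sym[-2:]) % 2 else "cell-cycle"
            de_rows.append((gid, lfc, padj, tag))
            de_targets[gid] = {"category": cat, "log2fc": lfc}
            gene_categories[gid] = cat
    for r in tss_records:
        if r.gene_symbol in target_syms:
            continue
        lfc = float(rng.normal(0.0, cfg.null_lfc_sd))
        padj = float(rng.uniform(1e-3, 1.0))
        de_rows.append((r.gene_id, lfc, padj, ""))
    de_rows.sort()
    de_path = outdir / "de.tsv"
    with open(de_path, "w") as fh:
        fh.write("gene_id\tlog2fc\tpadj\ttag\n")
        for gid, lfc, padj, tag in de_rows:
            fh.write(f"{gid}\t{lfc:.6g}\t{padj:.6g}\t{tag}\n")

    # ---- ground truth ----------------------------------------------------
    degs = {
        n.tf_name: n.total_degree
        for n in total_degrees(
            [RegulatoryEdge(a, b, ((None, "", ""),)) for a, b in edges], cfg.tf_names
        )
    }
    state_labels = []
    for j, (c, st) in enumerate(lay.state_peaks):
        state_labels.append({"summit": c, "state": st})
    for c in lay.category_peaks:
        state_labels.append({"summit": c, "state": 2})
    state_labels.sort(key=lambda d: d["summit"])
    truth = GroundTruth(
        master=cfg.master,
        edges=edges,
        total_degree=degs,
        se_intervals=[(chrom, *se_spans[tf]) for tf in cfg.tf_names],
        nfr_intervals=[(chrom, *span) for tf in cfg.tf_names for span in nfr_spans[tf]],
        state_labels=state_labels,
        de_targets=de_targets,
        gene_categories=gene_categories,
    )
    truth.to_json(outdir / "ground_truth.json")

    # ---- run config ------------------------------------------------------
    from .pipeline import RunConfig  # deferred: pipeline imports synth types

    # paths relative to the bundle directory: trees are relocatable and
    # byte-identical across output locations
    rel = lambda p: str(Path(p).relative_to(outdir))
    run_cfg = RunConfig(
        genome_fasta=rel(genome_fasta),
        tss_table=rel(tss_path),
        motifs=rel(motifs_path),
        de_table=rel(de_path),
        peaks={m: {l: rel(p) for l, p in d.items()} for m, d in peak_paths.items()},
        fragments={
            m: {l: [rel(b), rel(t)] for l, (b, t) in d.items()}
            for m, d in frag_paths.items()
        },
        output_dir="results",
        seed=cfg.seed,
    )
    run_cfg_path = outdir / "config.yaml"
    run_cfg.to_yaml(run_cfg_path)

    with open(outdir / "synth_config.json", "w") as fh:
        json.dump(
            {k: v for k, v in vars(cfg).items() if not k.startswith("_")},
            fh,
            indent=1,
            sort_keys=True,
            default=str,
        )
        fh.write("\n")

    return SyntheticBundle(
        outdir=outdir,
        config=cfg,
        truth=truth,
        genome_fasta=genome_fasta,
        tss_table=tss_path,
        motifs=motifs_path,
        de_table=de_path,
        peaks=peak_paths,
        fragments=frag_paths,
        run_config=run_cfg_path,
    )


def generate_state_profiles(
    n_per_state: int = 50,
    n_bins: int = 100,
    seed: int = 0,
    noise_sd: float = 0.15,
    bin_width: int = 10,
) -> tuple[dict[str, SignalMatrix], np.ndarray]:
    """Summit-centered mark profiles drawn from the three state archetypes.

    Returns per-mark SignalMatrix objects (rows interleave the states) and
    the true state label per row. Profiles are Gaussian bumps with the
    archetype's per-mark amplitude plus additive noise; amplitudes are on
    an arbitrary density scale.
    """
    rng = _rng(seed, "state-profiles")
    marks = ("H3K27ac", "H3K4me1", "H3K4me3")
    n = 3 * n_per_state
    labels = np.array([(i % 3) + 1 for i in range(n)])
    x = np.linspace(-2.5, 2.5, n_bins)
    bump = np.exp(-0.5 * x**2)
    mats = {}
    scale = max(v for a in STATE_ARCHETYPES.values() for v in a.values())
    for mark in marks:
        amp = np.array([STATE_ARCHETYPES[l][mark] / scale for l in labels])
        clean = amp[:, None] * bump[None, :]
        vals = clean + rng.normal(0, noise_sd, size=clean.shape)
        vals = np.maximum(vals, 0.0)
        mats[mark] = SignalMatrix(
            row_ids=[f"site_{i + 1}" for i in range(n)],
            bin_width=bin_width,
            window=bin_width * n_bins,
            values=vals,
        )
    return mats, labels
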