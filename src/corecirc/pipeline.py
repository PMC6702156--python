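"""Stage orchestration: configuration, the two analysis entry points, and
deterministic reports.

``run_crc`` executes the circuitry branch: active genes -> enhancer
stitching/scoring -> super-enhancer cutoff -> SE-to-gene assignment ->
nucleosome-free regions -> motif scanning -> TF-TF graph -> total-degree
ranking. ``run_targets`` executes the binding-site branch: cross-line
consensus peaks -> summit-centered matrices -> chromatin-state clustering,
and DE filter -> peak-distance categories -> Welch comparisons. Outputs
are plain TSV/BED/JSON, written once per run directory, with a manifest
recording parameters and input content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import io as cc_io
from .consensus import cluster_states, consensus_peaks, state_matrix
from .intervals import Peak
from .motifs import scan_nfrs
from .network import build_graph, candidate_tfs, rank_tfs, total_degrees
from .signal import FragmentTrack, pool_tracks
from .superenh import (
    active_genes,
    assign_to_genes,
    nucleosome_free_regions,
    score_and_rank,
    stitch_enhancers,
    super_cutoff,
)
from .targets import categorize_by_peak_distance, filter_de, welch_t

log = logging.getLogger("corecirc")

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Input paths plus every numeric parameter of the analysis.

    The defaults are the reference settings: consensus support 3 (of 4),
    1000 bp active-gene window, 1638 bp stitching, 2500 bp TSS exclusion,
    motif q < 1e-5, |log2FC| > 0.6 with adjusted p < 1e-10, 10 kb windows
    in 10 bp bins, k = 3 chromatin states, and 10 kb / 400 kb distance
    bins.
    """

    genome_fasta: str = ""
    tss_table: str = ""
    motifs: str = ""
    de_table: str = ""
    peaks: dict = field(default_factory=dict)  # mark -> {line: narrowPeak path}
    fragments: dict = field(default_factory=dict)  # mark -> {line: [bed, total.json]}
    output_dir: str = "results"
    # reference parameter values
    min_support: int = 3
    active_gene_window: int = 1000
    stitch_distance: int = 1638
    tss_exclusion: int = 2500
    q_threshold: float = 1e-5
    lfc_cutoff: float = 0.6
    padj_cutoff: float = 1e-10
    matrix_window: int = 10_000
    matrix_bin: int = 10
    n_states: int = 3
    promoter_max: int = 10_000
    enhancer_max: int = 400_000
    proximal_window: int = 50_000
    read_extension: int = 200
    pseudocount: float = 0.1
    fdr_scope: str = "per-tf"
    se_score_mode: str = "total"
    scale_marks: bool = True
    exclude_self: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config; relative paths resolve against the config's directory."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = Path(path).resolve().parent

        def resolve(p):
            return str(p) if Path(p).is_absolute() else str(base / p)

        for key in ("genome_fasta", "tss_table", "motifs", "de_table", "output_dir"):
            if data.get(key):
                data[key] = resolve(data[key])
        for group in ("peaks", "fragments"):
            for mark in data.get(group, {}):
                for line, entry in data[group][mark].items():
                    if isinstance(entry, (list, tuple)):
                        data[group][mark][line] = [resolve(p) for p in entry]
                    else:
                        data[group][mark][line] = resolve(entry)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def params(self) -> dict:
        skip = {"genome_fasta", "tss_table", "motifs", "de_table", "peaks",
                "fragments", "output_dir"}
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in skip
        }


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_peaksets(cfg: RunConfig, mark: str) -> dict[str, list[Peak]]:
    if mark not in cfg.peaks:
        raise FileNotFoundError(f"no peak files configured for mark {mark!r}")
    out = {}
    for line, path in sorted(cfg.peaks[mark].items()):
        if not Path(path).exists():
            raise FileNotFoundError(f"peak file missing: {path}")
        out[line] = cc_io.read_peaks(path, "narrowPeak")
    return out


def _load_tracks(cfg: RunConfig, mark: str) -> dict[str, FragmentTrack]:
    if mark not in cfg.fragments:
        raise FileNotFoundError(f"no fragment files configured for mark {mark!r}")
    out = {}
    for line, (bed, total) in sorted(cfg.fragments[mark].items()):
        tm = cc_io.read_total_mapped(total)
        log.info("track %s/%s: total_mapped=%d (as supplied)", mark, line, tm)
        out[line] = FragmentTrack.from_bed(bed, tm, label=f"{mark}:{line}")
    return out


def _manifest(cfg: RunConfig, counts: dict, outdir: Path) -> None:
    # keys are the trailing path components so manifests of identical
    # inputs are byte-identical regardless of where the bundle lives
    inputs = {}

    def record(p) -> None:
        if p and Path(p).exists():
            path = Path(p)
            key = (
                f"{path.parent.name}/{path.name}"
                if path.parent.name in ("peaks", "fragments")
                else path.name
            )
            inputs[key] = _sha256(p)

    for p in [cfg.genome_fasta, cfg.tss_table, cfg.motifs, cfg.de_table]:
        record(p)
    for group in (cfg.peaks, cfg.fragments):
        for mark in sorted(group):
            for line in sorted(group[mark]):
                entry = group[mark][line]
                for p in entry if isinstance(entry, (list, tuple)) else [entry]:
                    record(p)
    manifest = {
        "version": __version__,
        "parameters": cfg.params(),
        "inputs": inputs,
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_crc(cfg: RunConfig) -> dict:
    """Super-enhancer calling and core-regulatory-circuitry inference."""
    outdir = Path(cfg.output_dir)
    for p in [cfg.genome_fasta, cfg.tss_table, cfg.motifs]:
        if not Path(p).exists():
            raise FileNotFoundError(f"required input missing: {p}")
    outdir.mkdir(parents=True, exist_ok=True)
    tss = cc_io.read_tss_table(cfg.tss_table)
    k27 = _load_peaksets(cfg, "H3K27ac")
    atac = _load_peaksets(cfg, "ATAC")
    k27_tracks = _load_tracks(cfg, "H3K27ac")
    pooled = pool_tracks(list(k27_tracks.values()), label="H3K27ac:pooled")

    active = active_genes(tss, k27, cfg.active_gene_window)
    log.info("active genes: %d of %d", len(active), len({r.gene_id for r in tss}))
    regions = stitch_enhancers(k27, tss, cfg.stitch_distance, cfg.tss_exclusion)
    log.info("stitched enhancer regions: %d", len(regions))
    ranked = score_and_rank(
        regions, pooled, extension=cfg.read_extension, score_mode=cfg.se_score_mode
    )
    cutoff, flagged = super_cutoff(ranked)
    ses = [r for r in flagged if r.is_super]
    log.info("super-enhancers: %d (cutoff %.4g)", len(ses), cutoff)
    assignments = assign_to_genes(ses, tss, cfg.proximal_window)
    nfrs = nucleosome_free_regions(atac, ses, active, assignments)
    log.info("nucleosome-free regions: %d", len(nfrs))

    genome = Fasta(cfg.genome_fasta)
    motif_db = cc_io.read_jaspar_pfms(cfg.motifs)
    hits = scan_nfrs(
        nfrs,
        genome,
        motif_db,
        q_threshold=cfg.q_threshold,
        fdr_scope=cfg.fdr_scope,
        pseudocount=cfg.pseudocount,
    )
    n_hits = sum(len(v) for v in hits.values())
    log.info("q-passing motif hits: %d", n_hits)

    candidates = candidate_tfs(active, assignments, motif_db, tss)
    log.info("candidate TFs: %d", len(candidates))
    symbols = {r.gene_id: r.gene_symbol for r in tss}
    edges = build_graph(candidates, hits, nfrs, assignments, symbols)
    if cfg.exclude_self:
        edges = [e for e in edges if e.source_tf != e.target_tf]
    nodes = total_degrees(edges, candidates)
    ranking = rank_tfs(nodes)

    # ---- reports ---------------------------------------------------------
    with open(outdir / "superenhancers.tsv", "w") as fh:
        fh.write("se_id\tchrom\tstart\tend\trank\tdensity_rpm_bp\ttotal_signal\tis_super\tgenes\n")
        gene_map: dict[str, list[str]] = {}
        for a in assignments:
            gene_map.setdefault(a.se_id, []).append(f"{a.gene_id}:{a.relation}")
        for r in flagged:
            iv = r.interval
            fh.write(
                f"{r.name}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{r.rank}\t"
                f"{r.density_signal:.6g}\t{r.total_signal:.6g}\t"
                f"{int(r.is_super)}\t{','.join(gene_map.get(r.name, []))}\n"
            )
    cc_io.write_bed(outdir / "nfrs.bed", [n.interval for n in nfrs])
    with open(outdir / "edges.tsv", "w") as fh:
        fh.write("source\ttarget\tn_evidence\n")
        for e in edges:
            fh.write(f"{e.source_tf}\t{e.target_tf}\t{len(e.evidence)}\n")
    with open(outdir / "nodes.tsv", "w") as fh:
        fh.write("tf\tin_degree\tout_degree\ttotal_degree\trank\n")
        for i, n in enumerate(ranking, 1):
            fh.write(
                f"{n.tf_name}\t{len(n.in_set)}\t{len(n.out_set)}\t{n.total_degree}\t{i}\n"
            )
    with open(outdir / "hits.tsv", "w") as fh:
        fh.write("tf\tchrom\tstart\tend\tstrand\tscore\tp\tq\n")
        for tf in sorted(hits):
            for _, h in hits[tf]:
                iv = h.interval
                fh.write(
                    f"{tf}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{h.strand}\t"
                    f"{h.score:.4f}\t{h.p_value:.4g}\t{h.q_value:.4g}\n"
                )
    counts = {
        "active_genes": len(active),
        "stitched_regions": len(regions),
        "super_enhancers": len(ses),
        "nfrs": len(nfrs),
        "motif_hits": n_hits,
        "candidate_tfs": len(candidates),
        "edges": len(edges),
    }
    _manifest(cfg, counts, outdir)
    return {
        "active_genes": active,
        "regions": flagged,
        "cutoff": cutoff,
        "super_enhancers": ses,
        "assignments": assignments,
        "nfrs": nfrs,
        "hits": hits,
        "candidates": candidates,
        "edges": edges,
        "nodes": nodes,
        "ranking": ranking,
        "counts": counts,
    }


def run_targets(cfg: RunConfig) -> dict:
    """Consensus TF peaks, chromatin states, DE categories, Welch report."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tf_peaks = _load_peaksets(cfg, "TF")
    consensus = consensus_peaks(tf_peaks, cfg.min_support)
    log.info("consensus TF peaks: %d", len(consensus))
    marks = [m for m in ("H3K27ac", "H3K4me1", "H3K4me3", "ATAC", "TF") if m in cfg.fragments]
    tracks = {m: _load_tracks(cfg, m) for m in marks}
    matrices = state_matrix(
        consensus, tracks, window=cfg.matrix_window, bin_width=cfg.matrix_bin
    )
    states = cluster_states(matrices, k=cfg.n_states, scale=cfg.scale_marks)

    tss = cc_io.read_tss_table(cfg.tss_table)
    de = cc_io.read_de_table(cfg.de_table)
    if de.empty:
        warnings.warn("empty DE table; category and Welch reports will be empty")
    up, down = filter_de(de, cfg.lfc_cutoff, cfg.padj_cutoff)
    regulated = up | down
    cats = categorize_by_peak_distance(
        tss, consensus, regulated, cfg.promoter_max, cfg.enhancer_max
    )
    lfc_of = dict(zip(de["gene_id"].astype(str), de["log2fc"].astype(float)))
    groups: dict[str, list[float]] = {}
    for c in cats:
        groups.setdefault(c.category, []).append(lfc_of[c.gene_id])
    welch_rows = []
    for a, b in combinations(sorted(groups), 2):
        if len(groups[a]) >= 2 and len(groups[b]) >= 2:
            t, p, df = welch_t(groups[a], groups[b])
            welch_rows.append((a, b, len(groups[a]), len(groups[b]), t, p, df))

    # ---- reports ---------------------------------------------------------
    cc_io.write_bed(
        outdir / "consensus_peaks.bed",
        [Peak(c.interval, c.summit, float(c.support), name=c.name) for c in consensus],
        extra_cols=[(c.support,) for c in consensus],
    )
    with open(outdir / "states.tsv", "w") as fh:
        fh.write("peak_id\tcluster\tmean_H3K27ac\tmean_H3K4me1\tmean_H3K4me3\n")
        for s in states:
            fh.write(
                f"{s.peak_id}\t{s.cluster_label}\t"
                + "\t".join(f"{s.mark_means[m]:.6g}" for m in ("H3K27ac", "H3K4me1", "H3K4me3"))
                + "\n"
            )
    for mark, m in matrices.items():
        m.to_tsv(outdir / f"matrix_{mark}.tsv")
    with open(outdir / "categories.tsv", "w") as fh:
        fh.write("gene_id\tdistance_bp\tcategory\tdirection\n")
        for c in cats:
            d = "inf" if np.isinf(c.distance_bp) else str(int(c.distance_bp))
            direction = "up" if c.gene_id in up else "down"
            fh.write(f"{c.gene_id}\t{d}\t{c.category}\t{direction}\n")
    with open(outdir / "welch.tsv", "w") as fh:
        fh.write("category_a\tcategory_b\tn_a\tn_b\tt\tp\tdf\n")
        for a, b, na, nb, t, p, df in welch_rows:
            fh.write(f"{a}\t{b}\t{na}\t{nb}\t{t:.6g}\t{p:.6g}\t{df:.6g}\n")
    counts = {
        "consensus_peaks": len(consensus),
        "regulated_genes": len(regulated),
        "up": len(up),
        "down": len(down),
    }
    _manifest(cfg, counts, outdir)
    return {
        "consensus": consensus,
        "matrices": matrices,
        "states": states,
        "up": up,
        "down": down,
        "categories": cats,
        "welch": welch_rows,
        "counts": counts,
    }
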