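"""TF-TF regulatory graph construction and total-degree ranking.

A candidate TF is a gene that is active, has an assigned super-enhancer,
and has a matrix in the motif database. A regulatory interaction A -> B is
called when a q-passing occurrence of A's motif lies in a nucleosome-free
region contained in a super-enhancer assigned to B. Each TF's total degree
is the number of unique TFs regulating it plus the number of unique TFs it
regulates; autoregulation (A -> A) counts once in each set. Ranking TFs by
total degree surfaces the core regulatory circuitry's master regulators.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .motifs import MotifHit
from .superenh import GeneAssignment, NucleosomeFreeRegion


@dataclass(frozen=True)
class RegulatoryEdge:
    source_tf: str
    target_tf: str
    evidence: tuple[tuple[MotifHit, str, str], ...]  # (hit, nfr id/str, se_id)


@dataclass(frozen=True)
class TFNode:
    tf_name: str
    in_set: frozenset[str]
    out_set: frozenset[str]

    @property
    def total_degree(self) -> int:
        return len(self.in_set) + len(self.out_set)


def candidate_tfs(
    active_gene_ids: set[str],
    se_assignments: list[GeneAssignment],
    motif_db: dict,
    tss_records=None,
) -> list[str]:
    """TFs that are active, SE-assigned, and present in the motif database.

    Motif names are matched to gene symbols exactly but case-insensitively.
    ``tss_records`` (if given) maps gene_ids in the assignments to gene
    symbols; otherwise gene ids are matched to motif names directly.
    Returns gene symbols sorted alphabetically.
    """
    symbol_of = {}
    if tss_records is not None:
        symbol_of = {r.gene_id: r.gene_symbol for r in tss_records}
    motif_names = {name.upper(): name for name in motif_db}
    assigned = {a.gene_id for a in se_assignments}
    out = set()
    for gid in active_gene_ids & assigned:
        symbol = symbol_of.get(gid, gid)
        if symbol.upper() in motif_names:
            out.add(symbol)
    return sorted(out)


def build_graph(
    candidates: list[str],
    nfr_hits: dict[str, list[tuple[int, MotifHit]]],
    nfrs: list[NucleosomeFreeRegion],
    se_assignments: list[GeneAssignment],
    gene_symbols: dict[str, str] | None = None,
) -> list[RegulatoryEdge]:
    """Edges A -> B: a hit of A's motif in an NFR of an SE assigned to B.

    ``nfr_hits`` is the output of ``scan_nfrs`` (nfr index, hit). One edge
    is emitted per ordered TF pair, with all supporting (hit, NFR, SE)
    triples aggregated as evidence.
    """
    cand = {c.upper(): c for c in candidates}
    se_targets: dict[str, set[str]] = {}
    for a in se_assignments:
        symbol = gene_symbols.get(a.gene_id, a.gene_id) if gene_symbols else a.gene_id
        if symbol.upper() in cand:
            se_targets.setdefault(a.se_id, set()).add(cand[symbol.upper()])
    evidence: dict[tuple[str, str], list] = {}
    for tf, items in sorted(nfr_hits.items()):
        if tf.upper() not in cand:
            continue
        source = cand[tf.upper()]
        for idx, hit in items:
            nfr = nfrs[idx]
            if not nfr.se_id:
                raise ValueError(f"hit {hit.interval} in NFR not mapped to any SE")
            for target in sorted(se_targets.get(nfr.se_id, ())):
                evidence.setdefault((source, target), []).append(
                    (hit, str(nfr.interval), nfr.se_id)
                )
    return [
        RegulatoryEdge(s, t, tuple(ev))
        for (s, t), ev in sorted(evidence.items())
    ]


def total_degrees(
    edges: list[RegulatoryEdge], candidates: list[str]
) -> list[TFNode]:
    """Per-candidate in/out regulator sets and total degree.

    A self-loop contributes the TF to both its in-set and its out-set
    (counted once in each).
    """
    in_sets: dict[str, set[str]] = {c: set() for c in candidates}
    out_sets: dict[str, set[str]] = {c: set() for c in candidates}
    for e in edges:
        out_sets.setdefault(e.source_tf, set()).add(e.target_tf)
        in_sets.setdefault(e.target_tf, set()).add(e.source_tf)
    names = sorted(set(candidates) | set(in_sets) | set(out_sets))
    return [
        TFNode(n, frozenset(in_sets.get(n, ())), frozenset(out_sets.get(n, ())))
        for n in names
    ]


def rank_tfs(nodes: list[TFNode]) -> list[TFNode]:
    """Descending total degree; ties by out-degree descending, then name."""
    return sorted(
        nodes, key=lambda n: (-n.total_degree, -len(n.out_set), n.tf_name)
    )


def to_networkx(edges: list[RegulatoryEdge]) -> nx.DiGraph:
    """Export the regulatory graph as a networkx DiGraph."""
    g = nx.DiGraph()
    for e in edges:
        g.add_edge(e.source_tf, e.target_tf, n_evidence=len(e.evidence))
    return g
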