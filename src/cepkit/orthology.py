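"""Deterministic multi-species orthology by clustering reciprocal best hits.

Cross-organism similarity is scored by local (Smith-Waterman) alignment
with the same JTT-derived matrix used for global alignment, reported in
bits. A reciprocal-best-hit (RBH) graph connects genes in different
organisms that are each other's *unique* best hit; ties produce no edge.

The RBH graph is then pruned to cliques: edges are scanned in ascending
weight order and the first edge whose two endpoints do not share the same
set of orthologs (neighbor sets, excluding each other) is deleted; the
scan restarts until every surviving edge is consistent. The surviving
connected components are cliques; components of at least
``min_group_size`` members are emitted as orthologous groups. Fixed
tie-breaks make the whole procedure deterministic and independent of
input order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .evolution_stats import _make_aligner

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-9


@dataclass
class SimilarityMatrix:
    """Directional bit-score similarities between genes of different organisms."""

    organism_of: dict[str, str]
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def score(self, a: str, b: str) -> float:
        return self.scores[(a, b)]


@dataclass
class OrthoGroup:
    group_id: int
    members: list[str]


def similarity_scores(
    prepropeptides: Mapping[str, Mapping[str, str]],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> SimilarityMatrix:
    """Local-alignment bit scores for all cross-organism gene pairs.

    ``prepropeptides`` maps organism -> {gene_id: AA sequence}. Scores are
    Smith-Waterman with the JTT half-bit log-odds matrix, divided by 2 to
    give bits. The scorer is symmetric; both directions are recorded to
    preserve the directional contract. Organisms with zero genes are
    excluded with a warning.
    """
    organisms = {org: genes for org, genes in prepropeptides.items() if genes}
    for org in set(prepropeptides) - set(organisms):
        logger.warning("organism %s has no genes; excluded", org)
    if len(organisms) < 2:
        raise ValueError("need at least two organisms with genes")
    organism_of = {
        gid: org for org, genes in organisms.items() for gid in genes
    }
    if len(organism_of) != sum(len(g) for g in organisms.values()):
        raise ValueError("gene ids must be globally unique")
    aligner = _make_aligner("local", gap_open, gap_extend)
    matrix = SimilarityMatrix(organism_of=organism_of)
    for org_a, org_b in itertools.combinations(sorted(organisms), 2):
        for ga, seq_a in organisms[org_a].items():
            for gb, seq_b in organisms[org_b].items():
                bits = aligner.score(seq_a, seq_b) / 2.0
                matrix.scores[(ga, gb)] = bits
                matrix.scores[(gb, ga)] = bits
    return matrix


def load_scores_table(path, organism_of: Mapping[str, str]) -> SimilarityMatrix:
    """Load externally computed scores from a 3-column TSV.

    Columns: query gene id, subject gene id, bit score (tool-agnostic; the
    tabular output of any local search tool works). Within-organism rows
    and self hits are ignored.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["qseqid", "sseqid", "bitscore"],
    )
    matrix = SimilarityMatrix(organism_of=dict(organism_of))
    for row in df.itertuples(index=False):
        a, b = str(row.qseqid), str(row.sseqid)
        if a == b or organism_of[a] == organism_of[b]:
            continue
        matrix.scores[(a, b)] = float(row.bitscore)
    return matrix


def build_rbh_graph(matrix: SimilarityMatrix) -> nx.Graph:
    """Reciprocal-best-hit graph; edge weight = min of the two directions.

    ``(a, b)`` is an edge iff b is a's unique best hit within b's organism
    and vice versa. A tie for best hit (within score tolerance) yields no
    edge, preserving determinism.
    """
    hits: dict[tuple[str, str], list[tuple[float, str]]] = {}
    for (a, b), s in matrix.scores.items():
        hits.setdefault((a, matrix.organism_of[b]), []).append((s, b))
    best: dict[tuple[str, str], tuple[str, float] | None] = {}
    for key, lst in hits.items():
        s_max, b_max = max(lst)
        tied = [b for s, b in lst if abs(s - s_max) <= _TIE_TOL]
        if len(tied) > 1:
            logger.debug("tie for best hit of %s in %s: %s", key[0], key[1], tied)
            best[key] = None  # tie: no unique best hit in that organism
        else:
            best[key] = (b_max, s_max)
    graph = nx.Graph()
    graph.add_nodes_from(matrix.organism_of)
    for (a, org_b), hit in best.items():
        if hit is None:
            continue
        b, s_ab = hit
        back = best.get((b, matrix.organism_of[a]))
        if back is not None and back[0] == a and not graph.has_edge(a, b):
            weight = min(s_ab, back[1])
            graph.add_edge(a, b, weight=weight)
    return graph


def _sorted_edges(graph: nx.Graph) -> list[tuple[str, str, float]]:
    edges = [
        (min(u, v), max(u, v), d["weight"]) for u, v, d in graph.edges(data=True)
    ]
    return sorted(edges, key=lambda e: (e[2], e[0], e[1]))


def prune_to_cliques(
    graph: nx.Graph, min_group_size: int = 4
) -> list[OrthoGroup]:
    """Prune inconsistent RBH edges and emit clique groups.

    Edges are scanned in ascending (weight, gene-id pair) order; the first
    edge whose endpoints have unequal neighbor sets (each excluding the
    other endpoint) is deleted and the scan restarts. On termination every
    component is a clique. Components of >= ``min_group_size`` members are
    returned, labelled sequentially by descending size then lexicographic
    member order.
    """
    g = graph.copy()
    while True:
        for u, v, _w in _sorted_edges(g):
            if set(g[u]) - {v} != set(g[v]) - {u}:
                g.remove_edge(u, v)
                break
        else:
            break
    groups = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        n = len(members)
        assert g.subgraph(comp).number_of_edges() == n * (n - 1) // 2, (
            "pruned component is not a clique"
        )
        if n >= min_group_size:
            groups.append(members)
    groups.sort(key=lambda m: (-len(m), m))
    return [OrthoGroup(group_id=i + 1, members=m) for i, m in enumerate(groups)]


def groups_table(
    groups: Iterable[OrthoGroup], organism_of: Mapping[str, str]
) -> pd.DataFrame:
    rows = [
        {
            "group_id": grp.group_id,
            "gene_id": gid,
            "organism": organism_of.get(gid, ""),
        }
        for grp in groups
        for gid in grp.members
    ]
    return pd.DataFrame(rows, columns=["group_id", "gene_id", "organism"])
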