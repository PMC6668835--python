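"""Genetic-organisation (component contiguity) graphs.

For the systems of one type, nodes are component names and an edge joins two
components found encoded contiguously (adjacent gene ranks on the same
replicon; the origin of circular replicons is wrap-adjacent).  Pairs are
ordered along the gene order — component u immediately followed by
component v — and contiguity is counted at most once per system per ordered
pair, so both normalisations stay within [0, 1]:

* ``width_weight`` — contiguous systems / systems containing the rarer of
  the two components (edge width in the organisation figures);
* ``color_weight`` — contiguous systems / all systems of the type (edge
  colour).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

from .detection import DetectedSystem
from .models_io import GeneTable

__all__ = ["AdjacencyEdge", "AdjacencyGraph", "build_adjacency"]


@dataclass(frozen=True)
class AdjacencyEdge:
    component_u: str
    component_v: str
    contig_count: int
    occ_u: int
    occ_v: int
    n_systems: int

    @property
    def width_weight(self) -> float:
        return self.contig_count / min(self.occ_u, self.occ_v)

    @property
    def color_weight(self) -> float:
        return self.contig_count / self.n_systems


@dataclass
class AdjacencyGraph:
    nodes: list[str]
    edges: list[AdjacencyEdge]
    n_systems: int

    def edge(self, u: str, v: str) -> AdjacencyEdge | None:
        for e in self.edges:
            if (e.component_u, e.component_v) == (u, v):
                return e
        return None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.component_u, e.component_v,
                       contig_count=e.contig_count,
                       width_weight=e.width_weight,
                       color_weight=e.color_weight)
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = [(e.component_u, e.component_v, e.contig_count, e.occ_u,
                 e.occ_v, e.n_systems, e.width_weight, e.color_weight)
                for e in self.edges]
        return pd.DataFrame(rows, columns=[
            "component_u", "component_v", "contig_count", "occ_u", "occ_v",
            "n_systems", "width_weight", "color_weight"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _adjacent_pairs(system: DetectedSystem,
                    gene_table: GeneTable | None) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    for locus in system.loci:
        by_pos = {pos: comp for pos, _, comp in locus.members}
        size = None
        if gene_table is not None:
            info = gene_table.replicon_info(system.genome_id, locus.replicon_id)
            size = info.size if info.topology == "circular" else None
        for pos, comp in by_pos.items():
            nxt = pos + 1
            if size is not None:
                nxt %= size
            other = by_pos.get(nxt)
            if other is not None and other != comp:
                pairs.add((comp, other))
    return pairs


def build_adjacency(systems: Iterable[DetectedSystem],
                    gene_table: GeneTable | None = None) -> AdjacencyGraph:
    """Contiguity graph over the member components of ``systems``.

    ``gene_table`` enables wrap-adjacency on circular replicons; without it
    only consecutive gene ranks count as adjacent.  Gene orientation
    (strand) is ignored; the pair order follows increasing gene rank.
    """
    systems = sorted(systems, key=lambda s: s.system_id)
    n_systems = len(systems)
    occ: dict[str, int] = {}
    contig: dict[tuple[str, str], int] = {}
    nodes: set[str] = set()
    for system in systems:
        comps = system.components()
        nodes |= comps
        for c in comps:
            occ[c] = occ.get(c, 0) + 1
        for pair in _adjacent_pairs(system, gene_table):
            contig[pair] = contig.get(pair, 0) + 1
    edges = [AdjacencyEdge(u, v, c, occ[u], occ[v], n_systems)
             for (u, v), c in sorted(contig.items())]
    return AdjacencyGraph(sorted(nodes), edges, n_systems)
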