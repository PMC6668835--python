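"""Guilt-by-association analysis of system-flanking genes.

Genes found systematically next to a type of system may be unrecognised
components.  The analysis takes, for each detected locus, the genes within
``w`` positions of the locus bounds (default 10), excluding system members
and any gene matched by a model profile; clusters the flanking genes into
families by single-linkage on sequence-identity edges (transitive clustering
at a 50% identity threshold, SiLiX-style); and tests each family's
association with each system type with a Fisher exact test on the 2x2
presence table (type vs all other types), Bonferroni-corrected over all
(family, type) tests.  An association is kept when the family is *enriched*
(presence rate in the focal type above the rate elsewhere) and the corrected
p-value is below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
from scipy import stats

from .detection import DetectedSystem
from .models_io import ComponentHit, GeneTable

__all__ = [
    "NeighborhoodWindow",
    "GeneFamily",
    "EnrichmentResult",
    "extract_windows",
    "cluster_families",
    "family_presence",
    "test_association",
]

DEFAULT_WINDOW = 10
DEFAULT_IDENTITY = 50.0
DEFAULT_ALPHA = 0.05


@dataclass
class NeighborhoodWindow:
    system_id: str
    replicon_id: str
    window_genes: frozenset[str]
    w: int


@dataclass
class GeneFamily:
    family_id: str
    members: frozenset[str]
    #: systems whose windows contain >= 1 member (binary presence)
    systems: frozenset[str] = frozenset()


@dataclass
class EnrichmentResult:
    family_id: str
    system_type: str
    table: tuple[tuple[int, int], tuple[int, int]]
    raw_p: float
    corrected_p: float
    enriched: bool
    kept: bool


def _window_positions(first: int, last: int, w: int, size: int,
                      circular: bool, wraps: bool) -> set[int]:
    if circular:
        if wraps:
            # locus runs first..size-1,0..last
            length = (last - first) % size + 1
        else:
            length = last - first + 1
        if length + 2 * w >= size:
            return set(range(size))
        return {(first - d) % size for d in range(1, w + 1)} | \
               {(last + d) % size for d in range(1, w + 1)} | \
               ({(first + i) % size for i in range(length)})
    lo = max(0, first - w)
    hi = min(size - 1, last + w)
    return set(range(lo, hi + 1))


def extract_windows(systems: Iterable[DetectedSystem],
                    gene_table: GeneTable,
                    resolved: Mapping[str, ComponentHit],
                    w: int = DEFAULT_WINDOW) -> list[NeighborhoodWindow]:
    """One window per locus: genes within ``w`` of the locus bounds,
    excluding system members and profile-matched genes.

    Windows are clamped at the ends of linear replicons and wrap across the
    origin of circular ones.
    """
    if w <= 0:
        raise ValueError("window size must be positive")
    out = []
    for system in sorted(systems, key=lambda s: s.system_id):
        member_genes = system.gene_ids()
        for locus in system.loci:
            info = gene_table.replicon_info(system.genome_id, locus.replicon_id)
            first, last = locus.span
            positions = _window_positions(first, last, w, info.size,
                                          info.topology == "circular",
                                          locus.wraps)
            genes = gene_table.replicon_genes(system.genome_id, locus.replicon_id)
            window = frozenset(
                g.gene_id for g in genes
                if g.position in positions
                and g.gene_id not in member_genes
                and g.gene_id not in resolved)
            out.append(NeighborhoodWindow(system.system_id, locus.replicon_id,
                                          window, w))
    return out


def cluster_families(edges: Iterable[tuple[str, str, float]],
                     identity_threshold: float = DEFAULT_IDENTITY,
                     genes: Iterable[str] = ()) -> list[GeneFamily]:
    """Single-linkage transitive clustering of similarity edges.

    Families are the connected components of the graph of edges with
    identity >= threshold; genes listed in ``genes`` but absent from any
    retained edge form singleton families.  Family ids are assigned by
    smallest member label.
    """
    g = nx.Graph()
    g.add_nodes_from(genes)
    for a, b, ident in edges:
        if not (0 <= ident <= 100):
            raise ValueError(f"identity {ident} outside [0, 100]")
        g.add_nodes_from((a, b))
        if ident >= identity_threshold:
            g.add_edge(a, b)
    comps = sorted(nx.connected_components(g), key=min)
    return [GeneFamily(family_id=f"fam_{min(c)}", members=frozenset(c))
            for c in comps]


def family_presence(families: Iterable[GeneFamily],
                    windows: Iterable[NeighborhoodWindow],
                    min_systems: int = 2) -> list[GeneFamily]:
    """Attach binary per-system presence; keep families seen in >= 2 systems."""
    gene_systems: dict[str, set[str]] = {}
    for win in windows:
        for gid in win.window_genes:
            gene_systems.setdefault(gid, set()).add(win.system_id)
    out = []
    for fam in families:
        systems = set()
        for gid in fam.members:
            systems |= gene_systems.get(gid, set())
        if len(systems) >= min_systems:
            out.append(GeneFamily(fam.family_id, fam.members, frozenset(systems)))
    return out


def test_association(families: Iterable[GeneFamily],
                     system_types: Mapping[str, str],
                     alpha: float = DEFAULT_ALPHA,
                     alternative: str = "two-sided",
                     ) -> list[EnrichmentResult]:
    """Fisher exact test of each family against each system type.

    The 2x2 table counts systems: [[present & type, present & other],
    [absent & type, absent & other]].  The test is two-sided by default
    ("one-sided" uses the 'greater' alternative); the Bonferroni factor m is
    the number of (family, type) tests actually performed; a result is kept
    when enriched (presence rate higher in the focal type) and the corrected
    p-value is below ``alpha``.
    """
    if alternative not in ("two-sided", "one-sided"):
        raise ValueError("alternative must be 'two-sided' or 'one-sided'")
    families = sorted(families, key=lambda f: f.family_id)
    all_systems = set(system_types)
    types = sorted({t for t in system_types.values()})
    types = [t for t in types
             if sum(1 for s in all_systems if system_types[s] == t) > 0]
    if len(types) < 2:
        raise ValueError("need at least two system types")
    m = len(families) * len(types)
    out = []
    for fam in families:
        present = fam.systems & all_systems
        for t in types:
            in_type = {s for s in all_systems if system_types[s] == t}
            a = len(present & in_type)
            b = len(present - in_type)
            c = len(in_type) - a
            d = len(all_systems - in_type) - b
            scipy_alt = "two-sided" if alternative == "two-sided" else "greater"
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative=scipy_alt)
            rate_type = a / len(in_type)
            rate_other = b / (len(all_systems) - len(in_type))
            enriched = rate_type > rate_other
            corrected = min(1.0, p * m)
            out.append(EnrichmentResult(
                family_id=fam.family_id, system_type=t,
                table=((a, b), (c, d)), raw_p=float(p),
                corrected_p=float(corrected), enriched=enriched,
                kept=enriched and corrected < alpha))
    return out
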