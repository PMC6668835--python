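"""Profile-profile similarity graph and role groups.

Edges come from pairwise profile-profile alignments (HHsearch-like): each
ordered pair carries a p-value in both directions.  An edge is retained only
when *both* directional p-values fall strictly below the significance level
(reciprocal similarity, default alpha = 0.001).  Connected components of the
resulting undirected graph group homologous profiles; components seeded with
a known role (ATPase, IM platform, major pilin, secretin, prepilin
peptidase) label the role groups consumed by the generic detection model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "ProfileEdge",
    "RoleComponentSet",
    "build_graph",
    "components_and_roles",
    "role_sets_for_generic",
    "read_edge_table",
    "write_edge_table",
    "write_graphml",
]

DEFAULT_ALPHA = 1e-3


@dataclass(frozen=True)
class ProfileEdge:
    profile_a: str
    profile_b: str
    p_value_ab: float
    p_value_ba: float

    def __post_init__(self):
        if self.profile_a == self.profile_b:
            raise ValueError(f"self-edge on {self.profile_a!r}")
        for p in (self.p_value_ab, self.p_value_ba):
            if not (0 < p <= 1):
                raise ValueError(f"p-value {p} outside (0, 1]")


@dataclass(frozen=True)
class RoleComponentSet:
    role: str
    members: frozenset[str]
    conflict: bool = False


def build_graph(edges: Iterable[ProfileEdge],
                profiles: Iterable[str] = (),
                alpha: float = DEFAULT_ALPHA) -> nx.Graph:
    """Undirected graph of reciprocally significant profile similarities.

    ``profiles`` adds registered profiles as nodes even when isolated.  An
    edge survives iff both directional p-values are strictly below ``alpha``.
    """
    g = nx.Graph()
    g.add_nodes_from(profiles)
    for e in edges:
        g.add_nodes_from((e.profile_a, e.profile_b))
        if e.p_value_ab < alpha and e.p_value_ba < alpha:
            g.add_edge(e.profile_a, e.profile_b,
                       p_value_ab=e.p_value_ab, p_value_ba=e.p_value_ba)
    return g


def components_and_roles(graph: nx.Graph,
                         seeds: Mapping[str, str]) -> list[RoleComponentSet]:
    """Label connected components with the roles of their seeded members.

    A component containing seeds of several roles is flagged as a conflict
    (role names joined with '+'); components without any seed are labelled
    ``unknown``.  Output is sorted by (role, smallest member) and stable
    under edge-list permutation.
    """
    for prof in seeds:
        if prof not in graph:
            raise ValueError(f"seed profile {prof!r} not in graph")
    out = []
    for comp in nx.connected_components(graph):
        roles = sorted({seeds[p] for p in comp if p in seeds})
        if not roles:
            out.append(RoleComponentSet("unknown", frozenset(comp)))
        elif len(roles) == 1:
            out.append(RoleComponentSet(roles[0], frozenset(comp)))
        else:
            out.append(RoleComponentSet("+".join(roles), frozenset(comp), conflict=True))
    out.sort(key=lambda rs: (rs.role, min(rs.members)))
    return out


def role_sets_for_generic(role_components: Iterable[RoleComponentSet],
                          ) -> dict[str, set[str]]:
    """Merge role component sets into role -> profile-set mapping.

    Conflicted and unknown components are excluded; if one role labels
    several components (e.g., two disconnected pilin families), their
    members are unioned.
    """
    out: dict[str, set[str]] = {}
    for rs in role_components:
        if rs.conflict or rs.role == "unknown":
            continue
        out.setdefault(rs.role, set()).update(rs.members)
    return out


def read_edge_table(path) -> list[ProfileEdge]:
    df = pd.read_csv(path, sep="\t")
    need = ["profile_a", "profile_b", "p_value_ab", "p_value_ba"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"edge table missing column(s) {missing}")
    return [ProfileEdge(r.profile_a, r.profile_b, float(r.p_value_ab),
                        float(r.p_value_ba))
            for r in df.itertuples(index=False)]


def write_edge_table(edges: Iterable[ProfileEdge], path) -> None:
    pd.DataFrame([e.__dict__ for e in edges]).to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
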