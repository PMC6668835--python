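"""Redundancy reduction and paralogue dereplication.

Thousands of detected systems are far too many (and too similar) for
phylogenetic inference.  The reduction works on patristic distance matrices
of the core component families (ATPase, IM platform, major pilin, ...):

1. per component, the protein-level matrix is collapsed to a system-level
   matrix, taking the *minimum* distance over paralogous copies;
2. each system-level matrix is normalised by the total branch length of its
   component tree (components evolve at different rates), and the normalised
   matrices are averaged entrywise over the components shared by each pair
   of systems;
3. a BioNJ tree of the averaged matrix, rooted at the midpoint, is cut into
   a target number of groups, and one representative is picked per group —
   experimentally validated systems first, then systems with the fewest
   paralogous components, with a lexicographic tie-break;
4. remaining paralogues inside each kept system are dereplicated: for each
   multi-copy component, the nearest system carrying a single copy of it is
   located (on the ATPase tree when the focal ATPase is single-copy,
   otherwise on the IM-platform tree) and the copy closest to that
   neighbour's single copy is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .tree_ops import DistanceMatrix, bionj, find_cut_for_group_count, midpoint_root

__all__ = [
    "SystemComponentMap",
    "FusedDistance",
    "SelectionResult",
    "system_distance",
    "fuse_matrices",
    "filter_complex_systems",
    "select_representatives",
    "dereplicate",
]

ATPASE = "atpase"
IM_PLATFORM = "im_platform"


@dataclass
class SystemComponentMap:
    """Protein labels of one system in each component tree, plus metadata."""

    system_id: str
    #: component role -> protein leaf labels of this system in that tree
    components: dict[str, list[str]]
    validated: bool = False
    type: str = "generic"
    #: source system-types of the profiles that matched each component
    #: (used to spot chimeric generic systems)
    profile_types: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n_paralogues(self) -> int:
        return sum(1 for labels in self.components.values() if len(labels) > 1)

    def copies(self, role: str) -> list[str]:
        return self.components.get(role, [])


def system_distance(component_matrix: DistanceMatrix,
                    systems: Iterable[SystemComponentMap],
                    role: str) -> DistanceMatrix:
    """Collapse a protein-level matrix to systems, min over paralogue pairs.

    Systems without any protein in this component are absent from the
    output.
    """
    members = [(s.system_id, s.copies(role)) for s in systems if s.copies(role)]
    for sid, labels in members:
        for lab in labels:
            if lab not in component_matrix.labels:
                raise ValueError(
                    f"system {sid!r}: label {lab!r} missing from the {role} matrix")
    ids = [sid for sid, _ in members]
    n = len(ids)
    vals = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = min(component_matrix.get(x, y)
                    for x in members[a][1] for y in members[b][1])
            vals[a, b] = vals[b, a] = d
    return DistanceMatrix(ids, vals)


@dataclass
class FusedDistance:
    averaged: DistanceMatrix
    #: (system, system) pairs that share no component (NaN in ``averaged``
    #: would be invalid, so these pairs surface here and through ``strict``)
    missing_pairs: list[tuple[str, str]]

    def strict(self) -> DistanceMatrix:
        if self.missing_pairs:
            raise ValueError(
                f"{len(self.missing_pairs)} system pair(s) share no component, "
                f"e.g. {self.missing_pairs[0]}")
        return self.averaged


def fuse_matrices(matrices: Mapping[str, DistanceMatrix],
                  tree_lengths: Mapping[str, float]) -> FusedDistance:
    """Average per-component system matrices, normalised by tree length.

    Averaging runs over the components in which *both* systems of a pair
    appear.  Systems present in no matrix raise; pairs sharing no component
    are reported in :attr:`FusedDistance.missing_pairs` (their averaged
    entry is 0 and must not be consumed — use :meth:`FusedDistance.strict`).
    """
    if not matrices:
        raise ValueError("need at least one component matrix")
    for role in matrices:
        if role not in tree_lengths:
            raise ValueError(f"missing tree length for component {role!r}")
        if not tree_lengths[role] > 0:
            raise ValueError(f"tree length for {role!r} must be positive")
    ids = sorted(set().union(*(m.labels for m in matrices.values())))
    n = len(ids)
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for role, m in sorted(matrices.items()):
        norm = m.values / tree_lengths[role]
        idx = [ids.index(l) for l in m.labels]
        for a in range(len(m.labels)):
            for b in range(len(m.labels)):
                num[idx[a], idx[b]] += norm[a, b]
                cnt[idx[a], idx[b]] += 1
    missing = []
    vals = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            if cnt[a, b] == 0:
                missing.append((ids[a], ids[b]))
            else:
                vals[a, b] = vals[b, a] = num[a, b] / cnt[a, b]
    return FusedDistance(DistanceMatrix(ids, vals), missing)


#: the components whose joint duplication marks a "complex" system
CORE_ROLES = (ATPASE, IM_PLATFORM, "major_pilin")


def filter_complex_systems(systems: Iterable[SystemComponentMap],
                           core_roles: tuple[str, ...] = CORE_ROLES,
                           ) -> tuple[list[SystemComponentMap], list[SystemComponentMap]]:
    """Drop systems with paralogues of every core component, and chimeric
    generic systems whose components match profiles from several types."""
    kept, removed = [], []
    for s in systems:
        present = [r for r in core_roles if s.copies(r)]
        all_dup = bool(present) and all(len(s.copies(r)) >= 2 for r in present)
        chimeric = False
        if s.type == "generic" and s.profile_types:
            sources = set().union(*s.profile_types.values())
            chimeric = len(sources) >= 2
        (removed if all_dup or chimeric else kept).append(s)
    return kept, removed


@dataclass
class SelectionResult:
    representatives: list[str]
    groups: list[frozenset[str]]
    #: representative chosen for each group (parallel to ``groups``)
    by_group: list[str]
    height: float
    within_target: bool


def _pick_representative(group: Iterable[str],
                         meta: Mapping[str, SystemComponentMap]) -> str:
    """Validated first; then fewest paralogous components; then smallest id."""
    def key(sid):
        m = meta[sid]
        return (not m.validated, m.n_paralogues, sid)
    return min(group, key=key)


def select_representatives(fused: DistanceMatrix,
                           systems: Iterable[SystemComponentMap],
                           gmin: int, gmax: int,
                           min_per_type: int | None = None) -> SelectionResult:
    """Group systems on the fused-distance BioNJ tree and pick one per group.

    When ``min_per_type`` is set, any type ending up with fewer selected
    systems is re-cut on its own subtree (all systems of that type) to
    reach the minimum where attainable.
    """
    meta = {s.system_id: s for s in systems}
    unknown = set(fused.labels) - set(meta)
    if unknown:
        raise ValueError(f"no metadata for system(s) {sorted(unknown)}")
    if gmin > len(fused):
        raise ValueError(f"gmin {gmin} exceeds the {len(fused)} systems")
    tree = midpoint_root(bionj(fused))
    cut = find_cut_for_group_count(tree, gmin, gmax)
    groups = list(cut.groups)

    if min_per_type is not None:
        by_type: dict[str, list[frozenset[str]]] = {}
        for g in groups:
            t = meta[next(iter(g))].type  # groups may mix types; majority
            counts: dict[str, int] = {}
            for sid in g:
                counts[meta[sid].type] = counts.get(meta[sid].type, 0) + 1
            t = max(sorted(counts), key=lambda k: counts[k])
            by_type.setdefault(t, []).append(g)
        for t, tgroups in sorted(by_type.items()):
            members = sorted(set().union(*tgroups))
            if len(tgroups) >= min_per_type or len(members) < 2:
                continue
            target = min(min_per_type, len(members))
            from .tree_ops import prune_to_leaves
            subtree = prune_to_leaves(tree, members)
            sub = find_cut_for_group_count(subtree, target, len(members))
            groups = [g for g in groups if g not in tgroups] + list(sub.groups)

    groups.sort(key=min)
    by_group = [_pick_representative(g, meta) for g in groups]
    return SelectionResult(sorted(by_group), groups, by_group,
                           cut.height, cut.within_target)


def dereplicate(focal: SystemComponentMap,
                component_matrices: Mapping[str, DistanceMatrix],
                systems: Iterable[SystemComponentMap]) -> dict[str, str]:
    """Reduce a system to one protein label per component.

    For each multi-copy component, the nearest system (by min-rule distance
    on the reference tree: ATPase if the focal ATPase is single-copy, else
    IM platform) that carries exactly one copy of the component donates its
    copy as an anchor; the focal copy closest to the anchor is kept.
    """
    others = [s for s in systems if s.system_id != focal.system_id]
    ref_role = ATPASE if len(focal.copies(ATPASE)) == 1 else IM_PLATFORM
    if not focal.copies(ref_role):
        raise ValueError(
            f"system {focal.system_id!r} has no {ref_role} to anchor on")
    ref = component_matrices[ref_role]

    def ref_distance(other: SystemComponentMap) -> float:
        return min(ref.get(x, y) for x in focal.copies(ref_role)
                   for y in other.copies(ref_role))

    out: dict[str, str] = {}
    for role in sorted(focal.components):
        copies = focal.copies(role)
        if len(copies) == 1:
            out[role] = copies[0]
            continue
        candidates = [s for s in others
                      if len(s.copies(role)) == 1 and s.copies(ref_role)]
        if not candidates:
            raise ValueError(
                f"no single-copy system available for component {role!r}")
        nearest = min(candidates, key=lambda s: (ref_distance(s), s.system_id))
        anchor = nearest.copies(role)[0]
        m = component_matrices[role]
        out[role] = min(sorted(copies), key=lambda c: (m.get(c, anchor), c))
    return out
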