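"""Phylogenetic primitives: BioNJ, rooting, patristic distances, tree cutting.

Trees are :class:`dendropy.Tree` objects (newick is the single serialisation
format).  The module provides:

* :func:`bionj` — distance-based tree construction with Gascuel's
  variance-weighted branch estimates (plain neighbour joining available as a
  flagged fallback; both agree exactly on additive matrices);
* :func:`midpoint_root` — root at the midpoint of the longest leaf-to-leaf
  path, with a deterministic lexicographic tie rule;
* :func:`patristic_matrix` — sum of branch lengths along leaf-to-leaf paths;
* :func:`cut_tree` / :func:`find_cut_for_group_count` — partition leaves by
  a height threshold; the height of a node is the maximum patristic distance
  to its descendant leaves (the trees handled here are not ultrametric);
* :func:`assign_types_by_clade` — propagate type labels to "generic" leaves
  inside pure, experimentally anchored clades;
* :func:`prune_to_leaves` — induced subtree preserving patristic distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "CutResult",
    "bionj",
    "neighbor_joining",
    "midpoint_root",
    "patristic_matrix",
    "node_heights",
    "cut_tree",
    "find_cut_for_group_count",
    "assign_types_by_clade",
    "prune_to_leaves",
    "read_newick",
    "write_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with ordered unique labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("negative off-diagonal entries")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels: Iterable[str]) -> "DistanceMatrix":
        labels = list(labels)
        idx = [self._index[l] for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def total(self) -> float:
        return float(self.values.sum() / 2.0)

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != labels:
            raise ValueError("row and column labels differ")
        return cls(labels, df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path, sep="\t")


def _leaf_node(label: str, tns: dendropy.TaxonNamespace) -> dendropy.Node:
    node = dendropy.Node()
    node.taxon = tns.require_taxon(label=label)
    return node


def _build_distance_tree(dm: DistanceMatrix, variance_weighted: bool) -> dendropy.Tree:
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 labels")
    if n == 2:
        tns = dendropy.TaxonNamespace()
        seed = dendropy.Node()
        for lab in dm.labels:
            child = _leaf_node(lab, tns)
            child.edge.length = dm.values[0, 1] / 2.0
            seed.add_child(child)
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
        tree.is_rooted = False
        return tree

    tns = dendropy.TaxonNamespace()
    cap = 2 * n
    D = np.zeros((cap, cap))
    V = np.zeros((cap, cap))
    D[:n, :n] = dm.values
    V[:n, :n] = dm.values
    nodes: dict[int, dendropy.Node] = {i: _leaf_node(lab, tns)
                                       for i, lab in enumerate(dm.labels)}
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        r = len(active)
        S = {i: sum(D[i, k] for k in active) for i in active}
        best = None
        best_q = np.inf
        for a, i in enumerate(active):
            for j in active[a + 1:]:
                q = (r - 2) * D[i, j] - S[i] - S[j]
                if q < best_q:
                    best_q = q
                    best = (i, j)
        i, j = best
        d_ij = D[i, j]
        bi = 0.5 * d_ij + (S[i] - S[j]) / (2 * (r - 2))
        bj = d_ij - bi
        # standard NJ practice: clamp negative estimates, moving length to
        # the sibling branch so the pair distance is conserved
        if bi < 0:
            bi, bj = 0.0, d_ij
        elif bj < 0:
            bi, bj = d_ij, 0.0
        lam = 0.5
        if variance_weighted and V[i, j] > 1e-12 and r > 3:
            s = sum(V[j, k] - V[i, k] for k in active if k not in (i, j))
            lam = 0.5 + s / (2 * (r - 2) * V[i, j])
            lam = min(1.0, max(0.0, lam))
        u = dendropy.Node()
        nodes[i].edge.length = bi
        nodes[j].edge.length = bj
        u.add_child(nodes[i])
        u.add_child(nodes[j])
        nodes[nxt] = u
        for k in active:
            if k in (i, j):
                continue
            D[nxt, k] = D[k, nxt] = lam * (D[i, k] - bi) + (1 - lam) * (D[j, k] - bj)
            V[nxt, k] = V[k, nxt] = (lam * V[i, k] + (1 - lam) * V[j, k]
                                     - lam * (1 - lam) * V[i, j])
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    seed = dendropy.Node()
    if len(active) == 3:
        i, j, k = active
        bi = max(0.0, (D[i, j] + D[i, k] - D[j, k]) / 2.0)
        bj = max(0.0, (D[i, j] + D[j, k] - D[i, k]) / 2.0)
        bk = max(0.0, (D[i, k] + D[j, k] - D[i, j]) / 2.0)
        for idx, b in ((i, bi), (j, bj), (k, bk)):
            nodes[idx].edge.length = b
            seed.add_child(nodes[idx])
    else:  # two nodes remain (n == 3 cannot reach here; defensive)
        i, j = active
        for idx in (i, j):
            nodes[idx].edge.length = D[i, j] / 2.0
            seed.add_child(nodes[idx])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    return tree


def bionj(dm: DistanceMatrix) -> dendropy.Tree:
    """BioNJ agglomeration (variance-weighted branch estimates).

    For additive input matrices the reconstructed tree's patristic
    distances reproduce the input exactly.
    """
    return _build_distance_tree(dm, variance_weighted=True)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Plain Saitou-Nei neighbour joining (flagged fallback to BioNJ)."""
    return _build_distance_tree(dm, variance_weighted=False)


def _leaf_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    out = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else None
        if label is None:
            raise ValueError("leaf without taxon label")
        if label in out:
            raise ValueError(f"duplicate leaf label {label!r}")
        out[label] = leaf
    return out


def patristic_matrix(tree: dendropy.Tree,
                     labels: list[str] | None = None) -> DistanceMatrix:
    """Pairwise sums of branch lengths along leaf-to-leaf paths."""
    leaves = _leaf_map(tree)
    if labels is None:
        labels = sorted(leaves)
    # distances by a single post-order sweep per leaf would be O(n^2) anyway;
    # dendropy's phylogenetic distance matrix does the bookkeeping for us
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    vals = np.zeros((n, n))
    for a in range(n):
        ta = leaves[labels[a]].taxon
        for b in range(a + 1, n):
            d = pdm.patristic_distance(ta, leaves[labels[b]].taxon)
            vals[a, b] = vals[b, a] = d
    return DistanceMatrix(labels, vals)


def _path_edges(leaf_a: dendropy.Node, leaf_b: dendropy.Node):
    """Edges along the path from leaf_a to leaf_b, in order from leaf_a."""
    anc_a = [leaf_a]
    node = leaf_a
    while node.parent_node is not None:
        node = node.parent_node
        anc_a.append(node)
    index_a = {id(nd): i for i, nd in enumerate(anc_a)}
    chain_b = [leaf_b]
    node = leaf_b
    while id(node) not in index_a:
        node = node.parent_node
        chain_b.append(node)
    mrca = node
    edges = []
    for nd in anc_a[:index_a[id(mrca)]]:
        edges.append((nd, nd.edge.length or 0.0, "up"))
    down = [nd for nd in chain_b[:-1]]
    for nd in reversed(down):
        edges.append((nd, nd.edge.length or 0.0, "down"))
    return edges


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths break on the lexicographically smallest
    (leaf, leaf) label pair.  The input tree is left untouched.
    """
    t = tree.clone(depth=1)
    leaves = _leaf_map(t)
    labels = sorted(leaves)
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves")
    dm = patristic_matrix(t, labels)
    best_pair = None
    best_d = -1.0
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            d = dm.values[a, b]
            if d > best_d + 1e-15:
                best_d = d
                best_pair = (labels[a], labels[b])
    if best_d <= 0:
        t.is_rooted = True
        return t
    la, lb = best_pair
    half = best_d / 2.0
    edges = _path_edges(leaves[la], leaves[lb])
    cum = 0.0
    for node, length, direction in edges:
        if cum + length >= half - 1e-12:
            offset = half - cum  # distance into this edge, walking from la
            child = node
            parent = node.parent_node
            # distance from the child end of the edge to the root point
            x_child = offset if direction == "up" else length - offset
            x_child = min(max(x_child, 0.0), length)
            if x_child <= 1e-12 and not child.is_leaf():
                t.reroot_at_node(child, update_bipartitions=False)
            elif length - x_child <= 1e-12:
                t.reroot_at_node(parent, update_bipartitions=False)
            else:
                mid = dendropy.Node()
                parent.remove_child(child)
                parent.add_child(mid)
                mid.edge.length = length - x_child
                mid.add_child(child)
                child.edge.length = x_child
                t.reroot_at_node(mid, update_bipartitions=False)
            break
        cum += length
    t.is_rooted = True
    t.seed_node.edge.length = None
    return t


def node_heights(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Height of each node: max patristic distance to a descendant leaf."""
    heights: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            heights[node] = max(heights[ch] + (ch.edge.length or 0.0)
                                for ch in node.child_nodes())
    return heights


def cut_tree(tree: dendropy.Tree, h: float) -> list[frozenset[str]]:
    """Partition leaves into the maximal clades whose height is <= h."""
    if h < 0:
        raise ValueError("cut height must be non-negative")
    heights = node_heights(tree)
    groups: list[frozenset[str]] = []

    def descend(node):
        if heights[node] <= h:
            groups.append(frozenset(
                lf.taxon.label for lf in node.leaf_iter()))
            return
        for ch in node.child_nodes():
            descend(ch)

    descend(tree.seed_node)
    groups.sort(key=min)
    return groups


@dataclass
class CutResult:
    height: float
    groups: list[frozenset[str]]
    within_target: bool

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def find_cut_for_group_count(tree: dendropy.Tree, gmin: int, gmax: int) -> CutResult:
    """Find a height whose cut yields between gmin and gmax groups.

    Candidate heights are the node heights (the group count is a step
    function changing only there, non-increasing in h).  Heights are scanned
    from the root down and the first height within the target window is
    returned.  If the window is skipped over, the height giving the count
    closest above ``gmin`` is returned with ``within_target=False``.
    """
    if gmin > gmax:
        raise ValueError("gmin must be <= gmax")
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if gmin > n_leaves:
        raise ValueError(f"gmin {gmin} exceeds leaf count {n_leaves}")
    heights = sorted(set(node_heights(tree).values()), reverse=True)
    fallback = None
    for h in heights:
        groups = cut_tree(tree, h)
        c = len(groups)
        if gmin <= c <= gmax:
            return CutResult(h, groups, True)
        if c >= gmin and (fallback is None or c < fallback[1]):
            fallback = (h, c)
    h, _ = fallback
    return CutResult(h, cut_tree(tree, h), False)


def assign_types_by_clade(tree: dendropy.Tree,
                          types: Mapping[str, str],
                          validated: Iterable[str],
                          generic_label: str = "generic") -> dict[str, str]:
    """Propagate types to generic leaves within pure validated clades.

    For each maximal clade whose non-generic leaves all share one type and
    which contains at least one experimentally validated leaf of that type,
    the clade's generic leaves adopt the type.  Generic leaves in mixed or
    unvalidated clades keep the generic label.  Non-generic labels are never
    changed, and the operation is idempotent.
    """
    validated = set(validated)
    out = dict(types)
    info: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            t = types[lab]
            typed = set() if t == generic_label else {t}
            has_val = bool(typed) and lab in validated
            info[node] = (typed, has_val)
        else:
            typed = set()
            has_val = False
            for ch in node.child_nodes():
                typed |= info[ch][0]
                has_val = has_val or info[ch][1]
            info[node] = (typed, has_val)

    def descend(node):
        typed, has_val = info[node]
        if len(typed) == 1 and has_val:
            t = next(iter(typed))
            for lf in node.leaf_iter():
                if out[lf.taxon.label] == generic_label:
                    out[lf.taxon.label] = t
            return
        if node.is_leaf():
            return
        for ch in node.child_nodes():
            descend(ch)

    descend(tree.seed_node)
    return out


def prune_to_leaves(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on ``keep``; patristic distances among kept leaves
    are preserved (suppressed degree-2 nodes sum their branch lengths)."""
    keep = set(keep)
    t = tree.clone(depth=1)
    labels = set(_leaf_map(t))
    unknown = keep - labels
    if unknown:
        raise ValueError(f"unknown leaf label(s): {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 leaves to keep")
    if keep == labels:
        return t
    t.retain_taxa_with_labels(keep)
    return t


def read_newick(source) -> dendropy.Tree:
    if hasattr(source, "read"):
        data = source.read()
    else:
        with open(source) as fh:
            data = fh.read()
    return dendropy.Tree.get(data=data, schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", unquoted_underscores=True,
                       suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s
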