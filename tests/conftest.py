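import dendropy
import numpy as np
import pytest

from tffscan.detection import CandidateLocus, DetectedSystem
from tffscan.models_io import (
    GeneRecord,
    GeneTable,
    load_packaged_models,
    load_profile_registry,
)


@pytest.fixture(scope="session")
def registry():
    return load_profile_registry()


@pytest.fixture(scope="session")
def final_models(registry):
    return load_packaged_models("final", registry=registry)


@pytest.fixture(scope="session")
def initial_models(registry):
    return load_packaged_models("initial", registry=registry)


def linear_chromosome(n, genome="g0", replicon="r0", kind="chromosome",
                      topology="linear"):
    """Gene table with a single n-gene replicon."""
    return GeneTable([
        GeneRecord(genome, replicon, topology, kind, p, "+", f"{genome}|{replicon}|{p:05d}")
        for p in range(n)
    ])


def make_system(system_id, component_order, model="toy", genome="g0",
                replicon="r0", start=0, loners=()):
    """Single-locus detected system with components at consecutive ranks."""
    members = tuple((start + i, f"{system_id}~{i}", comp)
                    for i, comp in enumerate(component_order))
    locus = CandidateLocus(model, replicon, members)
    return DetectedSystem(system_id, model, genome, [locus], list(loners),
                          mandatory_count=0, total_count=0)


def random_unrooted_tree(rng, n, min_len=0.1, max_len=1.0):
    """Random unrooted binary tree with strictly positive branch lengths."""
    tns = dendropy.TaxonNamespace()
    labels = [f"L{i:02d}" for i in range(n)]

    def leaf(lab, length):
        nd = dendropy.Node()
        nd.taxon = tns.require_taxon(label=lab)
        nd.edge.length = length
        return nd

    def rand_len():
        return float(rng.uniform(min_len, max_len))

    seed = dendropy.Node()
    for lab in labels[:3]:
        seed.add_child(leaf(lab, rand_len()))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    for lab in labels[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
        edge = edges[int(rng.integers(len(edges)))]
        child, parent = edge.head_node, edge.tail_node
        total = edge.length
        split = float(rng.uniform(0.25, 0.75)) * total
        mid = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(mid)
        mid.edge.length = total - split
        mid.add_child(child)
        child.edge.length = split
        mid.add_child(leaf(lab, rand_len()))
    return tree


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p-value by exhaustive hypergeometric enumeration."""
    from scipy.stats import hypergeom

    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    kmin = max(0, col1 - (n_total - row1))
    kmax = min(row1, col1)
    ks = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(ks, n_total, col1, row1)
    p_obs = hypergeom.pmf(a, n_total, col1, row1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
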