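"""Synthetic inputs with the structure the analysis pipeline assumes.

No sequences are simulated: the pipeline operates on gene-order tables,
profile hits, trees and distance matrices, so the generators emulate those
directly:

* :func:`simulate_genomes` — genomes with planted systems obeying each
  packaged model's composition, organisation and quorum, plus decoy hits
  that can never assemble into a system: decoys are placed isolated (more
  than the co-localisation distance away from any other hit) and drawn only
  from non-loner ATPase/IM-platform profiles, so no decoy cluster can reach
  any quorum or the generic model's three-role requirement;
* :func:`simulate_component_trees` — per-component trees over systems with
  planted groups (within-group distances much smaller than between-group),
  type labels, validated flags and optional paralogous copies;
* :func:`simulate_enrichment` — neighbourhood gene families with planted
  per-type presence probabilities, as identity-edge lists;
* :func:`simulate_profile_edges` — profile-similarity edge lists with a
  known connected-component structure;
* :func:`simulate_events` — per-type DTL event-count tables.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .homology_graph import ProfileEdge
from .models_io import (
    ComponentHit,
    GeneRecord,
    GeneTable,
    ProfileRegistry,
    SystemModel,
    load_packaged_models,
    load_profile_registry,
)
from .redundancy import SystemComponentMap
from .transfer import ReconciliationEvents

__all__ = [
    "PlantSpec",
    "SimulationConfig",
    "PlantedSystem",
    "SimulatedGenomes",
    "ComponentTreeSim",
    "EnrichmentSim",
    "default_plant_plan",
    "simulate_genomes",
    "simulate_component_trees",
    "simulate_enrichment",
    "simulate_profile_edges",
    "simulate_events",
    "tree_length",
]

#: roles decoy hits may use (at most two roles, so the generic model's
#: three-role rule cannot be met by chance even if decoys did cluster)
DECOY_ROLES = ("atpase", "im_platform")

#: components of the planted "generic" systems: one ATPase, IM platform and
#: major pilin drawn from three different types, so no specific quorum is
#: ever approached
GENERIC_PLANT_PROFILES = ("T2SS_gspE", "T4P_pilC", "Tad_flp")


@dataclass(frozen=True)
class PlantSpec:
    model: str
    scatter: bool = False
    on_plasmid: bool = False


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genomes: int = 10
    genes_per_replicon: int = 200
    #: None -> the default plan; an empty list plants nothing (decoys only)
    plant_plan: list[PlantSpec] | None = None
    decoy_hit_rate: float = 0.02
    noise_hit_rate: float = 0.0  # hits above the e-value ceiling
    paralogue_rate: float = 0.0
    # component-tree plan
    n_groups: int = 12
    systems_per_group: int = 4
    within_scale: float = 0.02
    between_scale: float = 1.0
    generic_fraction: float = 0.25
    type_names: tuple[str, ...] = ("Tad", "T4aP", "T2SS", "ComM")
    # enrichment plan
    n_families: int = 20
    null_presence: float = 0.2
    systems_per_type: dict[str, int] = field(
        default_factory=lambda: {"Tad": 20, "T4aP": 30, "T2SS": 30, "ComM": 20})
    effects: dict[tuple[int, str], float] = field(default_factory=dict)
    # DTL event plan: type -> (transfers, duplications, losses, branches)
    event_plan: dict[str, tuple[int, int, int, int]] = field(
        default_factory=lambda: {
            "Tad": (21, 3, 30, 60), "T4aP": (6, 4, 28, 70),
            "T2SS": (9, 2, 22, 55), "ComM": (3, 1, 18, 40)})


def default_plant_plan() -> list[PlantSpec]:
    """One plant per packaged final model, plus a scattered multi-locus
    T4aP, a scattered Tad and a plasmid-borne Tad."""
    return [
        PlantSpec("Tad"),
        PlantSpec("T4aP"),
        PlantSpec("T2SS"),
        PlantSpec("ComM"),
        PlantSpec("Archaeal"),
        PlantSpec("T4bP"),
        PlantSpec("MSH"),
        PlantSpec("generic"),
        PlantSpec("T4aP", scatter=True),
        PlantSpec("Tad", on_plasmid=True),
    ]


@dataclass
class PlantedSystem:
    genome_id: str
    model_name: str
    n_loci: int
    locus_positions: list[list[tuple[str, int]]]  # per locus: (replicon, pos)
    loner_positions: list[tuple[str, int]]
    on_plasmid: bool

    @property
    def single_locus(self) -> bool:
        return self.n_loci == 1 and not self.loner_positions


@dataclass
class SimulatedGenomes:
    gene_table: GeneTable
    hits: list[ComponentHit]
    truth: list[PlantedSystem]


def _planted_blocks(model: SystemModel, spec: PlantSpec) -> tuple[list[list[str]], list[str]]:
    """Component profiles per locus block, plus loner profiles.

    Single-locus plants carry every non-loner mandatory component in one
    block plus all mandatory loners apart.  Scattered plants omit loners and
    split the non-loner mandatory components in two blocks, each below the
    quorum on its own (otherwise detection would rightly report a
    single-locus system).
    """
    non_loner = [c.name for c in model.mandatory_components() if not c.loner]
    loners = [c.name for c in model.mandatory_components() if c.loner]
    if not spec.scatter:
        return [non_loner], loners
    m = len(non_loner)
    if m < model.mgr or m < model.mmgr:
        raise ValueError(
            f"model {model.name!r}: scattered plant infeasible "
            f"(only {m} non-loner mandatory components, quorum needs {model.mgr})")
    first = math.ceil(m / 2)
    if first > model.mgr - 1:
        first = model.mgr - 1
    if m - first > model.mgr - 1:
        raise ValueError(
            f"model {model.name!r}: cannot split {m} components into two "
            f"sub-quorum loci")
    return [non_loner[:first], non_loner[first:]], []


class _RepliconBuilder:
    def __init__(self, genome_id, replicon_id, size, topology, kind, spacing):
        self.genome_id = genome_id
        self.replicon_id = replicon_id
        self.size = size
        self.topology = topology
        self.kind = kind
        self.spacing = spacing
        self.cursor = spacing  # keep the origin clear of planted hits
        self.hit_positions: list[int] = []

    def place_block(self, n: int) -> list[int]:
        if self.cursor + n + self.spacing > self.size:
            raise ValueError(
                f"plan infeasible for replicon size {self.size} "
                f"({self.replicon_id})")
        positions = list(range(self.cursor, self.cursor + n))
        self.cursor += n + self.spacing
        self.hit_positions.extend(positions)
        return positions

    def gene_id(self, pos: int) -> str:
        return f"{self.genome_id}|{self.replicon_id}|{pos:05d}"

    def records(self) -> list[GeneRecord]:
        return [GeneRecord(self.genome_id, self.replicon_id, self.topology,
                           self.kind, p, "+" if p % 2 == 0 else "-",
                           self.gene_id(p))
                for p in range(self.size)]


def simulate_genomes(config: SimulationConfig,
                     models: list[SystemModel] | None = None,
                     registry: ProfileRegistry | None = None,
                     ) -> SimulatedGenomes:
    """Genomes (gene table + hit table) with planted systems and decoys."""
    rng = np.random.default_rng(config.seed)
    if models is None:
        models = load_packaged_models("final")
    if registry is None:
        registry = load_profile_registry()
    by_name = {m.name: m for m in models}
    plan = (config.plant_plan if config.plant_plan is not None
            else default_plant_plan())
    max_space = max(m.inter_gene_max_space for m in models)
    spacing = max_space + 3

    decoy_pool = sorted(
        p for role in DECOY_ROLES for p in registry.profiles_by_role(role)
        if not _is_loner_profile(p, models))

    records: list[GeneRecord] = []
    hits: list[ComponentHit] = []
    truth: list[PlantedSystem] = []

    for gi in range(config.n_genomes):
        genome_id = f"g{gi:04d}"
        chrom = _RepliconBuilder(genome_id, "c0", config.genes_per_replicon,
                                 "circular", "chromosome", spacing)
        builders = [chrom]
        specs = [plan[gi % len(plan)]] if plan else []
        for spec in specs:
            if spec.model == "generic":
                positions = chrom.place_block(len(GENERIC_PLANT_PROFILES))
                for pos, prof in zip(positions, GENERIC_PLANT_PROFILES):
                    hits.append(_hit(chrom.gene_id(pos), prof, rng))
                truth.append(PlantedSystem(genome_id, "generic", 1,
                                           [[("c0", p) for p in positions]],
                                           [], False))
                continue
            model = by_name[spec.model]
            blocks, loners = _planted_blocks(model, spec)
            target = chrom
            if spec.on_plasmid:
                psize = max(40, sum(len(b) for b in blocks) + 4 * spacing)
                target = _RepliconBuilder(genome_id, "p1", psize,
                                          "circular", "plasmid", spacing)
                builders.append(target)
            locus_positions = []
            for block in blocks:
                positions = target.place_block(len(block))
                for pos, prof in zip(positions, block):
                    hits.append(_hit(target.gene_id(pos), prof, rng))
                locus_positions.append([(target.replicon_id, p) for p in positions])
            loner_positions = []
            for prof in loners:
                pos = chrom.place_block(1)[0]
                hits.append(_hit(chrom.gene_id(pos), prof, rng))
                loner_positions.append(("c0", pos))
            truth.append(PlantedSystem(genome_id, model.name, len(blocks),
                                       locus_positions, loner_positions,
                                       spec.on_plasmid))

        # decoys: isolated single hits, never within max_space of another
        # hit.  Profiles of the models planted in this genome are excluded:
        # for multi-locus models, stray decoy singletons would otherwise
        # pool with the planted loners (or the scattered loci) and either
        # complete a spurious quorum or inflate the planted system
        genome_pool = list(decoy_pool)
        for spec in specs:
            if spec.model == "generic":
                continue
            banned = set(by_name[spec.model].profile_map())
            genome_pool = [p for p in genome_pool if p not in banned]
        for builder in builders:
            occupied = sorted(builder.hit_positions)
            for pos in range(builder.size):
                if rng.random() >= config.decoy_hit_rate:
                    continue
                if _near_any(pos, occupied, builder.size, max_space + 1):
                    continue
                prof = genome_pool[int(rng.integers(len(genome_pool)))]
                hits.append(_hit(builder.gene_id(pos), prof, rng, decoy=True))
                occupied = sorted(occupied + [pos])
            if config.noise_hit_rate > 0:
                for pos in range(builder.size):
                    if rng.random() < config.noise_hit_rate:
                        prof = decoy_pool[int(rng.integers(len(decoy_pool)))]
                        hits.append(ComponentHit(builder.gene_id(pos), prof,
                                                 0.5, float(rng.uniform(5, 15))))
            records.extend(builder.records())

    return SimulatedGenomes(GeneTable(records), hits, truth)


def _is_loner_profile(profile: str, models: list[SystemModel]) -> bool:
    for m in models:
        for comp in m.components:
            if comp.loner and (profile == comp.name or profile in comp.exchangeable_with):
                return True
    return False


def _near_any(pos: int, occupied: Sequence[int], size: int, min_gap: int) -> bool:
    for p in occupied:
        lin = abs(pos - p)
        if min(lin, size - lin) <= min_gap:
            return True
    return False


def _hit(gene_id: str, profile: str, rng, decoy: bool = False) -> ComponentHit:
    if decoy:
        e = 10.0 ** -float(rng.uniform(4, 8))
        score = float(rng.uniform(20, 60))
    else:
        e = 10.0 ** -float(rng.uniform(12, 20))
        score = float(rng.uniform(80, 250))
    return ComponentHit(gene_id, profile, e, score)


# ---------------------------------------------------------------------------
# component trees

TREE_ROLES = ("atpase", "im_platform", "major_pilin")


@dataclass
class ComponentTreeSim:
    trees: dict[str, dendropy.Tree]
    systems: list[SystemComponentMap]
    groups: list[frozenset[str]]  # planted partition of system ids


def tree_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.edges() if e.length is not None)


def _group_clade(labels: list[str], rng, within: float) -> dendropy.Node:
    """Caterpillar clade over labels with short internal branches."""
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd._sim_label = lab
        nd.edge.length = within * float(rng.uniform(0.5, 1.5))
        nodes.append(nd)
    while len(nodes) > 1:
        a = nodes.pop(0)
        b = nodes.pop(0)
        joint = dendropy.Node()
        joint.add_child(a)
        joint.add_child(b)
        joint.edge.length = within * float(rng.uniform(0.5, 1.5))
        nodes.append(joint)
    return nodes[0]


def simulate_component_trees(config: SimulationConfig) -> ComponentTreeSim:
    """Per-component trees with planted, well-separated system groups.

    Groups are attached to a star backbone with stems of ``between_scale``
    while within-group branches are of order ``within_scale`` (10x smaller
    or more by default), so cutting at the tallest group height recovers the
    planted partition exactly.  Each group carries one type; one member per
    group is flagged experimentally validated; ``generic_fraction`` of the
    remaining members are labelled generic.  Paralogous copies appear as
    near-duplicate leaves at rate ``paralogue_rate``.
    """
    if config.n_groups < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_groups * config.systems_per_group
    system_ids = [f"s{i:04d}" for i in range(n)]
    groups = [frozenset(system_ids[k * config.systems_per_group:
                                   (k + 1) * config.systems_per_group])
              for k in range(config.n_groups)]
    meta: dict[str, SystemComponentMap] = {
        sid: SystemComponentMap(sid, {}, validated=False, type="generic")
        for sid in system_ids}
    for k, group in enumerate(groups):
        members = sorted(group)
        gtype = config.type_names[k % len(config.type_names)]
        meta[members[0]].validated = True
        meta[members[0]].type = gtype
        for sid in members[1:]:
            if rng.random() < config.generic_fraction:
                meta[sid].type = "generic"
            else:
                meta[sid].type = gtype

    trees: dict[str, dendropy.Tree] = {}
    for role in TREE_ROLES:
        copies: dict[str, list[str]] = {}
        for sid in system_ids:
            k = 2 if rng.random() < config.paralogue_rate else 1
            copies[sid] = [f"{sid}|{role}|{c + 1}" for c in range(k)]
            meta[sid].components[role] = copies[sid]
        tns = dendropy.TaxonNamespace()
        root = dendropy.Node()
        for group in groups:
            clade = _group_clade(sorted(group), rng, config.within_scale)
            clade.edge.length = config.between_scale * float(rng.uniform(1.0, 1.3))
            root.add_child(clade)
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
        # expand system placeholders into leaves (cherries for paralogues)
        for nd in list(tree.leaf_node_iter()):
            sid = nd._sim_label
            labs = copies[sid]
            if len(labs) == 1:
                nd.taxon = tns.require_taxon(label=labs[0])
            else:
                for lab in labs:
                    child = dendropy.Node()
                    child.taxon = tns.require_taxon(label=lab)
                    child.edge.length = 0.1 * config.within_scale
                    nd.add_child(child)
        tree.is_rooted = True
        trees[role] = tree
    return ComponentTreeSim(trees, [meta[sid] for sid in system_ids], groups)


# ---------------------------------------------------------------------------
# neighbourhood enrichment

@dataclass
class EnrichmentSim:
    system_types: dict[str, str]
    presence: dict[str, frozenset[str]]  # family id -> systems present
    genes: list[str]
    gene_systems: dict[str, str]
    edges: list[tuple[str, str, float]]
    truth: set[tuple[str, str]]  # planted enriched (family, type)


def simulate_enrichment(config: SimulationConfig) -> EnrichmentSim:
    """Family presence per system drawn from the per-type effect table.

    Null families are present with probability ``null_presence`` in every
    type; entries of ``config.effects`` override the probability for one
    (family index, type) cell and are recorded as planted truth when they
    exceed the null.  Gene-level identity edges chain each family's genes at
    80% identity, with sub-threshold (30%) edges between consecutive
    families to exercise the clustering threshold.
    """
    rng = np.random.default_rng(config.seed + 2)
    system_types: dict[str, str] = {}
    for t, k in sorted(config.systems_per_type.items()):
        for i in range(k):
            system_types[f"{t}_{i:03d}"] = t
    fam_ids = [f"f{j:03d}" for j in range(config.n_families)]
    presence: dict[str, frozenset[str]] = {}
    genes: list[str] = []
    gene_systems: dict[str, str] = {}
    edges: list[tuple[str, str, float]] = []
    truth = {(fam_ids[j], t) for (j, t), p in config.effects.items()
             if p > config.null_presence}
    for j, fam in enumerate(fam_ids):
        present = []
        for sid, t in sorted(system_types.items()):
            p = config.effects.get((j, t), config.null_presence)
            if rng.random() < p:
                present.append(sid)
        presence[fam] = frozenset(present)
        fam_genes = [f"{sid}~{fam}" for sid in present]
        genes.extend(fam_genes)
        for g, sid in zip(fam_genes, present):
            gene_systems[g] = sid
        for a, b in zip(fam_genes, fam_genes[1:]):
            edges.append((a, b, float(rng.uniform(60, 95))))
    # decoy sub-threshold edges between families (must not merge them)
    prev = None
    for fam in fam_ids:
        if presence[fam]:
            first = sorted(presence[fam])[0] + "~" + fam
            if prev is not None:
                edges.append((prev, first, float(rng.uniform(10, 40))))
            prev = first
    return EnrichmentSim(system_types, presence, genes, gene_systems,
                         edges, truth)


# ---------------------------------------------------------------------------
# profile-similarity edges and DTL events

def simulate_profile_edges(groups: Iterable[Iterable[str]],
                           seed: int = 0,
                           alpha: float = 1e-3) -> list[ProfileEdge]:
    """Edge list whose reciprocally significant part has exactly the given
    connected components; cross-group edges are insignificant or
    one-directional only."""
    rng = np.random.default_rng(seed)
    groups = [sorted(g) for g in groups]
    edges: list[ProfileEdge] = []

    def sig() -> float:
        return alpha * 10.0 ** -float(rng.uniform(0.5, 4.0))

    def insig() -> float:
        return float(rng.uniform(alpha * 2, 1.0))

    for g in groups:
        for a, b in zip(g, g[1:]):  # spanning path keeps the group connected
            edges.append(ProfileEdge(a, b, sig(), sig()))
        extra = max(0, len(g) - 2)
        for _ in range(extra):
            a, b = rng.choice(len(g), size=2, replace=False)
            if g[a] != g[b]:
                edges.append(ProfileEdge(g[min(a, b)], g[max(a, b)], sig(), sig()))
    for ga, gb in zip(groups, groups[1:]):
        # reciprocity failure: significant one way only
        edges.append(ProfileEdge(ga[0], gb[0], sig(), insig()))
        edges.append(ProfileEdge(ga[-1], gb[-1], insig(), insig()))
    return edges


def simulate_events(config: SimulationConfig) -> list[ReconciliationEvents]:
    return [ReconciliationEvents(t, *counts)
            for t, counts in sorted(config.event_plan.items())]
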