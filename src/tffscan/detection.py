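"""Quorum/co-localisation detection of multi-gene systems.

A candidate system is a run of component-annotated genes in which consecutive
members are separated by at most ``inter_gene_max_space`` intervening genes
(gaps are measured on the shorter arc of circular replicons).  Loner
components are excluded from clustering and collected genome-wide.  A locus
containing a gene annotated to a forbidden component of the model is
discarded.  A candidate is validated when the distinct components it carries
satisfy the model quorum: at least MMGR mandatory components and at least MGR
mandatory + accessory components (duplicated components count once).

Specific models are evaluated first; genes consumed by an accepted specific
system are unavailable to other systems (loners may be shared).  Remaining
clusters are evaluated under the *generic* model, which accepts any cluster
carrying at least one ATPase-role, one IM-platform-role and one
major-pilin-role gene, whatever the source profile.

For models flagged ``multi_loci``, loci that satisfy the quorum on their own
become single-locus systems, and the remaining loci pool their components
(with the loners) into at most one multi-locus system.  Strictly pooling
every locus would fuse independent complete systems that happen to share a
replicon, which the per-locus-first rule avoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models_io import (
    ComponentHit,
    GeneTable,
    ProfileRegistry,
    SystemModel,
)

__all__ = [
    "CandidateLocus",
    "DetectedSystem",
    "Rejection",
    "EvaluationOutcome",
    "GENERIC_CORE_ROLES",
    "cluster_colocalized_hits",
    "evaluate_candidate",
    "detect_systems",
    "write_systems_table",
]

#: roles a generic candidate must all carry to be accepted
GENERIC_CORE_ROLES = ("atpase", "im_platform", "major_pilin")
#: roles searched by the generic model (the two accessory roles are optional)
GENERIC_ALL_ROLES = GENERIC_CORE_ROLES + ("secretin", "prepilin_peptidase")


@dataclass(frozen=True)
class CandidateLocus:
    model_name: str
    replicon_id: str
    #: ordered (position, gene_id, component_name); on circular replicons the
    #: order is the run order, which may wrap through position 0
    members: tuple[tuple[int, str, str], ...]
    wraps: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (self.members[0][0], self.members[-1][0])

    def gene_ids(self) -> set[str]:
        return {g for _, g, _ in self.members}

    def components(self) -> set[str]:
        return {c for _, _, c in self.members}

    def span_length(self, replicon_size: int | None = None) -> int:
        first, last = self.span
        if self.wraps:
            if replicon_size is None:
                raise ValueError("replicon_size needed for a wrapped locus")
            return (last - first) % replicon_size + 1
        return last - first + 1

    def covers_position(self, pos: int, replicon_size: int | None = None) -> bool:
        first, last = self.span
        if not self.wraps:
            return first <= pos <= last
        return pos >= first or pos <= last


@dataclass(frozen=True)
class Rejection:
    reason: str  # forbidden | below_mmgr | below_mgr
    model_name: str
    loci: tuple[CandidateLocus, ...] = ()


@dataclass
class DetectedSystem:
    system_id: str
    model_name: str
    genome_id: str
    loci: list[CandidateLocus]
    loner_genes: list[tuple[str, str]]  # (gene_id, component_name)
    mandatory_count: int
    total_count: int

    @property
    def single_locus(self) -> bool:
        return len(self.loci) == 1 and not self.loner_genes

    def gene_ids(self) -> set[str]:
        out = set()
        for locus in self.loci:
            out |= locus.gene_ids()
        out |= {g for g, _ in self.loner_genes}
        return out

    def components(self) -> set[str]:
        out = set()
        for locus in self.loci:
            out |= locus.components()
        out |= {c for _, c in self.loner_genes}
        return out


@dataclass
class EvaluationOutcome:
    systems: list[DetectedSystem] = field(default_factory=list)
    rejections: list[Rejection] = field(default_factory=list)


def _runs_from_positions(positions: list[int], size: int, circular: bool,
                         max_space: int) -> list[tuple[list[int], bool]]:
    """Split sorted positions into maximal runs with gaps <= max_space.

    Returns (run, wraps) pairs; a run is a list of positions in run order.
    """
    if not positions:
        return []
    positions = sorted(positions)
    n = len(positions)
    if n == 1:
        return [(positions, False)]
    gaps = [positions[i + 1] - positions[i] - 1 for i in range(n - 1)]
    if circular:
        wrap_gap = positions[0] + size - positions[-1] - 1
        if all(g <= max_space for g in gaps) and wrap_gap <= max_space:
            # the whole set forms one circular run; open it at the largest gap
            # (deterministically the first largest) so the run order is stable
            all_gaps = gaps + [wrap_gap]
            cut = max(range(len(all_gaps)), key=lambda i: (all_gaps[i], -i))
            order = positions[cut + 1:] + positions[:cut + 1]
            return [(order, cut != len(all_gaps) - 1)]
        if wrap_gap <= max_space:
            # rotate so the linear scan starts after a real break
            brk = next(i for i, g in enumerate(gaps) if g > max_space)
            rotated = positions[brk + 1:] + positions[:brk + 1]
            runs = []
            cur = [rotated[0]]
            for prev, nxt in zip(rotated, rotated[1:]):
                gap = (nxt - prev - 1) % size
                if gap <= max_space:
                    cur.append(nxt)
                else:
                    runs.append(cur)
                    cur = [nxt]
            runs.append(cur)
            return [(run, run[0] > run[-1]) for run in runs]
    runs = []
    cur = [positions[0]]
    for gap, nxt in zip(gaps, positions[1:]):
        if gap <= max_space:
            cur.append(nxt)
        else:
            runs.append(cur)
            cur = [nxt]
    runs.append(cur)
    return [(run, False) for run in runs]


def annotate_for_model(resolved: dict[str, ComponentHit], model: SystemModel,
                       gene_table: GeneTable, genome_id: str,
                       ) -> list[tuple[object, str]]:
    """(gene record, component name) pairs for this genome under this model.

    Hits to exchangeable profiles are mapped to their host component here,
    before any clustering.
    """
    pmap = model.profile_map()
    out = []
    for gene_id, hit in resolved.items():
        comp = pmap.get(hit.profile_name)
        if comp is None:
            continue
        rec = gene_table.gene(gene_id)
        if rec.genome_id != genome_id:
            continue
        out.append((rec, comp))
    out.sort(key=lambda rc: (rc[0].replicon_id, rc[0].position))
    return out


def cluster_colocalized_hits(annotations, gene_table: GeneTable,
                             model: SystemModel) -> list[CandidateLocus]:
    """Cluster non-loner component annotations into candidate loci.

    ``annotations`` are (gene record, component) pairs restricted to one
    genome; loner components must already have been removed by the caller
    (see :func:`candidate_loci_for_model`).
    """
    by_replicon: dict[str, dict[int, tuple[str, str]]] = {}
    for rec, comp in annotations:
        by_replicon.setdefault(rec.replicon_id, {})[rec.position] = (rec.gene_id, comp)
    loci: list[CandidateLocus] = []
    for replicon_id in sorted(by_replicon):
        members = by_replicon[replicon_id]
        genome_id = gene_table.gene(next(iter(members.values()))[0]).genome_id
        info = gene_table.replicon_info(genome_id, replicon_id)
        runs = _runs_from_positions(list(members), info.size,
                                    info.topology == "circular",
                                    model.inter_gene_max_space)
        for run, wraps in runs:
            loci.append(CandidateLocus(
                model_name=model.name,
                replicon_id=replicon_id,
                members=tuple((p, *members[p]) for p in run),
                wraps=wraps,
            ))
    loci.sort(key=lambda l: (l.replicon_id, l.members[0][0]))
    return loci


def candidate_loci_for_model(gene_table: GeneTable, genome_id: str,
                             resolved: dict[str, ComponentHit],
                             model: SystemModel):
    """Build clustered loci, loner annotations and forbidden-gene positions."""
    annotations = annotate_for_model(resolved, model, gene_table, genome_id)
    loners: list[tuple[str, str]] = []
    forbidden: list[tuple[str, int]] = []  # (replicon_id, position)
    clusterable = []
    for rec, comp_name in annotations:
        comp = model.component(comp_name)
        if comp.status == "forbidden":
            forbidden.append((rec.replicon_id, rec.position))
        elif comp.loner:
            loners.append((rec.gene_id, comp_name))
        else:
            clusterable.append((rec, comp_name))
    loci = cluster_colocalized_hits(clusterable, gene_table, model)
    return loci, sorted(set(loners)), forbidden


def _quorum(components: set[str], model: SystemModel) -> tuple[int, int]:
    mand = {c.name for c in model.mandatory_components()}
    acc = {c.name for c in model.accessory_components()}
    mandatory_count = len(components & mand)
    total_count = mandatory_count + len(components & acc)
    return mandatory_count, total_count


def _locus_has_forbidden(locus: CandidateLocus, forbidden, gene_table, genome_id) -> bool:
    for replicon_id, pos in forbidden:
        if replicon_id != locus.replicon_id:
            continue
        size = gene_table.replicon_info(genome_id, replicon_id).size if locus.wraps else None
        if locus.covers_position(pos, size):
            return True
    return False


def evaluate_candidate(loci, loners, model: SystemModel,
                       forbidden=(), gene_table: GeneTable | None = None,
                       genome_id: str | None = None) -> EvaluationOutcome:
    """Apply forbidden-gene exclusion and the quorum rule to candidate loci.

    Returns accepted (unnamed) systems and per-candidate rejections with a
    reason code among ``forbidden``, ``below_mmgr``, ``below_mgr``.
    """
    outcome = EvaluationOutcome()
    surviving = []
    for locus in loci:
        if forbidden and _locus_has_forbidden(locus, forbidden, gene_table, genome_id):
            outcome.rejections.append(Rejection("forbidden", model.name, (locus,)))
        else:
            surviving.append(locus)

    loners = sorted(set(loners))

    def components_of(group) -> set[str]:
        comps = set()
        for locus in group:
            comps |= locus.components()
        comps |= {c for _, c in loners}
        return comps

    def try_accept(group) -> bool:
        comps = components_of(group)
        mand, total = _quorum(comps, model)
        if mand < model.mmgr:
            outcome.rejections.append(Rejection("below_mmgr", model.name, tuple(group)))
            return False
        if total < model.mgr:
            outcome.rejections.append(Rejection("below_mgr", model.name, tuple(group)))
            return False
        outcome.systems.append(DetectedSystem(
            system_id="", model_name=model.name, genome_id=genome_id or "",
            loci=list(group), loner_genes=list(loners),
            mandatory_count=mand, total_count=total))
        return True

    if not surviving:
        return outcome
    if model.multi_loci:
        rest = []
        for locus in surviving:
            comps = components_of([locus])
            mand, total = _quorum(comps, model)
            if mand >= model.mmgr and total >= model.mgr:
                try_accept([locus])
            else:
                rest.append(locus)
        if rest:
            try_accept(rest)
    else:
        for locus in surviving:
            try_accept([locus])
    return outcome


def _precedence_key(system: DetectedSystem, gene_table: GeneTable):
    first = system.loci[0]
    size = gene_table.replicon_info(system.genome_id, first.replicon_id).size
    span = sum(l.span_length(gene_table.replicon_info(system.genome_id,
                                                      l.replicon_id).size)
               for l in system.loci)
    return (-len(system.components()), span, first.replicon_id,
            first.members[0][0] % size, system.model_name)


def detect_systems(gene_table: GeneTable,
                   resolved: dict[str, ComponentHit],
                   models: list[SystemModel],
                   registry: ProfileRegistry | None = None,
                   role_sets: dict[str, set[str]] | None = None,
                   ) -> list[DetectedSystem]:
    """Detect systems in every genome of ``gene_table``.

    ``models`` may include a model named ``generic``; it is evaluated last,
    on genes not consumed by accepted specific systems, using the role
    groups in ``role_sets`` (profile sets per role, typically the connected
    components of the profile-similarity graph).  When ``role_sets`` is not
    given it is derived from ``registry`` roles.
    """
    specific = [m for m in models if m.name != "generic"]
    generic = next((m for m in models if m.name == "generic"), None)
    if generic is not None and role_sets is None:
        if registry is None:
            raise ValueError("generic model requires role_sets or a registry")
        role_sets = {role: registry.profiles_by_role(role)
                     for role in GENERIC_ALL_ROLES}

    out: list[DetectedSystem] = []
    for genome_id in gene_table.genomes():
        candidates: list[DetectedSystem] = []
        for model in specific:
            loci, loners, forbidden = candidate_loci_for_model(
                gene_table, genome_id, resolved, model)
            outcome = evaluate_candidate(loci, loners, model, forbidden,
                                         gene_table, genome_id)
            candidates.extend(outcome.systems)

        candidates.sort(key=lambda s: _precedence_key(s, gene_table))
        consumed: set[str] = set()
        accepted: list[DetectedSystem] = []
        for cand in candidates:
            model = next(m for m in specific if m.name == cand.model_name)
            trimmed = []
            for locus in cand.loci:
                members = tuple(m for m in locus.members if m[1] not in consumed)
                if members:
                    trimmed.append(CandidateLocus(locus.model_name, locus.replicon_id,
                                                  members, locus.wraps))
            if not trimmed:
                continue
            comps = set()
            for locus in trimmed:
                comps |= locus.components()
            comps |= {c for _, c in cand.loner_genes}
            mand, total = _quorum(comps, model)
            if mand < model.mmgr or total < model.mgr:
                continue
            accepted.append(DetectedSystem(
                system_id="", model_name=cand.model_name, genome_id=genome_id,
                loci=trimmed, loner_genes=cand.loner_genes,
                mandatory_count=mand, total_count=total))
            for locus in trimmed:
                consumed |= locus.gene_ids()

        if generic is not None:
            accepted.extend(_detect_generic(gene_table, genome_id, resolved,
                                            generic, role_sets, consumed))

        accepted.sort(key=lambda s: (s.loci[0].replicon_id,
                                     s.loci[0].members[0][0], s.model_name))
        counter: dict[str, int] = {}
        for system in accepted:
            k = counter.get(system.model_name, 0) + 1
            counter[system.model_name] = k
            system.system_id = f"{genome_id}::{system.model_name}::{k}"
        out.extend(accepted)
    return out


def _detect_generic(gene_table, genome_id, resolved, generic: SystemModel,
                    role_sets, consumed) -> list[DetectedSystem]:
    profile_role: dict[str, str] = {}
    for role, profs in role_sets.items():
        for p in profs:
            profile_role[p] = role
    annotations = []
    for gene_id, hit in resolved.items():
        if gene_id in consumed:
            continue
        role = profile_role.get(hit.profile_name)
        if role is None:
            continue
        rec = gene_table.gene(gene_id)
        if rec.genome_id != genome_id:
            continue
        annotations.append((rec, role))
    loci = cluster_colocalized_hits(annotations, gene_table, generic)
    systems = []
    for locus in loci:
        roles = locus.components()
        if all(r in roles for r in GENERIC_CORE_ROLES):
            mand, total = _quorum(roles, generic)
            systems.append(DetectedSystem(
                system_id="", model_name="generic", genome_id=genome_id,
                loci=[locus], loner_genes=[],
                mandatory_count=mand, total_count=total))
    return systems


def write_systems_table(systems: list[DetectedSystem], path) -> None:
    """Long-format TSV: one row per member gene of each detected system."""
    import pandas as pd

    rows = []
    for s in systems:
        for locus in s.loci:
            for pos, gene_id, comp in locus.members:
                rows.append((s.system_id, s.model_name, s.genome_id, len(s.loci),
                             s.single_locus, comp, gene_id, locus.replicon_id, pos))
        for gene_id, comp in s.loner_genes:
            rows.append((s.system_id, s.model_name, s.genome_id, len(s.loci),
                         s.single_locus, comp, gene_id, "", -1))
    pd.DataFrame(rows, columns=[
        "system_id", "model_name", "genome_id", "n_loci", "single_locus",
        "component", "gene_id", "replicon_id", "position",
    ]).to_csv(path, sep="\t", index=False)
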