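"""Parsing and validation of gene-order tables, profile-hit tables and system models.

The detection engine works on three kinds of inputs:

* a *gene table* giving, for every gene, its genome, replicon, 0-based rank on
  the replicon, strand, and the replicon's topology (linear/circular) and kind
  (chromosome/plasmid).  Gene positions are ranks, not nucleotide coordinates,
  because all co-localisation distances in the models are counted in genes;
* a *hit table* associating genes with HMM-profile names (e-value + score),
  the moral equivalent of an HMMER tblout reduced to its useful columns;
* declarative *system models* describing, for each system type, its
  components (mandatory / accessory / forbidden, loner flags, exchangeable
  profiles) and the quorum thresholds MMGR (minimum mandatory genes required)
  and MGR (minimum mandatory + accessory genes required).

Models are shipped with the package for the eight final and six initial
system definitions (``load_packaged_models``), together with a registry
mapping every profile to its functional role (ATPase, IM platform, pilins,
secretin, prepilin peptidase, ...) and source system type.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "ModelConfigError",
    "GeneTableError",
    "HitError",
    "GeneRecord",
    "GeneTable",
    "ComponentHit",
    "ModelComponent",
    "SystemModel",
    "ProfileRegistry",
    "parse_models",
    "write_models",
    "load_packaged_models",
    "load_profile_registry",
    "parse_gene_table",
    "write_gene_table",
    "parse_hit_table",
    "write_hit_table",
    "resolve_hits",
]

TOPOLOGIES = ("linear", "circular")
REPLICON_KINDS = ("chromosome", "plasmid")
STATUSES = ("mandatory", "accessory", "forbidden")

#: default ceiling on hit e-values; exposed as a parameter because the
#: reporting threshold used with the original profiles is not documented.
DEFAULT_MAX_EVALUE = 1e-3

GENE_TABLE_COLUMNS = [
    "genome_id", "replicon_id", "topology", "replicon_kind",
    "position", "strand", "gene_id",
]
HIT_TABLE_COLUMNS = ["gene_id", "profile_name", "e_value", "score"]


class ModelConfigError(ValueError):
    """A system-model definition violates the config grammar or an invariant."""


class GeneTableError(ValueError):
    """A gene table violates the per-replicon position contract."""


class HitError(ValueError):
    """A hit row is malformed or references an unknown gene."""


@dataclass(frozen=True)
class GeneRecord:
    genome_id: str
    replicon_id: str
    topology: str
    replicon_kind: str
    position: int
    strand: str
    gene_id: str


@dataclass(frozen=True)
class RepliconInfo:
    topology: str
    replicon_kind: str
    size: int


class GeneTable:
    """Genome-indexed collection of :class:`GeneRecord`.

    Validates on construction that positions within each replicon form
    exactly ``0..n-1`` and that gene ids are unique within a genome.
    """

    def __init__(self, records: Iterable[GeneRecord]):
        self.records = list(records)
        self._by_replicon: dict[tuple[str, str], list[GeneRecord]] = {}
        self._replicon_info: dict[tuple[str, str], RepliconInfo] = {}
        self._gene_index: dict[str, GeneRecord | None] = {}
        genome_gene_ids: dict[str, set[str]] = {}
        for rec in self.records:
            if rec.topology not in TOPOLOGIES:
                raise GeneTableError(f"unknown topology token {rec.topology!r}")
            if rec.replicon_kind not in REPLICON_KINDS:
                raise GeneTableError(f"unknown replicon kind {rec.replicon_kind!r}")
            if rec.strand not in ("+", "-"):
                raise GeneTableError(f"unknown strand token {rec.strand!r}")
            key = (rec.genome_id, rec.replicon_id)
            self._by_replicon.setdefault(key, []).append(rec)
            seen = genome_gene_ids.setdefault(rec.genome_id, set())
            if rec.gene_id in seen:
                raise GeneTableError(
                    f"duplicate gene_id {rec.gene_id!r} in genome {rec.genome_id!r}")
            seen.add(rec.gene_id)
            if rec.gene_id in self._gene_index:
                # ambiguous across genomes; lookups by bare gene_id will fail
                self._gene_index[rec.gene_id] = None
            else:
                self._gene_index[rec.gene_id] = rec
        for key, recs in self._by_replicon.items():
            recs.sort(key=lambda r: r.position)
            positions = [r.position for r in recs]
            if positions != list(range(len(recs))):
                dupes = {p for p in positions if positions.count(p) > 1}
                if dupes:
                    raise GeneTableError(
                        f"duplicate position(s) {sorted(dupes)} on replicon {key}")
                raise GeneTableError(
                    f"positions on replicon {key} are not contiguous from 0")
            topo = {r.topology for r in recs}
            kind = {r.replicon_kind for r in recs}
            if len(topo) > 1 or len(kind) > 1:
                raise GeneTableError(f"inconsistent replicon flags on {key}")
            self._replicon_info[key] = RepliconInfo(topo.pop(), kind.pop(), len(recs))

    def genomes(self) -> list[str]:
        return sorted({g for g, _ in self._by_replicon})

    def replicons(self, genome_id: str) -> list[str]:
        return sorted(r for g, r in self._by_replicon if g == genome_id)

    def replicon_genes(self, genome_id: str, replicon_id: str) -> list[GeneRecord]:
        return self._by_replicon[(genome_id, replicon_id)]

    def replicon_info(self, genome_id: str, replicon_id: str) -> RepliconInfo:
        return self._replicon_info[(genome_id, replicon_id)]

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            rec = self._gene_index[gene_id]
        except KeyError:
            raise HitError(f"unknown gene_id {gene_id!r}") from None
        if rec is None:
            raise HitError(f"gene_id {gene_id!r} is ambiguous across genomes")
        return rec

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True, order=True)
class ComponentHit:
    gene_id: str
    profile_name: str
    e_value: float
    score: float

    def __post_init__(self):
        if not self.e_value > 0:
            raise HitError(
                f"hit {self.gene_id}/{self.profile_name}: e_value must be > 0")


@dataclass(frozen=True)
class ModelComponent:
    name: str
    status: str
    loner: bool = False
    exchangeable_with: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ModelConfigError(
                f"component {self.name!r}: unknown status {self.status!r}")
        if self.status == "forbidden" and self.loner:
            raise ModelConfigError(
                f"component {self.name!r}: a forbidden component cannot be a loner")
        if self.name in self.exchangeable_with:
            raise ModelConfigError(
                f"component {self.name!r}: exchangeable_with contains itself")


@dataclass
class SystemModel:
    name: str
    components: list[ModelComponent]
    mmgr: int
    mgr: int
    inter_gene_max_space: int = 5
    multi_loci: bool = False

    def __post_init__(self):
        if self.inter_gene_max_space < 0:
            raise ModelConfigError(f"model {self.name!r}: negative inter_gene_max_space")
        if self.mmgr < 1 or self.mgr < 1:
            raise ModelConfigError(f"model {self.name!r}: quorum values must be positive")
        if self.mmgr > self.mgr:
            raise ModelConfigError(
                f"model {self.name!r}: quorum inconsistency (mmgr {self.mmgr} > mgr {self.mgr})")
        n_mand = len(self.mandatory_components())
        n_scoring = n_mand + len(self.accessory_components())
        if self.mgr > n_scoring:
            raise ModelConfigError(
                f"model {self.name!r}: mgr {self.mgr} exceeds the "
                f"{n_scoring} mandatory+accessory components")
        if self.mmgr > n_mand:
            raise ModelConfigError(
                f"model {self.name!r}: mmgr {self.mmgr} exceeds the "
                f"{n_mand} mandatory components")
        names = [c.name for c in self.components]
        if len(names) != len(set(names)):
            raise ModelConfigError(f"model {self.name!r}: duplicate component names")

    def mandatory_components(self) -> list[ModelComponent]:
        return [c for c in self.components if c.status == "mandatory"]

    def accessory_components(self) -> list[ModelComponent]:
        return [c for c in self.components if c.status == "accessory"]

    def forbidden_components(self) -> list[ModelComponent]:
        return [c for c in self.components if c.status == "forbidden"]

    def component(self, name: str) -> ModelComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def profile_map(self) -> dict[str, str]:
        """Map every detectable profile to the component it stands for.

        A component is detected by the profile bearing its own name and by
        any profile listed in ``exchangeable_with``.  A profile claimed by
        two components of the same model is a config error.
        """
        mapping: dict[str, str] = {}
        for comp in self.components:
            for prof in (comp.name, *sorted(comp.exchangeable_with)):
                if prof in mapping and mapping[prof] != comp.name:
                    raise ModelConfigError(
                        f"model {self.name!r}: profile {prof!r} claimed by both "
                        f"{mapping[prof]!r} and {comp.name!r}")
                mapping[prof] = comp.name
        return mapping


class ProfileRegistry:
    """Registry of known profiles with functional role and source system type."""

    def __init__(self, rows: Iterable[tuple[str, str, str]]):
        self._role: dict[str, str] = {}
        self._source: dict[str, str] = {}
        for profile, role, source in rows:
            if profile in self._role:
                raise ModelConfigError(f"profile {profile!r} registered twice")
            self._role[profile] = role
            self._source[profile] = source

    def __contains__(self, profile: str) -> bool:
        return profile in self._role

    def __len__(self) -> int:
        return len(self._role)

    def profiles(self) -> list[str]:
        return sorted(self._role)

    def role(self, profile: str) -> str:
        return self._role[profile]

    def source_model(self, profile: str) -> str:
        return self._source[profile]

    def profiles_by_role(self, role: str) -> set[str]:
        return {p for p, r in self._role.items() if r == role}

    def role_seeds(self) -> dict[str, str]:
        """One representative profile per role, for seeding the homology graph."""
        seeds: dict[str, str] = {}
        for profile in self.profiles():
            seeds.setdefault(self._role[profile], profile)
        return {prof: role for role, prof in seeds.items()}


def _component_from_dict(d: Mapping, model_name: str) -> ModelComponent:
    try:
        name = d["name"]
        status = d["status"]
    except KeyError as exc:
        raise ModelConfigError(
            f"model {model_name!r}: component missing key {exc}") from None
    return ModelComponent(
        name=name,
        status=status,
        loner=bool(d.get("loner", False)),
        exchangeable_with=frozenset(d.get("exchangeable_with", ())),
    )


def parse_models(source, registry: ProfileRegistry | None = None) -> list[SystemModel]:
    """Parse a YAML model-config file into validated :class:`SystemModel`.

    ``source`` is a path or an already-open text stream.  When a ``registry``
    is supplied, every component and exchangeable profile of non-generic
    models must be a registered profile name.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "models" not in doc:
        raise ModelConfigError("model config must be a mapping with a 'models' list")
    models = []
    for entry in doc["models"]:
        name = entry.get("name")
        if not name:
            raise ModelConfigError("model without a name")
        comps = [_component_from_dict(c, name) for c in entry.get("components", [])]
        try:
            model = SystemModel(
                name=name,
                components=comps,
                mmgr=int(entry["mmgr"]),
                mgr=int(entry["mgr"]),
                inter_gene_max_space=int(entry.get("inter_gene_max_space", 5)),
                multi_loci=bool(entry.get("multi_loci", False)),
            )
            model.profile_map()  # surfaces duplicate profile claims early
        except KeyError as exc:
            raise ModelConfigError(f"model {name!r}: missing key {exc}") from None
        if registry is not None and name != "generic":
            for comp in comps:
                for prof in (comp.name, *comp.exchangeable_with):
                    if prof not in registry:
                        raise ModelConfigError(
                            f"model {name!r}: profile {prof!r} not in registry")
        models.append(model)
    names = [m.name for m in models]
    if len(names) != len(set(names)):
        raise ModelConfigError("duplicate model names in config")
    return models


def write_models(models: Iterable[SystemModel], path) -> None:
    doc = {"models": []}
    for m in models:
        doc["models"].append({
            "name": m.name,
            "inter_gene_max_space": m.inter_gene_max_space,
            "mmgr": m.mmgr,
            "mgr": m.mgr,
            "multi_loci": m.multi_loci,
            "components": [
                {
                    "name": c.name,
                    "status": c.status,
                    "loner": c.loner,
                    "exchangeable_with": sorted(c.exchangeable_with),
                }
                for c in m.components
            ],
        })
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _packaged(name: str):
    return importlib.resources.files("tffscan").joinpath("models", name)


def load_packaged_models(which: str = "final",
                         registry: ProfileRegistry | None = None) -> list[SystemModel]:
    """Load the packaged ``final`` or ``initial`` model set."""
    if which not in ("final", "initial"):
        raise ValueError("which must be 'final' or 'initial'")
    with _packaged(f"{which}.yaml").open() as fh:
        return parse_models(fh, registry=registry)


def load_profile_registry() -> ProfileRegistry:
    with _packaged("profiles.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return ProfileRegistry(df[["profile_name", "role", "source_model"]].itertuples(index=False, name=None))


def parse_gene_table(path) -> GeneTable:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "replicon_id": str,
                                            "gene_id": str, "strand": str})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise GeneTableError(f"gene table missing column(s) {missing}")
    records = [
        GeneRecord(
            genome_id=row.genome_id,
            replicon_id=row.replicon_id,
            topology=row.topology,
            replicon_kind=row.replicon_kind,
            position=int(row.position),
            strand=row.strand,
            gene_id=row.gene_id,
        )
        for row in df.itertuples(index=False)
    ]
    return GeneTable(records)


def write_gene_table(table: GeneTable, path) -> None:
    df = pd.DataFrame([r.__dict__ for r in table.records], columns=GENE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def parse_hit_table(path, registry: ProfileRegistry | None = None) -> list[ComponentHit]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "profile_name": str})
    missing = [c for c in HIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise HitError(f"hit table missing column(s) {missing}")
    hits = []
    for row in df.itertuples(index=False):
        if registry is not None and row.profile_name not in registry:
            raise HitError(f"unregistered profile {row.profile_name!r}")
        hits.append(ComponentHit(row.gene_id, row.profile_name,
                                 float(row.e_value), float(row.score)))
    return hits


def write_hit_table(hits: Iterable[ComponentHit], path) -> None:
    df = pd.DataFrame([h.__dict__ for h in hits], columns=HIT_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def resolve_hits(hits: Iterable[ComponentHit],
                 max_evalue: float = DEFAULT_MAX_EVALUE,
                 gene_table: GeneTable | None = None) -> dict[str, ComponentHit]:
    """Keep one best annotation per gene.

    Hits above ``max_evalue`` are discarded.  Among survivors, the hit with
    the smallest e-value wins; ties break on higher score, then on the
    lexicographically smaller profile name, making the result independent of
    input row order.
    """
    if max_evalue <= 0:
        raise ValueError("max_evalue must be positive")
    best: dict[str, ComponentHit] = {}
    for hit in hits:
        if gene_table is not None and hit.gene_id not in gene_table:
            raise HitError(f"hit references unknown gene_id {hit.gene_id!r}")
        if hit.e_value > max_evalue:
            continue
        cur = best.get(hit.gene_id)
        if cur is None:
            best[hit.gene_id] = hit
            continue
        key_new = (hit.e_value, -hit.score, hit.profile_name)
        key_cur = (cur.e_value, -cur.score, cur.profile_name)
        if key_new < key_cur:
            best[hit.gene_id] = hit
    return best
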