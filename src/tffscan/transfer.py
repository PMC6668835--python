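"""Horizontal-transfer summaries from reconciliation event counts.

Reconciling each system-type subtree with a 16S rRNA reference tree yields
counts of duplication, transfer and loss (DTL) events.  The per-type
transfer proportion is the transfer count divided by the number of branches
of the system subtree (rooted convention: a rooted binary tree on L leaves
has 2L - 2 branches; an unrooted convention is available via ``n_branches``
suppliers).  These proportions are juxtaposed with the fraction of systems
encoded in a single locus and the fraction encoded entirely on chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .detection import DetectedSystem

__all__ = [
    "ReconciliationEvents",
    "TransferSummary",
    "transfer_proportion",
    "locus_replicon_summary",
    "parse_event_table",
    "write_event_table",
    "summarize",
]

EVENT_COLUMNS = ["system_type", "transfers", "duplications", "losses", "branches"]


@dataclass(frozen=True)
class ReconciliationEvents:
    system_type: str
    n_transfers: int
    n_duplications: int
    n_losses: int
    n_branches: int

    def __post_init__(self):
        for name in ("n_transfers", "n_duplications", "n_losses"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.system_type}: negative {name}")
        if self.n_branches < 1:
            raise ValueError(f"{self.system_type}: n_branches must be >= 1")


@dataclass(frozen=True)
class TransferSummary:
    system_type: str
    transfer_proportion: float
    single_locus_proportion: float
    chromosome_proportion: float


def transfer_proportion(events: ReconciliationEvents) -> float:
    """Transfers per branch of the system subtree."""
    return events.n_transfers / events.n_branches


def locus_replicon_summary(systems: Iterable[DetectedSystem],
                           ) -> tuple[float, float]:
    """(single-locus fraction, all-loci-on-chromosome fraction).

    A system touching any plasmid replicon counts as plasmid-borne.
    Replicon kinds are read from the loci's member gene records, so the
    systems must carry a ``replicon_kinds`` attribute or be paired with a
    gene table via :func:`summarize`.
    """
    systems = list(systems)
    if not systems:
        raise ValueError("empty system list")
    single = sum(1 for s in systems if s.single_locus)
    on_chromosome = 0
    for s in systems:
        kinds = getattr(s, "replicon_kinds", None)
        if kinds is None:
            raise ValueError(
                f"system {s.system_id!r} lacks replicon kinds; use summarize()")
        if all(k == "chromosome" for k in kinds):
            on_chromosome += 1
    return single / len(systems), on_chromosome / len(systems)


def _attach_replicon_kinds(systems, gene_table):
    for s in systems:
        kinds = []
        for locus in s.loci:
            info = gene_table.replicon_info(s.genome_id, locus.replicon_id)
            kinds.append(info.replicon_kind)
        s.replicon_kinds = kinds
    return systems


def summarize(events: Iterable[ReconciliationEvents],
              systems: Iterable[DetectedSystem],
              gene_table) -> list[TransferSummary]:
    """Per-type transfer proportion with locus/replicon context."""
    systems = _attach_replicon_kinds(list(systems), gene_table)
    by_type: dict[str, list[DetectedSystem]] = {}
    for s in systems:
        by_type.setdefault(s.model_name, []).append(s)
    out = []
    for ev in sorted(events, key=lambda e: e.system_type):
        group = by_type.get(ev.system_type, [])
        if not group:
            continue
        single, chrom = locus_replicon_summary(group)
        out.append(TransferSummary(ev.system_type, transfer_proportion(ev),
                                   single, chrom))
    return out


def parse_event_table(path) -> list[ReconciliationEvents]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing column(s) {missing}")
    return [ReconciliationEvents(r.system_type, int(r.transfers),
                                 int(r.duplications), int(r.losses),
                                 int(r.branches))
            for r in df.itertuples(index=False)]


def write_event_table(events: Iterable[ReconciliationEvents], path) -> None:
    rows = [(e.system_type, e.n_transfers, e.n_duplications, e.n_losses,
             e.n_branches) for e in events]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)
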