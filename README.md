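# tffscan

Detection and comparative-genomics analysis of **type IV filament (TFF)
superfamily** systems — type IVa/IVb pili, Tad, T2SS, ComM, MSH and
archaeal type-IV-related pili — from gene-order tables and HMM-profile
hits. The package is aimed at comparative genomicists who want a tested,
scriptable version of the classic quorum/co-localisation detection logic
(MacSyFinder-style) together with the downstream phylogenetic plumbing:
profile-homology role groups, distance-based redundancy reduction,
paralogue dereplication, clade-based type reassignment, gene-organisation
graphs, neighbourhood enrichment and horizontal-transfer summaries.

## The model

A system type is declared by components with statuses
(mandatory/accessory/forbidden), loner and exchangeable flags, a
co-localisation distance `d` (max intervening genes between consecutive
components), and the quorum thresholds MMGR/MGR. A candidate cluster
`C` with distinct component sets `M(C)` (mandatory) and `A(C)` (accessory)
is validated iff

```
|M(C)| >= MMGR   and   |M(C)| + |A(C)| >= MGR
```

and no forbidden component lies inside the cluster span. Loner components
are collected genome-wide; `multi_loci` models may pool sub-quorum
clusters into one multi-locus system. A *generic* model accepts any
remaining cluster with an ATPase, an IM platform and a major pilin, where
the role groups are the connected components of the reciprocal
profile-similarity graph (both directional p-values < 0.001).

Redundancy reduction fuses per-component patristic matrices
(min over paralogues, normalised by total tree length, averaged over
shared components), builds a BioNJ tree, roots it at the midpoint, cuts it
into a target number of groups by node height, and picks one
representative per group (validated first, then fewest paralogues).
Neighbourhood enrichment is a two-sided Fisher exact test per
(gene family, system type) with Bonferroni correction and an enrichment
direction filter. Transfer rates are transfers per branch of each type's
system subtree.

Everything runs on synthetic data from `tffscan.synthetic_data`, which
plants systems obeying the packaged models, decoy hits that cannot
assemble into systems, separable component-tree groups and planted
enrichment effects. See `docs/methods.md` for the full model description
and design choices.

## Worked example

```python
from tffscan import detection, models_io, synthetic_data as sd

registry = models_io.load_profile_registry()
models = models_io.load_packaged_models("final", registry=registry)

cfg = sd.SimulationConfig(seed=1, n_genomes=20)
sim = sd.simulate_genomes(cfg, models=models, registry=registry)
resolved = models_io.resolve_hits(sim.hits, gene_table=sim.gene_table)
systems = detection.detect_systems(sim.gene_table, resolved, models,
                                   registry=registry)
print(len(sim.truth), "planted /", len(systems), "detected")
for s in systems[:3]:
    print(s.system_id, len(s.loci), "locus/loci,",
          s.mandatory_count, "mandatory,", s.total_count, "total")
```

prints

```
20 planted / 20 detected
g0000::Tad::1 1 locus/loci, 7 mandatory, 7 total
g0001::T4aP::1 1 locus/loci, 8 mandatory, 8 total
g0002::T2SS::1 1 locus/loci, 6 mandatory, 6 total
```

i.e. every planted system is recovered under its planted model, and the
first three systems (a Tad, a T4aP and a T2SS) each sit in one locus with
their full mandatory complement (cluster genes plus loner genes such as
the prepilin peptidase).

The same workflow is available from the shell:

```
tffscan simulate genomes --seed 1 --n-genomes 20 --out sim/
tffscan detect --genes sim/genes.tsv --hits sim/hits.tsv --out systems.tsv
tffscan neighborhood --systems systems.tsv --genes sim/genes.tsv \
    --hits sim/hits.tsv --simil edges.tsv --out enrichment.tsv
```

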