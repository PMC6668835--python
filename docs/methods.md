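# Methods

`tffscan` re-implements, as a tested library, a comparative-genomics
workflow for the type IV filament (TFF) superfamily — the homologous family
of bacterial and archaeal machines comprising type IVa and IVb pili (T4aP,
T4bP), the tight-adherence pilus (Tad), the type II secretion system
(T2SS), the competence pilus of monoderms (ComM), the mannose-sensitive
hemagglutinin pilus (MSH) and the archaeal type-IV-related pili
(Archaeal-T4P). All stages run on synthetic data with the statistical and
combinatorial structure the analysis assumes; no sequences are handled.

## System models and detection

A *system model* declares, for one system type, its components and the
rules validating a candidate occurrence:

* component statuses: **mandatory** (ubiquitous, easy to identify),
  **accessory** (frequently absent or easily missed), **forbidden**
  (discriminates against closely related systems);
* **loner** components may be encoded away from the main cluster and are
  collected genome-wide;
* **exchangeable** profiles: a component may be detected by homologous
  profiles from other system types (e.g. the prepilin peptidases
  pilD/gspO/comC stand in for each other);
* quorum thresholds **MMGR** (minimum mandatory genes required) and **MGR**
  (minimum mandatory+accessory genes required);
* `inter_gene_max_space`: the maximum number of intervening genes between
  consecutive components of a cluster (a gene count, not a nucleotide
  distance — which is why gene positions are 0-based ranks throughout);
* `multi_loci`: whether one system may be encoded in several separated
  clusters.

Detection clusters the component-annotated genes of each replicon into
maximal runs with gaps `<= inter_gene_max_space` (measured on the shorter
arc of circular replicons), discards any locus whose span contains a gene
annotated to a forbidden component, attaches loner annotations, and
accepts a candidate iff it carries `>= MMGR` distinct mandatory and
`>= MGR` distinct mandatory+accessory components. Duplicated components
are retained in the assignment but count once towards the quorum. One best
profile annotation is kept per gene (smallest e-value, then highest score,
then lexicographic profile name; e-value ceiling 1e-3 by default, exposed
as a parameter because no reporting threshold is documented for the
original profiles).

Choices made where the procedure was genuinely open:

* **Quorum conjunction.** The quorum is MMGR AND MGR (both must hold).
* **multi_loci semantics.** Loci that satisfy the quorum on their own
  become single-locus systems; only the remaining loci pool (with the
  loners) into at most one multi-locus system. Pooling everything
  unconditionally would fuse independent complete systems that share a
  replicon. Loners alone never constitute a system.
* **Conflict resolution.** Specific models win over the generic one; among
  accepted specific candidates competing for genes, precedence goes to
  more distinct components, then smaller genomic span, then replicon and
  position order. Cluster genes are consumed by an accepted system; loner
  genes may be shared between co-detected systems (prepilin peptidases
  really are shared in vivo).
* **Forbidden-gene test.** A locus is excluded when a forbidden-annotated
  gene lies within its span (wrap-aware on circular replicons).

The packaged model sets (`models/initial.yaml`, `models/final.yaml`)
encode the six initial (conservative) and eight final (relaxed)
definitions with the documented quorum values — T4aP 8/8 initial and 4/5
final, T2SS MGR 8 initial and 4/5 final, ComM 3/5 initial and 4/4 final
with inter-gene distance 5, Archaeal 4/4 initial and 3/3 final, T4bP 4/4,
MSH 3/4 with mandatory mshA/mshE/mshG/mshL/mshM. Where a roster or quorum
value is not documented (Tad quorum, several accessory lists), a single
reasonable choice was made from the component tables and kept fixed.

The **generic** model identifies divergent or chimeric systems: any
cluster carrying at least one ATPase-role, one IM-platform-role and one
major-pilin-role gene (whatever the source profiles), evaluated only on
genes not consumed by specific systems. Its role groups are the connected
components of the profile-similarity graph.

## Profile-homology graph

Profile–profile alignment edges carry a p-value in each direction; an edge
is significant only if **both** p-values are strictly below alpha (default
0.001) — reciprocity is required because the directionality convention of
the underlying aligner is asymmetric and a one-sided hit is weak evidence.
Connected components inherit the role of their seeded members; components
seeded with conflicting roles are flagged rather than silently merged.

## Tree primitives

* **BioNJ** (variance-weighted neighbour joining): agglomeration with the
  pair-choice criterion of plain NJ, branch estimates
  `b_i = d_ij/2 + (S_i - S_j)/(2(r-2))`, and reduction weights
  `lambda = 1/2 + sum_k(V_jk - V_ik) / (2(r-2) V_ij)` clamped to [0, 1],
  where V is the variance matrix (initialised to the distances). Negative
  branch estimates are clamped to zero with the length moved to the
  sibling branch (standard NJ practice). Plain NJ (`neighbor_joining`) is
  a flagged fallback; both are exact on additive matrices.
* **Midpoint rooting** places the root halfway along the longest
  leaf-to-leaf path; ties break on the lexicographically smallest leaf
  pair, making the result deterministic.
* **Tree cutting.** The trees here are not ultrametric, so a node's
  *height* is defined as the maximum patristic distance to its descendant
  leaves. Cutting at height h returns the leaf sets of the maximal nodes
  with height `<= h`; the group count is a step function of h, changing
  only at node heights and non-increasing in h.
  `find_cut_for_group_count` scans the node heights from the root down and
  returns the first height within the target window, or the height whose
  count is closest above the lower bound, flagged, when the window is
  skipped over.
* **Clade-based reassignment.** Generic leaves inside a maximal clade
  whose non-generic leaves all share one type, and which contains at least
  one experimentally validated leaf of that type, adopt the type; generic
  leaves in mixed or unvalidated clades are left unassigned. The operation
  never changes a typed leaf and is idempotent.

## Redundancy reduction

Per component, the protein-level patristic matrix is collapsed to systems
by the minimum distance over paralogous copies. Because component families
evolve at different rates, each system-level matrix is normalised by the
total branch length of its component tree before averaging. The average
runs over the components in which **both** systems of a pair appear
(no imputation — how absent components, e.g. secretins in monoderms,
should enter the average is undefined); pairs sharing no component are
flagged and refuse to feed downstream steps silently.

Representatives are picked per group of the cut BioNJ tree: validated
systems first, then fewest paralogous components, then smallest system id.
Group-count bounds are parameters (`gmin`/`gmax`) so desk-scale analyses
can use small targets where a genome-scale run would use 200–300; an
optional per-type re-cut pass subdivides a type's subtree when it ends up
with fewer than `min_per_type` systems (default 20 in the CLI).

"Complex" systems — every core component duplicated, or generic systems
whose components match profiles of two or more specific types — are
removed before selection.

**Dereplication** reduces a kept system to one protein per component: for
each multi-copy component the nearest system carrying a single copy of it
is found — measured on the ATPase tree when the focal system's ATPase is
single-copy, otherwise on the IM-platform tree — and the copy closest to
that neighbour's single copy is retained. Ties break lexicographically.

## Genetic organisation

For the systems of one type, components are linked when some gene of one
is immediately followed (next gene rank; wrap-aware) by a gene of the
other. Contiguity is ordered along the gene order and counted at most once
per system per ordered pair. Two normalisations are reported per edge:
contiguous systems divided by the occurrences of the rarer component
(edge width), and contiguous systems divided by all systems of the type
(edge colour). Both lie in [0, 1]; strand is ignored.

## Neighbourhood enrichment

For every detected locus the genes within w positions of the locus bounds
(default 10; a ±20 variant is a flag) are collected, excluding system
members and any profile-matched gene. Flanking genes are clustered into
families by single-linkage on identity edges at a 50% threshold
(transitive, SiLiX-style); families seen in fewer than two systems are
dropped. Each (family, type) pair is tested with a two-sided Fisher exact
test on the 2x2 table of system counts (presence x focal-type vs others),
Bonferroni-corrected over all tests performed; an association is *kept*
when the family is enriched (higher presence rate in the focal type) and
the corrected p-value is below 0.05. The two-sided test plus a direction
post-filter was preferred over a one-sided test (available as a mode) so
that significant depletions are visible but never kept.

## Transfer summaries

Reconciliation of each type's system subtree against a 16S rRNA reference
yields duplication/transfer/loss counts; the reconciliation itself is an
input table (its computation is out of scope), while tree pruning for the
reference (16S tree restricted to the species of the system tree) is
provided by `tree_ops.prune_to_leaves`. The transfer proportion is
transfers divided by the branch count of the system subtree; branches are
counted on the rooted convention (2L−2 for a rooted binary tree on L
leaves) — the unrooted convention is obtained by passing that count
instead. These proportions are juxtaposed with the fraction of single-locus
systems and the fraction of systems encoded entirely on chromosomes (a
system touching any plasmid counts as plasmid-borne).

## Synthetic data: what it emulates, and what it does not

`simulate_genomes` builds circular chromosomes (200 genes by default, one
genome per planted system; plasmids of ≥40 genes when requested) and
plants systems that satisfy their model by construction: all non-loner
mandatory components contiguous, mandatory loners isolated elsewhere.
Scattered (multi-locus) plants omit loners and split the mandatory
components into two sub-quorum clusters separated by more than the
co-localisation distance. Decoy hits are placed isolated (more than
`inter_gene_max_space` from any other hit), drawn only from non-loner
ATPase/IM-platform profiles (at most two roles, so the generic three-role
rule is out of reach) and never from profiles of the models planted in the
same genome — otherwise stray decoys would pool with planted loners under
a multi-locus model and manufacture a quorum. Hit e-values are log-uniform
(1e-20–1e-12 for planted, 1e-8–1e-4 for decoys), with optional
above-threshold noise hits to exercise filtering.

`simulate_component_trees` attaches per-group caterpillar clades (branch
scale 0.02) to a star backbone (stem scale 1.0, i.e. 50x separation), one
type and one validated leader per group, paralogous copies as
near-duplicate cherry leaves. `simulate_enrichment` draws family presence
per system from a per-type probability table (null 0.2) and serialises it
as identity-edge chains at 80% identity with sub-threshold 30% edges
between families.

What passing on these data does **not** show: robustness to erosion
(partially deleted loci), overlapping or nested systems, annotation noise
correlated with genomic context, non-separable phylogenetic groups, or
families whose presence is phylogenetically autocorrelated rather than
independent across systems. The generators produce clean instances of the
structures the rules are defined on; they validate the machinery, not its
behaviour on degraded real genomes.

## Numerical notes and limitations

* Distance matrices must be exactly symmetric (tolerance 1e-12) with zero
  diagonals; BioNJ raises on violations rather than symmetrising.
* Patristic round-trips are exact to ~1e-15 on additive inputs; the test
  tolerance is 1e-8.
* All tie-breaks (hit resolution, midpoint pairs, representative picks,
  dereplication copies, detection precedence) are deterministic and
  documented at the function level; outputs are invariant to input row
  order.
* Problem sizes in the test and acceptance runs — 100 planted plus 100
  decoy genomes of 200 genes, 12 groups x 4 systems, 500 null and 200
  effect enrichment replicates, Fisher tables up to total 30 — were chosen
  as the smallest scales at which every property is non-trivially
  exercised; all scale linearly if enlarged.
* The per-type re-cut pass (`min_per_type`) re-partitions a type's systems
  on the pruned global tree rather than interleaving global and local
  cuts; the exact interleaving is unspecified in the source procedure.
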