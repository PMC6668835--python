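"""Clustering, quorum evaluation and end-to-end system detection."""

import itertools

import pytest

from tffscan.detection import (
    CandidateLocus,
    cluster_colocalized_hits,
    detect_systems,
    evaluate_candidate,
)
from tffscan.models_io import (
    ComponentHit,
    GeneRecord,
    GeneTable,
    ModelComponent,
    SystemModel,
    resolve_hits,
)
from tffscan import synthetic_data as sd

from conftest import linear_chromosome


def annotations_at(table, positions_components, genome="g0", replicon="r0"):
    genes = table.replicon_genes(genome, replicon)
    return [(genes[p], comp) for p, comp in positions_components]


def toy_model(max_space=5, mmgr=2, mgr=3, multi_loci=False):
    comps = [
        ModelComponent("m1", "mandatory"),
        ModelComponent("m2", "mandatory"),
        ModelComponent("m3", "mandatory"),
        ModelComponent("a1", "accessory"),
        ModelComponent("a2", "accessory"),
        ModelComponent("f1", "forbidden"),
    ]
    return SystemModel("toy", comps, mmgr=mmgr, mgr=mgr,
                       inter_gene_max_space=max_space, multi_loci=multi_loci)


class TestClustering:
    def test_single_run(self):
        table = linear_chromosome(40)
        loci = cluster_colocalized_hits(
            annotations_at(table, [(10, "m1"), (12, "m2"), (13, "m3")]),
            table, toy_model())
        assert len(loci) == 1
        assert [m[0] for m in loci[0].members] == [10, 12, 13]

    def test_split_on_large_gap(self):
        table = linear_chromosome(40)
        loci = cluster_colocalized_hits(
            annotations_at(table, [(10, "m1"), (30, "m2")]), table, toy_model())
        assert len(loci) == 2

    def test_circular_wrap_matches_brute_force(self):
        # brute force: enumerate circular gaps between annotated positions
        size = 100
        table = linear_chromosome(size, topology="circular")
        positions = [0, 99]
        loci = cluster_colocalized_hits(
            annotations_at(table, [(0, "m1"), (99, "m2")]), table, toy_model())
        lin = abs(positions[1] - positions[0]) - 1
        wrap = size - abs(positions[1] - positions[0]) - 1
        assert min(lin, wrap) == 0  # the shorter arc has no intervening gene
        assert len(loci) == 1
        assert loci[0].wraps
        assert [m[0] for m in loci[0].members] == [99, 0]

    def test_circular_runs_brute_force_random(self):
        import numpy as np
        rng = np.random.default_rng(7)
        model = toy_model(max_space=2)
        for _ in range(30):
            size = int(rng.integers(12, 30))
            k = int(rng.integers(1, 7))
            positions = sorted(rng.choice(size, size=k, replace=False).tolist())
            table = linear_chromosome(size, topology="circular")
            loci = cluster_colocalized_hits(
                annotations_at(table, [(p, "m1") for p in positions]),
                table, model)
            # oracle: count breaks (circular gaps > max_space)
            gaps = [(positions[(i + 1) % k] - positions[i] - 1) % size
                    for i in range(k)] if k > 1 else []
            n_breaks = sum(1 for g in gaps if g > model.inter_gene_max_space)
            expected = n_breaks if n_breaks > 0 else 1
            assert len(loci) == expected, (size, positions)
            assert sorted(p for l in loci for p, _, _ in l.members) == positions

    def test_empty_input(self):
        table = linear_chromosome(10)
        assert cluster_colocalized_hits([], table, toy_model()) == []


class TestQuorum:
    def test_msh_final_locus_accepted(self, final_models):
        msh = next(m for m in final_models if m.name == "MSH")
        locus = CandidateLocus("MSH", "r0", tuple(
            (i, f"x{i}", c) for i, c in enumerate(
                ["MSH_mshE", "MSH_mshG", "MSH_mshM"])))
        out = evaluate_candidate([locus], [("y0", "MSH_mshA")], msh)
        assert len(out.systems) == 1
        assert out.systems[0].mandatory_count == 4
        assert out.systems[0].total_count == 4

    def test_forbidden_gene_rejects_locus(self):
        model = toy_model()
        table = linear_chromosome(20)
        locus = CandidateLocus("toy", "r0", ((0, "x0", "m1"), (1, "x1", "m2"),
                                             (3, "x3", "m3"), (4, "x4", "a1")))
        out = evaluate_candidate([locus], [], model,
                                 forbidden=[("r0", 2)], gene_table=table,
                                 genome_id="g0")
        assert not out.systems
        assert out.rejections[0].reason == "forbidden"

    def test_below_mmgr(self):
        model = toy_model(mmgr=3, mgr=4)
        locus = CandidateLocus("toy", "r0", ((0, "x0", "m1"), (1, "x1", "m2"),
                                             (2, "x2", "a1"), (3, "x3", "a2")))
        out = evaluate_candidate([locus], [], model)
        assert not out.systems
        assert out.rejections[0].reason == "below_mmgr"

    def test_multi_locus_pooling(self):
        comps = [ModelComponent(f"m{i}", "mandatory") for i in range(1, 5)]
        comps += [ModelComponent("a1", "accessory")]
        model = SystemModel("toy", comps, mmgr=4, mgr=5,
                            inter_gene_max_space=5, multi_loci=True)
        locus_a = CandidateLocus("toy", "r0", ((0, "x0", "m1"), (1, "x1", "m2"),
                                               (2, "x2", "m3")))
        locus_b = CandidateLocus("toy", "r0", ((20, "x20", "m4"), (21, "x21", "a1")))
        out = evaluate_candidate([locus_a, locus_b], [], model)
        assert len(out.systems) == 1
        assert len(out.systems[0].loci) == 2
        assert out.systems[0].mandatory_count == 4
        assert out.systems[0].total_count == 5

    def test_duplicated_components_count_once(self):
        model = toy_model(mmgr=3, mgr=3)
        locus = CandidateLocus("toy", "r0", ((0, "x0", "m1"), (1, "x1", "m1"),
                                             (2, "x2", "m2")))
        out = evaluate_candidate([locus], [], model)
        assert not out.systems  # m1 twice still counts once
        assert out.rejections[0].reason == "below_mmgr"

    def test_exhaustive_truth_table_vs_oracle(self):
        """All 64 composition subsets of the 6-component toy model match a
        direct application of the forbidden + quorum rules."""
        model = toy_model(mmgr=2, mgr=3)
        comps = ["m1", "m2", "f1", "m3", "a1", "a2"]  # forbidden mid-span
        table = linear_chromosome(10)
        for mask in itertools.product([0, 1], repeat=6):
            present = [c for c, m in zip(comps, mask) if m]
            positions = {c: i for i, c in enumerate(comps) if c in present}
            cluster = [(positions[c], f"x{positions[c]}", c)
                       for c in present if c != "f1"]
            forbidden = [("r0", positions["f1"])] if "f1" in present else []
            loci = ([CandidateLocus("toy", "r0", tuple(cluster))]
                    if cluster else [])
            out = evaluate_candidate(loci, [], model, forbidden=forbidden,
                                     gene_table=table, genome_id="g0")
            # oracle: direct rule application
            span = ([p for p, _, _ in cluster] or [None])
            f_inside = ("f1" in present and cluster
                        and min(span) <= positions["f1"] <= max(span))
            mand = len({c for c in present if c.startswith("m")})
            total = mand + len({c for c in present if c.startswith("a")})
            expect_accept = (bool(cluster) and not f_inside
                             and mand >= 2 and total >= 3)
            assert bool(out.systems) == expect_accept, present
            if cluster and not expect_accept:
                reason = out.rejections[0].reason
                if f_inside:
                    assert reason == "forbidden"
                elif mand < 2:
                    assert reason == "below_mmgr"
                else:
                    assert reason == "below_mgr"


class TestDetectSystems:
    def _detect(self, sim, models, registry):
        resolved = resolve_hits(sim.hits, gene_table=sim.gene_table)
        return detect_systems(sim.gene_table, resolved, models, registry=registry)

    def test_planted_tad_detected(self, final_models, registry):
        cfg = sd.SimulationConfig(seed=11, n_genomes=1,
                                  plant_plan=[sd.PlantSpec("Tad")])
        sim = sd.simulate_genomes(cfg)
        systems = self._detect(sim, final_models, registry)
        assert [s.model_name for s in systems] == ["Tad"]
        assert len(systems[0].loci) == 1

    def test_generic_cluster_detected(self, final_models, registry):
        cfg = sd.SimulationConfig(seed=12, n_genomes=1,
                                  plant_plan=[sd.PlantSpec("generic")])
        sim = sd.simulate_genomes(cfg)
        systems = self._detect(sim, final_models, registry)
        assert [s.model_name for s in systems] == ["generic"]
        assert systems[0].components() >= {"atpase", "im_platform", "major_pilin"}

    def test_decoy_only_genomes_empty(self, final_models, registry):
        cfg = sd.SimulationConfig(seed=13, n_genomes=10, plant_plan=[],
                                  decoy_hit_rate=0.05)
        sim = sd.simulate_genomes(cfg)
        assert not sim.truth
        assert self._detect(sim, final_models, registry) == []

    def test_scattered_multi_locus_system(self, final_models, registry):
        cfg = sd.SimulationConfig(seed=14, n_genomes=1,
                                  plant_plan=[sd.PlantSpec("T4aP", scatter=True)])
        sim = sd.simulate_genomes(cfg)
        systems = self._detect(sim, final_models, registry)
        assert [s.model_name for s in systems] == ["T4aP"]
        assert len(systems[0].loci) == 2
        assert not systems[0].single_locus

    def test_row_order_determinism(self, final_models, registry):
        cfg = sd.SimulationConfig(seed=15, n_genomes=4)
        sim = sd.simulate_genomes(cfg)
        resolved = resolve_hits(sim.hits, gene_table=sim.gene_table)
        resolved_rev = resolve_hits(list(reversed(sim.hits)),
                                    gene_table=sim.gene_table)
        a = detect_systems(sim.gene_table, resolved, final_models, registry=registry)
        b = detect_systems(sim.gene_table, resolved_rev, final_models,
                           registry=registry)
        assert [(s.system_id, sorted(s.gene_ids())) for s in a] == \
               [(s.system_id, sorted(s.gene_ids())) for s in b]

    def test_monotonicity_of_extra_hits(self):
        """Adding a non-forbidden component never breaks acceptance; adding a
        forbidden hit inside the locus always rejects it."""
        model = toy_model(mmgr=2, mgr=3)
        table = linear_chromosome(20)
        base = [(0, "x0", "m1"), (1, "x1", "m2"), (2, "x2", "a1")]
        out = evaluate_candidate([CandidateLocus("toy", "r0", tuple(base))],
                                 [], model)
        assert out.systems
        richer = base + [(3, "x3", "a2")]
        out2 = evaluate_candidate([CandidateLocus("toy", "r0", tuple(richer))],
                                  [], model)
        assert out2.systems
        out3 = evaluate_candidate([CandidateLocus("toy", "r0", tuple(base))],
                                  [], model, forbidden=[("r0", 1)],
                                  gene_table=table, genome_id="g0")
        assert not out3.systems
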