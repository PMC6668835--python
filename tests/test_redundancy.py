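import numpy as np
import pytest

from tffscan.redundancy import (
    FusedDistance,
    SystemComponentMap,
    dereplicate,
    filter_complex_systems,
    fuse_matrices,
    select_representatives,
    system_distance,
)
from tffscan.tree_ops import DistanceMatrix
from tffscan import synthetic_data as sd, tree_ops as to


def random_symmetric(labels, rng, scale=1.0):
    n = len(labels)
    v = rng.uniform(0.1, scale, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    return DistanceMatrix(labels, v)


def scm(sid, copies, validated=False, stype="generic"):
    """SystemComponentMap with the given copy counts per role."""
    comps = {role: [f"{sid}|{role}|{k + 1}" for k in range(n)]
             for role, n in copies.items() if n > 0}
    return SystemComponentMap(sid, comps, validated=validated, type=stype)


class TestSystemDistance:
    def test_min_over_paralogues(self):
        dm = DistanceMatrix(["a1", "a2", "t1"],
                            np.array([[0, .1, .3], [.1, 0, .7], [.3, .7, 0]]))
        systems = [SystemComponentMap("S", {"atpase": ["a1", "a2"]}),
                   SystemComponentMap("T", {"atpase": ["t1"]})]
        out = system_distance(dm, systems, "atpase")
        assert out.get("S", "T") == pytest.approx(0.3)

    def test_single_copy_equals_protein_distance(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, .4], [.4, 0]]))
        systems = [SystemComponentMap("S", {"atpase": ["a"]}),
                   SystemComponentMap("T", {"atpase": ["b"]})]
        assert system_distance(dm, systems, "atpase").get("S", "T") == \
            pytest.approx(0.4)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            systems = [scm(f"s{i}", {"atpase": int(rng.integers(1, 4))})
                       for i in range(6)]
            labels = [l for s in systems for l in s.copies("atpase")]
            dm = random_symmetric(labels, rng)
            out = system_distance(dm, systems, "atpase")
            for a in systems:
                for b in systems:
                    if a.system_id == b.system_id:
                        continue
                    expected = min(dm.get(x, y) for x in a.copies("atpase")
                                   for y in b.copies("atpase"))
                    assert out.get(a.system_id, b.system_id) == \
                        pytest.approx(expected)

    def test_missing_label_rejected(self):
        dm = DistanceMatrix(["a"], np.zeros((1, 1)))
        with pytest.raises(ValueError, match="missing"):
            system_distance(dm, [SystemComponentMap("S", {"atpase": ["zz"]})],
                            "atpase")


class TestFuse:
    def test_normalised_average(self):
        m1 = DistanceMatrix(["S", "T"], np.array([[0, 1.0], [1.0, 0]]))
        m2 = DistanceMatrix(["S", "T"], np.array([[0, 1.0], [1.0, 0]]))
        fused = fuse_matrices({"atpase": m1, "im_platform": m2},
                              {"atpase": 10.0, "im_platform": 5.0})
        assert fused.averaged.get("S", "T") == pytest.approx(0.15)
        assert not fused.missing_pairs

    def test_system_missing_from_one_component(self):
        m1 = DistanceMatrix(["S", "T", "U"], np.array(
            [[0, 1, 2], [1, 0, 3], [2, 3, 0]], float))
        m2 = DistanceMatrix(["S", "T"], np.array([[0, 4.0], [4.0, 0]]))
        fused = fuse_matrices({"c1": m1, "c2": m2}, {"c1": 1.0, "c2": 2.0})
        # (S,U) averages over c1 only; (S,T) over both
        assert fused.averaged.get("S", "U") == pytest.approx(2.0)
        assert fused.averaged.get("S", "T") == pytest.approx((1.0 + 2.0) / 2)

    def test_identical_systems_zero_distance(self):
        m = DistanceMatrix(["S", "T"], np.zeros((2, 2)))
        fused = fuse_matrices({"c": m}, {"c": 3.0})
        assert fused.averaged.get("S", "T") == 0.0

    def test_no_shared_component_flagged(self):
        m1 = DistanceMatrix(["S"], np.zeros((1, 1)))
        m2 = DistanceMatrix(["T"], np.zeros((1, 1)))
        fused = fuse_matrices({"c1": m1, "c2": m2}, {"c1": 1.0, "c2": 1.0})
        assert fused.missing_pairs == [("S", "T")]
        with pytest.raises(ValueError, match="share no component"):
            fused.strict()

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        m1 = random_symmetric(["S", "T", "U"], rng)
        m2 = random_symmetric(["S", "T", "U"], rng)
        a = fuse_matrices({"x": m1, "y": m2}, {"x": 2.0, "y": 3.0})
        b = fuse_matrices({"y": m2, "x": m1}, {"y": 3.0, "x": 2.0})
        assert np.allclose(a.averaged.values, b.averaged.values)


class TestFilterComplex:
    def test_all_core_duplicated_removed(self):
        s = scm("dup", {"atpase": 2, "im_platform": 2, "major_pilin": 2})
        kept, removed = filter_complex_systems([s])
        assert not kept and removed == [s]

    def test_chimeric_generic_removed(self):
        s = SystemComponentMap("chim", {"atpase": ["a"], "im_platform": ["b"]},
                               type="generic",
                               profile_types={"atpase": {"T2SS"},
                                              "im_platform": {"T4aP"}})
        kept, removed = filter_complex_systems([s])
        assert removed == [s]

    def test_ordinary_system_kept(self):
        s = scm("ok", {"atpase": 1, "im_platform": 1, "major_pilin": 1},
                stype="Tad")
        kept, removed = filter_complex_systems([s])
        assert kept == [s]


class TestSelectRepresentatives:
    def _planted(self, rng, n_groups=12, per_group=3, eps=0.01):
        ids = [f"s{i:03d}" for i in range(n_groups * per_group)]
        n = len(ids)
        v = np.full((n, n), 10.0 * eps)
        for g in range(n_groups):
            sl = slice(g * per_group, (g + 1) * per_group)
            block = rng.uniform(0, eps, (per_group, per_group))
            block = (block + block.T) / 2
            v[sl, sl] = block
        # spread between-group distances so the backbone is tree-like enough
        for g in range(n_groups):
            for h in range(g + 1, n_groups):
                d = 10.0 * eps * (1 + 0.3 * abs(g - h))
                v[g * per_group:(g + 1) * per_group,
                  h * per_group:(h + 1) * per_group] = d
                v[h * per_group:(h + 1) * per_group,
                  g * per_group:(g + 1) * per_group] = d
        np.fill_diagonal(v, 0)
        groups = [frozenset(ids[g * per_group:(g + 1) * per_group])
                  for g in range(n_groups)]
        return DistanceMatrix(ids, v), groups

    def test_one_representative_per_planted_cluster(self):
        rng = np.random.default_rng(31)
        dm, groups = self._planted(rng)
        systems = [scm(sid, {"atpase": 1}) for sid in dm.labels]
        res = select_representatives(dm, systems, 12, 12)
        assert sorted(map(sorted, res.groups)) == sorted(map(sorted, groups))
        assert len(res.representatives) == 12

    def test_validated_beats_fewer_paralogues(self):
        rng = np.random.default_rng(32)
        dm, groups = self._planted(rng, n_groups=2, per_group=2)
        meta = {
            "s000": scm("s000", {"atpase": 2, "im_platform": 2}, validated=True),
            "s001": scm("s001", {"atpase": 1}),
            "s002": scm("s002", {"atpase": 1}),
            "s003": scm("s003", {"atpase": 2}),
        }
        res = select_representatives(dm, list(meta.values()), 2, 2)
        group_of = {frozenset(g): rep for g, rep in zip(res.groups, res.by_group)}
        assert group_of[frozenset({"s000", "s001"})] == "s000"  # validated wins
        assert group_of[frozenset({"s002", "s003"})] == "s002"  # fewest paralogues

    def test_priorities_match_bruteforce_selector(self):
        rng = np.random.default_rng(33)
        for _ in range(100):
            n_groups = int(rng.integers(2, 6))
            per_group = int(rng.integers(2, 5))
            dm, groups = self._planted(rng, n_groups, per_group)
            systems = [scm(sid, {"atpase": int(rng.integers(1, 4)),
                                 "im_platform": int(rng.integers(1, 3))},
                           validated=bool(rng.random() < 0.3))
                       for sid in dm.labels]
            meta = {s.system_id: s for s in systems}
            res = select_representatives(dm, systems, n_groups, n_groups)
            for group, rep in zip(res.groups, res.by_group):
                # brute force: filter validated if any, then min paralogues,
                # then smallest id
                pool = sorted(group)
                validated = [s for s in pool if meta[s].validated]
                if validated:
                    pool = validated
                best_n = min(meta[s].n_paralogues for s in pool)
                pool = [s for s in pool if meta[s].n_paralogues == best_n]
                assert rep == min(pool)

    def test_gmin_above_system_count_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
        systems = [scm("a", {"atpase": 1}), scm("b", {"atpase": 1})]
        with pytest.raises(ValueError):
            select_representatives(dm, systems, 5, 6)


class TestDereplicate:
    def test_keeps_copy_closest_to_anchor(self):
        labels = ["F|atpase|1", "F|pilin|1", "F|pilin|2",
                  "N|atpase|1", "N|pilin|1"]
        atp = DistanceMatrix(["F|atpase|1", "N|atpase|1"],
                             np.array([[0, .2], [.2, 0]]))
        pil = DistanceMatrix(["F|pilin|1", "F|pilin|2", "N|pilin|1"],
                             np.array([[0, .05, .2], [.05, 0, .5], [.2, .5, 0]]))
        focal = SystemComponentMap("F", {"atpase": ["F|atpase|1"],
                                         "pilin": ["F|pilin|1", "F|pilin|2"]})
        other = SystemComponentMap("N", {"atpase": ["N|atpase|1"],
                                         "pilin": ["N|pilin|1"]})
        out = dereplicate(focal, {"atpase": atp, "pilin": pil}, [focal, other])
        assert out == {"atpase": "F|atpase|1", "pilin": "F|pilin|1"}

    def test_single_copy_system_unchanged(self):
        focal = SystemComponentMap("F", {"atpase": ["F|atpase|1"]})
        atp = DistanceMatrix(["F|atpase|1"], np.zeros((1, 1)))
        assert dereplicate(focal, {"atpase": atp}, [focal]) == \
            {"atpase": "F|atpase|1"}

    def test_error_when_no_single_copy_neighbor(self):
        focal = scm("F", {"atpase": 1, "pilin": 2})
        other = scm("G", {"atpase": 1, "pilin": 2})
        labels = focal.copies("atpase") + other.copies("atpase")
        rng = np.random.default_rng(0)
        mats = {"atpase": random_symmetric(labels, rng),
                "pilin": random_symmetric(focal.copies("pilin")
                                          + other.copies("pilin"), rng)}
        with pytest.raises(ValueError, match="pilin"):
            dereplicate(focal, mats, [focal, other])

    def test_matches_exhaustive_search(self):
        """100 random instances: the kept copy and implied neighbour equal a
        full enumeration over copies x single-copy candidate systems."""
        rng = np.random.default_rng(41)
        roles = ["atpase", "im_platform", "major_pilin"]
        for _ in range(100):
            n_sys = int(rng.integers(3, 7))
            systems = []
            for i in range(n_sys):
                copies = {r: int(rng.integers(1, 4)) for r in roles}
                if i >= n_sys - 2:  # guarantee single-copy donors
                    copies = {r: 1 for r in roles}
                systems.append(scm(f"s{i}", copies))
            mats = {r: random_symmetric(
                [l for s in systems for l in s.copies(r)], rng)
                for r in roles}
            focal = systems[0]
            out = dereplicate(focal, mats, systems)
            ref_role = "atpase" if len(focal.copies("atpase")) == 1 \
                else "im_platform"
            ref = mats[ref_role]
            for role in roles:
                copies = focal.copies(role)
                if len(copies) == 1:
                    assert out[role] == copies[0]
                    continue
                cands = [s for s in systems[1:] if len(s.copies(role)) == 1]
                best = None
                for cand in sorted(cands, key=lambda s: s.system_id):
                    d_ref = min(ref.get(x, y)
                                for x in focal.copies(ref_role)
                                for y in cand.copies(ref_role))
                    if best is None or d_ref < best[0] - 1e-15:
                        best = (d_ref, cand)
                anchor = best[1].copies(role)[0]
                expected = min(sorted(copies),
                               key=lambda c: mats[role].get(c, anchor))
                assert out[role] == expected

    def test_invariant_to_copy_order(self):
        rng = np.random.default_rng(43)
        focal = scm("F", {"atpase": 1, "pilin": 3})
        donor = scm("N", {"atpase": 1, "pilin": 1})
        mats = {"atpase": random_symmetric(
            focal.copies("atpase") + donor.copies("atpase"), rng),
            "pilin": random_symmetric(
            focal.copies("pilin") + donor.copies("pilin"), rng)}
        out1 = dereplicate(focal, mats, [focal, donor])
        flipped = SystemComponentMap("F", {
            "atpase": focal.copies("atpase"),
            "pilin": list(reversed(focal.copies("pilin")))})
        out2 = dereplicate(flipped, mats, [flipped, donor])
        assert out1 == out2


def test_pipeline_on_simulated_trees():
    """End-to-end: simulated component trees -> fused matrix -> groups equal
    the planted partition, and dereplication returns one label per role."""
    cfg = sd.SimulationConfig(seed=8, paralogue_rate=0.25)
    sim = sd.simulate_component_trees(cfg)
    mats = {r: to.patristic_matrix(t) for r, t in sim.trees.items()}
    lens = {r: sd.tree_length(t) for r, t in sim.trees.items()}
    sysmats = {r: system_distance(mats[r], sim.systems, r) for r in mats}
    fused = fuse_matrices(sysmats, lens).strict()
    res = select_representatives(fused, sim.systems, cfg.n_groups, cfg.n_groups)
    assert sorted(map(sorted, res.groups)) == sorted(map(sorted, sim.groups))
    for s in sim.systems:
        if s.n_paralogues == 0:
            continue
        out = dereplicate(s, mats, sim.systems)
        assert set(out) == set(s.components)
        for role, label in out.items():
            assert label in s.copies(role)
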