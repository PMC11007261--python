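"""Representatives, UPGMA, Robinson–Foulds, and the congruence test."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from oracles import rf_normalized_dendropy

from phylosym.datamodel import FeatureTable
from phylosym.io import read_newick
from phylosym.phylosymbiosis import (phylosymbiosis_test,
                                     population_representatives,
                                     random_topology,
                                     robinson_foulds_normalized, upgma)
from phylosym.simulate import (SimulationConfig, simulate_communities,
                               simulate_host_tree)


class TestRepresentatives:
    def test_single_sample_population_is_identity(self):
        t = FeatureTable(("s1",), ("a", "b"), np.array([[3, 1]]))
        reps = population_representatives(t, {"s1": "P1"})
        assert np.allclose(reps.loc["P1"], [0.75, 0.25])

    def test_mean_of_opposite_profiles(self):
        t = FeatureTable(("s1", "s2"), ("a", "b"),
                         np.array([[5, 0], [0, 7]]))
        reps = population_representatives(t, {"s1": "P1", "s2": "P1"})
        assert np.allclose(reps.loc["P1"], [0.5, 0.5])

    def test_random_pick_selects_member(self):
        t = FeatureTable(("s1", "s2"), ("a", "b"),
                         np.array([[5, 0], [0, 7]]))
        reps = population_representatives(t, {"s1": "P1", "s2": "P1"},
                                          mode="random_pick", seed=3)
        assert (np.allclose(reps.loc["P1"], [1, 0])
                or np.allclose(reps.loc["P1"], [0, 1]))
        again = population_representatives(t, {"s1": "P1", "s2": "P1"},
                                           mode="random_pick", seed=3)
        assert np.allclose(reps.to_numpy(), again.to_numpy())


class TestUPGMA:
    def test_hand_agglomeration(self):
        dm = DistanceMatrix([[0, 2, 6], [2, 0, 6], [6, 6, 0]],
                            ids=list("ABC"))
        tree = upgma(dm)
        # (A,B) join at height 1; C joins at height 3
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        assert all(d == pytest.approx(3.0) for d in depths.values())
        ab_parent = tree.find("A").parent
        assert {t.name for t in ab_parent.tips()} == {"A", "B"}
        assert tree.find("A").length == pytest.approx(1.0)
        assert tree.find("C").length == pytest.approx(3.0)

    def test_ultrametric_input_cophenetic_round_trip(self):
        host = simulate_host_tree(8, seed=3)
        coph = host.tip_tip_distances()
        tree = upgma(coph)
        back = tree.tip_tip_distances().filter(list(coph.ids))
        assert np.allclose(back.data, coph.data, atol=1e-9)

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(5)
        for rep in range(5):
            pts = rng.random((7, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            np.fill_diagonal(d, 0)
            dm = DistanceMatrix(d, ids=[f"L{i}" for i in range(7)])
            tree = upgma(dm)
            mine = tree.tip_tip_distances().filter(list(dm.ids)).data
            linked = average(squareform(d, checks=False))
            scipy_coph = squareform(cophenet(linked))
            assert np.allclose(mine, scipy_coph, atol=1e-9)

    def test_equal_distances_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(d, ids=list("DCBA"))
        t1, t2 = upgma(dm), upgma(dm)
        assert str(t1) == str(t2)
        heights = {t.accumulate_to_ancestor(t1) for t in t1.tips()}
        assert all(h == pytest.approx(0.5) for h in heights)


class TestRobinsonFoulds:
    def test_identical_topologies_zero(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = read_newick("((C:2,D:2):2,(B:2,A:2):2);")
        assert robinson_foulds_normalized(t1, t2) == 0.0

    def test_four_leaf_alternative_splits(self):
        ab_cd = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        ac_bd = read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds_normalized(ab_cd, ac_bd) == 1.0

    def test_leaf_set_mismatch_rejected(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = read_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValueError, match="differ"):
            robinson_foulds_normalized(t1, t2)

    def test_matches_dendropy_on_random_pairs(self):
        labels = [f"L{i}" for i in range(8)]
        for seed in range(30):
            t1 = random_topology(labels, seed=seed)
            t2 = random_topology(labels, seed=seed + 1000)
            mine = robinson_foulds_normalized(t1, t2)
            oracle = rf_normalized_dendropy(str(t1), str(t2))
            assert mine == pytest.approx(oracle, abs=1e-12)


class TestRandomTopology:
    def test_structure_and_determinism(self):
        labels = [f"L{i}" for i in range(6)]
        t = random_topology(labels, seed=4)
        assert sorted(x.name for x in t.tips()) == sorted(labels)
        assert str(t) == str(random_topology(labels, seed=4))
        # binary: n-1 internal nodes
        assert sum(1 for _ in t.non_tips(include_self=True)) == 5

    def test_uniform_over_four_leaf_topologies(self):
        """Each of the 3 unrooted 4-leaf topologies appears ~1/3."""
        refs = [read_newick(s) for s in (
            "((A:1,B:1):1,(C:1,D:1):1);",
            "((A:1,C:1):1,(B:1,D:1):1);",
            "((A:1,D:1):1,(B:1,C:1):1);")]
        counts = [0, 0, 0]
        for seed in range(10000):
            t = random_topology(list("ABCD"), seed=seed)
            rfs = [robinson_foulds_normalized(t, ref) for ref in refs]
            counts[int(np.argmin(rfs))] += 1
        for c in counts:
            assert abs(c / 10000 - 1 / 3) < 0.02

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            random_topology(["a", "b", "c"], seed=0)


class TestPhylosymbiosisTest:
    def test_cophenetic_input_recovers_host_topology(self):
        host = simulate_host_tree(8, seed=9)
        beta_dm = host.tip_tip_distances()
        res = phylosymbiosis_test(host, beta_dm, n_random=999, seed=1)
        assert res.rf_observed == 0.0
        assert res.p == pytest.approx(1 / 1000)

    def test_four_leaf_support(self):
        host = simulate_host_tree(4, seed=2)
        rng = np.random.default_rng(0)
        for rep in range(5):
            from conftest import random_distance_matrix

            dm = random_distance_matrix(4, rng,
                                        ids=[f"P{i+1:02d}" for i in range(4)])
            res = phylosymbiosis_test(host, dm, n_random=99, seed=rep)
            assert res.rf_observed in (0.0, 0.5, 1.0)

    def test_relabeling_invariance(self):
        host = simulate_host_tree(6, seed=5)
        from conftest import random_distance_matrix

        dm = random_distance_matrix(
            6, np.random.default_rng(3), ids=[f"P{i+1:02d}" for i in range(6)])
        res1 = phylosymbiosis_test(host, dm, n_random=199, seed=7)
        relabel = {f"P{i+1:02d}": f"Q{i+1:02d}" for i in range(6)}
        host2 = host.copy()
        for tip in host2.tips():
            tip.name = relabel[tip.name]
        dm2 = DistanceMatrix(dm.data, ids=[relabel[i] for i in dm.ids])
        res2 = phylosymbiosis_test(host2, dm2, n_random=199, seed=7)
        assert res1.rf_observed == res2.rf_observed
        assert res1.p == res2.p

    def test_host_tree_pruned_to_shared_populations(self):
        host = simulate_host_tree(10, seed=6)
        sub = [f"P{i+1:02d}" for i in range(6)]
        beta_dm = host.tip_tip_distances().filter(sub)
        res = phylosymbiosis_test(host, beta_dm, n_random=199, seed=0)
        assert res.rf_observed == 0.0

    def test_random_pick_mode_reports_replicates(self):
        cfg = SimulationConfig(n_populations=6, samples_per_population=3,
                               n_taxa=30, depth=500, sigma_phylo=2.0,
                               seed=12)
        ds = simulate_communities(cfg)
        mapping = {m.sample_id: m.population for m in ds.metadata}
        res = phylosymbiosis_test(ds.host_tree, table=ds.table,
                                  mapping=mapping, mode="random_pick",
                                  n_picks=10, n_random=199, seed=3)
        assert res.rf_replicates is not None
        assert len(res.rf_replicates) == 10
        assert res.rf_observed == pytest.approx(res.rf_replicates.mean())

    def test_random_trees_far_from_each_other(self):
        """Normalized RF between independent random 16-leaf trees
        concentrates near 1."""
        labels = [f"L{i}" for i in range(16)]
        vals = [robinson_foulds_normalized(random_topology(labels, seed=2 * k),
                                           random_topology(labels,
                                                           seed=2 * k + 1))
                for k in range(100)]
        assert np.mean(vals) > 0.9
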