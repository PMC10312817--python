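import itertools

import numpy as np
import pytest

from fibrasync import (Coloring, LocomotionNetwork, automorphisms, base_graph,
                       input_tree, is_balanced, minimal_balanced_coloring,
                       orbit_coloring, trees_isomorphic)
from fibrasync.partitioning import SizeLimitError


def brute_force_coarsest_check(network, coloring):
    """No merge of two cells of ``coloring`` stays balanced (coarsest)."""
    cells = coloring.cells
    for i, j in itertools.combinations(range(len(cells)), 2):
        merged = dict(coloring.mapping)
        for v in cells[j]:
            merged[v] = coloring.mapping[min(cells[i])]
        if is_balanced(network, Coloring(merged)):
            return False
    return True


class TestMinimalBalancedColoring:
    def test_edgeless_graph_is_one_cell(self):
        net = LocomotionNetwork()
        for i in range(5):
            net.add_node(f"n{i}")
        assert minimal_balanced_coloring(net).k == 1

    def test_planted_lift_recovered(self, lift_factory):
        net, planted = lift_factory(seed=7, sizes=(2, 3, 1))
        found = minimal_balanced_coloring(net)
        assert found.as_sets() == planted.as_sets()
        assert brute_force_coarsest_check(net, found)

    def test_output_is_balanced_on_random_lifts(self, lift_factory):
        for seed in range(25):
            net, _ = lift_factory(seed=seed)
            col = minimal_balanced_coloring(net)
            assert is_balanced(net, col)
            assert brute_force_coarsest_check(net, col)

    def test_weighted_and_binary_modes_can_differ(self):
        # two nodes with equal edge counts but unequal weights
        net = LocomotionNetwork()
        for v in "suv":
            net.add_node(v)
        net.add_edge("s", "u", 1, "chem")
        net.add_edge("s", "v", 2, "chem")
        assert minimal_balanced_coloring(net, weighted=True).k == 3
        assert minimal_balanced_coloring(net, weighted=False).k == 2


class TestIsBalanced:
    def test_singletons_always_balanced(self, lift_factory):
        net, _ = lift_factory()
        assert is_balanced(net, Coloring.singletons(net.nodes))

    def test_one_cell_unbalanced_with_unequal_in_degrees(self):
        net = LocomotionNetwork()
        for v in "ab":
            net.add_node(v)
        net.add_edge("a", "b", 1, "chem")
        assert not is_balanced(net, Coloring.trivial(net.nodes))

    def test_coloring_must_cover_nodes(self):
        net = LocomotionNetwork()
        net.add_node("a")
        net.add_node("b")
        with pytest.raises(Exception):
            is_balanced(net, Coloring({"a": 0}))


class TestInputTree:
    def test_depth_zero_single_root(self, toys):
        t = input_tree(toys["cyan_trail"], "C", 0)
        assert list(t.a) == [1]
        assert t.layers == [[("C", 0.0, -1)]]

    def test_two_cycle_single_walk_per_length(self):
        net = LocomotionNetwork()
        net.add_node("u")
        net.add_node("v")
        net.add_edge("u", "v", 1, "chem")
        net.add_edge("v", "u", 1, "chem")
        t = input_tree(net, "u", 5)
        assert list(t.a) == [1, 1, 1, 1, 1, 1]

    def test_layer_counts_from_weighted_in_degrees(self, toys):
        # layer-2 sources with weighted in-degrees {3, 4, 4} -> 11 walks
        t = input_tree(toys["layer_counts"], "R", 2)
        assert t.a[1] == 3
        assert t.a[2] == 11

    def test_unknown_node_and_negative_depth_rejected(self, toys):
        with pytest.raises(Exception):
            input_tree(toys["cyan_trail"], "Q", 2)
        with pytest.raises(Exception):
            input_tree(toys["cyan_trail"], "C", -1)


class TestTreeIsomorphism:
    def test_tree_isomorphic_to_itself(self, toys):
        t = input_tree(toys["cyan_trail"], "C", 2)
        assert trees_isomorphic(t, t)

    def test_different_layer_counts_not_isomorphic(self):
        def chain(k):
            net = LocomotionNetwork()
            for i in range(k + 1):
                net.add_node(f"c{i}")
            for i in range(k):
                net.add_edge(f"c{i}", f"c{i+1}", 1, "chem")
            return net

        t2 = input_tree(chain(2), "c2", 3)
        t3 = input_tree(chain(3), "c3", 3)
        assert not trees_isomorphic(t2, t3)

    def test_depth_mismatch_raises(self, toys):
        t1 = input_tree(toys["cyan_trail"], "C", 2)
        t2 = input_tree(toys["cyan_trail"], "C", 3)
        with pytest.raises(Exception):
            trees_isomorphic(t1, t2)

    def test_isomorphism_at_depth_n_minus_1_matches_fibers(self, lift_factory):
        for seed in range(8):
            net, planted = lift_factory(seed=seed)
            depth = net.n - 1
            trees = {v: input_tree(net, v, depth) for v in net.nodes}
            for u, v in itertools.combinations(net.nodes, 2):
                same_fiber = planted.mapping[u] == planted.mapping[v]
                assert trees_isomorphic(trees[u], trees[v]) == same_fiber


class TestBaseGraph:
    def test_singleton_coloring_is_identity(self, lift_factory):
        net, _ = lift_factory(seed=2)
        base = base_graph(net, Coloring.singletons(net.nodes))
        assert base == net

    def test_lift_collapses_to_generating_base(self, lift_factory):
        net, planted = lift_factory(seed=5)
        base = base_graph(net, planted)
        renamed = {(u.split(".")[0], v.split(".")[0], ch): w
                   for u, v, w, ch in base.edges()}
        expected = {("x", "y", "chem"): 2.0, ("y", "z", "chem"): 1.0,
                    ("z", "x", "chem"): 1.0, ("x", "x", "chem"): 1.0}
        assert renamed == expected

    def test_directed_square_collapses_to_self_loop(self):
        net = LocomotionNetwork()
        for i in range(4):
            net.add_node(f"s{i}")
        for i in range(4):
            net.add_edge(f"s{i}", f"s{(i+1) % 4}", 1, "chem")
        base = base_graph(net, Coloring.trivial(net.nodes))
        assert base.n == 1
        (u, v, w, ch), = base.edges()
        assert u == v and w == 1.0 and ch == "chem"

    def test_unbalanced_coloring_rejected(self):
        net = LocomotionNetwork()
        for v in "ab":
            net.add_node(v)
        net.add_edge("a", "b", 1, "chem")
        with pytest.raises(Exception):
            base_graph(net, Coloring.trivial(net.nodes))


class TestAutomorphisms:
    def test_asymmetric_weighted_path_identity_only(self):
        net = LocomotionNetwork()
        for v in "abc":
            net.add_node(v)
        net.add_edge("a", "b", 1, "chem")
        net.add_edge("b", "c", 2, "chem")
        auts = automorphisms(net)
        assert len(auts) == 1
        assert auts[0].mapping == {v: v for v in "abc"}

    def test_undirected_triangle_full_symmetric_group(self):
        net = LocomotionNetwork()
        for v in "xyz":
            net.add_node(v)
        for u, v in itertools.combinations("xyz", 2):
            net.add_edge(u, v, 1, "gap")
        auts = automorphisms(net)
        assert len(auts) == 6
        # brute force over all 3! permutations agrees
        from fibrasync.partitioning import Automorphism

        valid = [dict(zip("xyz", perm)) for perm in itertools.permutations("xyz")
                 if Automorphism(dict(zip("xyz", perm))).is_valid(net)]
        assert sorted(a.mapping.items() for a in auts) == sorted(
            v.items() for v in valid)

    def test_directed_four_cycle_cyclic_group(self):
        net = LocomotionNetwork()
        for i in range(4):
            net.add_node(f"c{i}")
        for i in range(4):
            net.add_edge(f"c{i}", f"c{(i+1) % 4}", 1, "chem")
        auts = automorphisms(net)
        assert len(auts) == 4
        assert all(a.is_valid(net) for a in auts)

    def test_node_limit_refusal(self):
        net = LocomotionNetwork()
        for i in range(5):
            net.add_node(f"n{i}")
        with pytest.raises(SizeLimitError):
            automorphisms(net, node_limit=4)


class TestOrbitColoring:
    def test_orbits_refine_fibers_everywhere(self, lift_factory, toys, locomotion):
        cases = [lift_factory(seed=s)[0] for s in range(4)]
        cases += [toys["fiber_vs_orbit_directed"],
                  toys["fiber_vs_orbit_undirected"], locomotion[0]]
        for net in cases:
            fib = minimal_balanced_coloring(net)
            orb = orbit_coloring(net)
            assert orb.refines(fib)
            assert is_balanced(net, orb)

    def test_counterexamples_have_strictly_more_orbits(self, toys):
        for name in ("fiber_vs_orbit_directed", "fiber_vs_orbit_undirected"):
            net = toys[name]
            assert orbit_coloring(net).k > minimal_balanced_coloring(net).k

    def test_directed_counterexample_orbits_by_brute_force(self, toys):
        from fibrasync.partitioning import Automorphism

        net = toys["fiber_vs_orbit_directed"]
        nodes = net.nodes
        parent = {v: v for v in nodes}

        def find(v):
            while parent[v] != v:
                v = parent[v]
            return v

        for perm in itertools.permutations(nodes):
            mapping = dict(zip(nodes, perm))
            if Automorphism(mapping).is_valid(net):
                for a, b in mapping.items():
                    parent[find(b)] = find(a)
        brute = {frozenset(n for n in nodes if find(n) == r)
                 for r in {find(v) for v in nodes}}
        assert orbit_coloring(net).as_sets() == brute
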