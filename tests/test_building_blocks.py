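import itertools

import numpy as np
import pytest

from fibrasync import (Coloring, LocomotionNetwork, branching_ratio,
                       classify_fbb, extract_circuit, extract_fbb,
                       minimal_balanced_coloring, trail_count)
from fibrasync.building_blocks import fiber_numbers
from fibrasync.partitioning import SizeLimitError


def brute_force_trails(edges, root):
    """Independent oracle: forward walk enumeration with explicit edge sets."""
    edges = [e for e in edges if e[0] != root]
    count = 0
    stack = [((e,), e[1]) for e in edges]
    while stack:
        used, head = stack.pop()
        if head == root:
            count += 1
            continue
        for e in edges:
            if e[0] == head and e not in used:
                stack.append((used + (e,), e[1]))
    return count


class TestTrailCount:
    def test_single_edge(self):
        net = LocomotionNetwork()
        net.add_node("u")
        net.add_node("v")
        net.add_edge("u", "v", 1, "chem")
        assert trail_count(net, "v") == 1

    def test_cyan_toy_has_six_trails(self, toys):
        assert trail_count(toys["cyan_trail"], "C") == 6

    def test_matches_brute_force_on_random_digraphs(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = 5
            edges = {(f"n{rng.integers(n)}", f"n{rng.integers(n)}")
                     for _ in range(rng.integers(3, 9))}
            edges = {(u, v) for u, v in edges if u != v}
            net = LocomotionNetwork()
            for i in range(n):
                net.add_node(f"n{i}")
            for u, v in edges:
                net.add_edge(u, v, 1, "chem")
            assert trail_count(net, "n0") == brute_force_trails(sorted(edges), "n0")

    def test_multiplicity_is_disregarded(self, toys):
        net = toys["cyan_trail"].copy()
        net.add_edge("M", "C", 3, "chem")  # heavier edge, same trail set
        assert trail_count(net, "C") == 6

    def test_edge_limit_refusal(self, toys):
        with pytest.raises(SizeLimitError):
            trail_count(toys["cyan_trail"], "C", edge_limit=2)


class TestBranchingRatio:
    def test_acyclic_block_is_zero(self, toys):
        net, expected = toys["fibonacci_bases"]["acyclic"]
        assert branching_ratio(net, "b") == expected == 0.0

    def test_unit_self_loop_is_one(self):
        net = LocomotionNetwork()
        net.add_node("s")
        net.add_edge("s", "s", 1, "chem")
        assert branching_ratio(net, "s") == pytest.approx(1.0, abs=1e-9)

    def test_fibonacci_bases_match_closed_forms(self, toys):
        for name, (net, expected) in toys["fibonacci_bases"].items():
            assert branching_ratio(net, "a") == pytest.approx(expected, abs=1e-9), name

    def test_golden_ratio_value(self, toys):
        net, _ = toys["fibonacci_bases"]["golden"]
        assert branching_ratio(net, "a") == pytest.approx((1 + np.sqrt(5)) / 2,
                                                          abs=1e-9)

    def test_two_node_integer_matrix_sweep_vs_eigenvalues(self):
        """All 2x2 integer adjacencies with entries <= 3: layer-limit value
        equals the dominant-eigenvalue magnitude; the Fibonacci flag marks
        exactly the non-integer ratios."""
        for m in itertools.product(range(4), repeat=4):
            a = np.array(m, dtype=float).reshape(2, 2)
            net = LocomotionNetwork()
            net.add_node("a")
            net.add_node("b")
            for (i, j), w in np.ndenumerate(a):
                if w:
                    net.add_edge("ab"[i], "ab"[j], int(w), "chem")
            expected = float(max(abs(np.linalg.eigvals(a))))
            got = branching_ratio(net, "a")
            # nodes not reaching 'a' are outside its in-component
            reaches = a[1, 0] > 0 or (a[0, 0] > 0 and False)
            sub = a if a[1, 0] > 0 else a[:1, :1]
            expected = float(max(abs(np.linalg.eigvals(sub))))
            if expected < 1e-6:
                expected = 0.0
            assert got == pytest.approx(expected, abs=1e-6), m


class TestExtractFbb:
    def test_isolated_fiber_block_is_fiber_only(self):
        net = LocomotionNetwork()
        for v in "pq":
            net.add_node(v)
        col = minimal_balanced_coloring(net)  # single cell, no edges
        blk = extract_fbb(net, col, col.cells[0])
        assert set(blk.block.nodes) == {"p", "q"}
        assert blk.regulators == frozenset()
        assert not blk.composite

    def test_two_loop_included_with_regulator(self):
        net = LocomotionNetwork()
        for v in "uv":
            net.add_node(v)
        net.add_edge("u", "v", 1, "chem")
        net.add_edge("v", "u", 1, "chem")
        col = Coloring.singletons(net.nodes)
        blk = extract_fbb(net, col, {"v"})
        assert set(blk.block.nodes) == {"u", "v"}
        edges = {(a, b) for a, b, _, _ in blk.block.edges()}
        assert edges == {("u", "v"), ("v", "u")}

    def test_composite_flag_when_pieces_reconnected(self):
        # fiber {m1, m2} fed by two sources living in disconnected pieces
        # joined through a bridge node
        net = LocomotionNetwork()
        for v in ("s1", "s2", "bridge", "m1", "m2"):
            net.add_node(v)
        net.add_edge("s1", "m1", 1, "chem")
        net.add_edge("s2", "m2", 1, "chem")
        net.add_edge("bridge", "s1", 1, "chem")
        net.add_edge("bridge", "s2", 1, "chem")
        col = Coloring({"m1": 0, "m2": 0, "s1": 1, "s2": 2, "bridge": 3})
        blk = extract_fbb(net, col, {"m1", "m2"})
        assert blk.composite
        assert "bridge" in blk.block.nodes
        assert 4 in blk.rules_applied


class TestCircuits:
    def test_fiber_with_no_inputs_collapses_to_one_node(self, lift_factory):
        net = LocomotionNetwork()
        for v in "ab":
            net.add_node(v)
        col = minimal_balanced_coloring(net)
        circuit = extract_circuit(net, col, col.cells[0])
        assert circuit.n == 1

    def test_circuit_is_reachable_ancestry_of_base(self):
        # base chain x -> y -> f plus unrelated cell w
        net = LocomotionNetwork()
        for v in ("x", "y", "f", "w"):
            net.add_node(v)
        net.add_edge("x", "y", 1, "chem")
        net.add_edge("y", "f", 1, "chem")
        col = Coloring.singletons(net.nodes)
        circuit = extract_circuit(net, col, {"f"})
        assert set(circuit.nodes) == {"x", "y", "f"}


class TestClassifyFbb:
    def test_single_layer_block(self, toys):
        net = toys["cyan_trail"]
        col = Coloring.singletons(net.nodes)
        numbers, expr = classify_fbb(net, col, {"C"})
        assert len(expr.layers[0]) == 1
        assert numbers.ell_trails == 6
        # in the multiplicity-free base the M<->P loop gives unit growth
        assert numbers.n == pytest.approx(branching_ratio(net, "C"), abs=1e-9)
        assert numbers.n == pytest.approx(1.0, abs=1e-9)

    def test_square_fiber_is_two_zero_with_no_regulators(self):
        # 4-node square, every node weighted in-degree 2, no external input
        net = LocomotionNetwork()
        for i in range(4):
            net.add_node(f"q{i}")
        for i in range(4):
            net.add_edge(f"q{i}", f"q{(i + 1) % 4}", 1, "chem")
            net.add_edge(f"q{(i + 1) % 4}", f"q{i}", 1, "chem")
        col = minimal_balanced_coloring(net)
        assert col.k == 1
        numbers, expr = classify_fbb(net, col, col.cells[0])
        assert numbers.n == pytest.approx(2.0, abs=1e-9)
        assert numbers.ell_trails == 0
        assert numbers.ell_regulators == 0
        assert numbers.render() == "|2,0>"
        assert expr.render() == "|2,0>"

    def test_two_layer_chain_renders_with_layer_separator(self):
        # fiber {f1,f2} regulated by cell {r1,r2}, itself driven by {s}
        net = LocomotionNetwork()
        for v in ("s", "r1", "r2", "f1", "f2"):
            net.add_node(v)
        net.add_edge("s", "r1", 1, "chem")
        net.add_edge("s", "r2", 1, "chem")
        net.add_edge("r1", "f1", 1, "chem")
        net.add_edge("r1", "f2", 1, "chem")
        net.add_edge("r2", "f1", 1, "chem")
        net.add_edge("r2", "f2", 1, "chem")
        col = Coloring({"s": 0, "r1": 1, "r2": 1, "f1": 2, "f2": 2})
        _, expr = classify_fbb(net, col, {"f1", "f2"})
        assert len(expr.layers) >= 2
        assert "(+)" in expr.render()

    def test_fiber_numbers_layer_and_spectral_agree(self, lift_factory):
        net, planted = lift_factory(seed=13)
        for cell in planted.cells:
            blk = extract_fbb(net, planted, cell)
            numbers = fiber_numbers(blk, planted)
            assert numbers.n >= 0
            assert numbers.ell_trails >= 0
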