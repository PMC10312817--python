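"""Generators for test inputs: planted fibration lifts, locomotion-style
left-right symmetric fixtures, small worked-example toys, weight
perturbations, and the three simulation protocols.

A *planted lift* expands every base node into a fiber of prescribed size so
that each lifted node's total input per source fiber equals the base edge
weight; the planted partition is balanced by construction, and when the
base has a trivial (discrete) minimal balanced coloring the partitioner
recovers it exactly.  The locomotion fixture emulates the repaired
C. elegans sub-circuits: left-right interneuron pairs driving motor-neuron
classes over chemical and gap channels with small integer weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_core import LocomotionNetwork, NetworkError
from .partitioning import Coloring, minimal_balanced_coloring

PA = 1e-12
MV = 1e-3


# ---------------------------------------------------------------------------
# Planted lifts


@dataclass
class LiftSpec:
    """Base network plus per-node fiber sizes for a fibration lift."""

    base: LocomotionNetwork
    sizes: dict[str, int]
    seed: int = 0
    identifiable: bool = False

    def validate(self) -> None:
        if set(self.sizes) != set(self.base.nodes):
            raise NetworkError("fiber sizes must cover exactly the base nodes")
        if any(s < 1 for s in self.sizes.values()):
            raise NetworkError("fiber sizes must be >= 1")
        for u, v, _, ch in self.base.edges("gap"):
            if u != v and self.sizes[u] != self.sizes[v]:
                raise NetworkError(
                    f"gap base edge {u}<->{v} joins fibers of unequal sizes "
                    f"{self.sizes[u]} != {self.sizes[v]}; a balanced symmetric "
                    "lift requires equal sizes")
        if self.identifiable:
            mbc = minimal_balanced_coloring(self.base)
            if mbc.k != self.base.n:
                raise NetworkError(
                    "identifiable flag requires a base with a discrete minimal "
                    f"balanced coloring (got {mbc.k} cells for {self.base.n} nodes)")


def _lift_names(base_node: str, size: int) -> list[str]:
    if size == 1:
        return [base_node]
    return [f"{base_node}.{k}" for k in range(size)]


def planted_lift(spec: LiftSpec) -> tuple[LocomotionNetwork, Coloring]:
    """Random fibration lift of ``spec.base`` with planted fiber partition.

    Chemical base edges ``x -> b`` of integer weight ``w`` give every lifted
    node of ``b`` exactly ``w`` unit inputs with tails drawn uniformly (with
    replacement, folded into weights) from fiber(x).  Gap edges are lifted
    symmetrically: unit permutations between equal-size fibers, and
    cycle/matching decompositions within a fiber; an odd within-fiber demand
    falls back to flagged self-pairings (``gap_self_pairing_fallback``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    net = LocomotionNetwork()
    fibers: dict[str, list[str]] = {}
    for b in spec.base.nodes:
        attrs = spec.base.graph.nodes[b]
        names = _lift_names(b, spec.sizes[b])
        fibers[b] = names
        for name in names:
            net.add_node(name, role=attrs.get("role", "generic"),
                         vs=attrs.get("vs", 0.0), pair=attrs.get("pair"))

    for x, b, w, _ in spec.base.edges("chem"):
        if not float(w).is_integer():
            raise NetworkError("planted lifts require integer chem base weights")
        tails = fibers[x]
        for head in fibers[b]:
            for _ in range(int(w)):
                net.add_edge(tails[rng.integers(len(tails))], head, 1, "chem")

    fallback = False
    for x, b, w, _ in sorted(spec.base.edges("gap")):
        if x > b:
            continue  # symmetric pair handled once
        if not float(w).is_integer():
            raise NetworkError("planted lifts require integer gap base weights")
        w = int(w)
        if x != b:
            p = spec.sizes[x]
            for _ in range(w):
                perm = rng.permutation(p)
                for i in range(p):
                    net.add_edge(fibers[x][i], fibers[b][perm[i]], 1, "gap")
        else:
            fallback |= _lift_gap_self(net, fibers[b], w, rng)
    if fallback:
        net.graph.graph["gap_self_pairing_fallback"] = True
    coloring = Coloring({name: i for i, b in enumerate(spec.base.nodes)
                         for name in fibers[b]}, channel="both", weighted=True)
    net.validate()
    return net, coloring


def _lift_gap_self(net: LocomotionNetwork, members: list[str], w: int,
                   rng: np.random.Generator) -> bool:
    """Within-fiber gap lifting: every member must gain total gap in-weight
    ``w`` from the fiber itself.  Returns True when the self-pairing
    fallback fired."""
    p = len(members)
    if p == 1:
        net.add_edge(members[0], members[0], w, "gap")
        return False
    remaining = w
    fallback = False
    while remaining >= 2 and p >= 3:
        cycle = [members[i] for i in rng.permutation(p)]
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            net.add_edge(a, b, 1, "gap")
        remaining -= 2
    while remaining >= 1 and p % 2 == 0:
        pairing = [members[i] for i in rng.permutation(p)]
        for a, b in zip(pairing[0::2], pairing[1::2]):
            net.add_edge(a, b, 1, "gap")
        remaining -= 1
    if remaining == 1 and p == 2:
        net.add_edge(members[0], members[1], 1, "gap")
        remaining = 0
    if remaining > 0:  # odd demand on an odd fiber: flagged self-pairings
        for m in members:
            net.add_edge(m, m, remaining, "gap")
        fallback = True
    return fallback


# ---------------------------------------------------------------------------
# Locomotion-style fixture


def locomotion_base() -> LocomotionNetwork:
    """Base circuit emulating a repaired locomotion sub-network: command
    interneuron classes driving motor-neuron classes, chem + gap channels."""
    base = LocomotionNetwork()
    for name in ("AVB", "PVC", "RIB"):
        base.add_node(name, role="interneuron")
    for name in ("DB1", "DB2", "VB1", "VB2"):
        base.add_node(name, role="motorneuron")
    # chemical feed-forward drive (weights = synaptic multiplicities)
    base.add_edge("PVC", "AVB", 1, "chem")
    base.add_edge("AVB", "RIB", 2, "chem")
    base.add_edge("AVB", "DB1", 2, "chem")
    base.add_edge("AVB", "VB1", 1, "chem")
    base.add_edge("PVC", "VB1", 1, "chem")
    base.add_edge("PVC", "VB2", 2, "chem")
    base.add_edge("DB1", "DB2", 1, "chem")
    base.add_edge("VB1", "VB2", 1, "chem")
    base.add_edge("VB2", "DB2", 1, "chem")
    # gap channel between equal-size classes and within classes
    base.add_edge("AVB", "PVC", 1, "gap")
    base.add_edge("DB1", "DB1", 2, "gap")
    base.add_edge("VB1", "VB1", 2, "gap")
    return base


def locomotion_fixture(seed: int = 0) -> tuple[LocomotionNetwork, Coloring]:
    """Left-right symmetric locomotion-like network (15-30 nodes).

    Interneuron classes are size-2 left-right pairs sharing a fiber; motor
    classes are larger fibers.  The planted coloring has <= 8 cells.
    """
    base = locomotion_base()
    sizes = {"AVB": 2, "PVC": 2, "RIB": 2, "DB1": 3, "DB2": 2, "VB1": 4, "VB2": 3}
    net, coloring = planted_lift(LiftSpec(base, sizes, seed=seed))
    for b, suffix in (("AVB", "LR"), ("PVC", "LR"), ("RIB", "LR")):
        for name in _lift_names(b, sizes[b]):
            net.graph.nodes[name]["pair"] = b
    return net, coloring


# ---------------------------------------------------------------------------
# Worked-example toys


def paper_toys() -> dict:
    """Small named fixtures with closed-form or enumerable answers."""
    toys: dict = {}

    cyan = LocomotionNetwork()
    for v in ("C", "M", "P"):
        cyan.add_node(v)
    for u, v in (("M", "C"), ("P", "C"), ("M", "P"), ("P", "M")):
        cyan.add_edge(u, v, 1, "chem")
    toys["cyan_trail"] = cyan  # 6 edge-distinct trails terminate at C

    def two_node(m):
        net = LocomotionNetwork()
        net.add_node("a")
        net.add_node("b")
        for (i, j), w in np.ndenumerate(np.asarray(m)):
            if w > 0:
                net.add_edge("ab"[i], "ab"[j], int(w), "chem")
        return net

    toys["fibonacci_bases"] = {
        "golden": (two_node([[1, 1], [1, 0]]), (1 + np.sqrt(5)) / 2),
        "nested_33": (two_node([[1, 4], [2, 0]]), (1 + np.sqrt(33)) / 2),
        "integer_2": (two_node([[2, 1], [0, 0]]), 2.0),
        "acyclic": (two_node([[0, 2], [0, 0]]), 0.0),
    }

    # directed fiber-vs-orbit counterexample: A..D share a fiber (one input
    # from R each) but their out-degrees differ, so orbits split them.
    fo = LocomotionNetwork()
    for v in ("R", "A", "B", "C", "D", "E", "F"):
        fo.add_node(v)
    for v in ("A", "B", "C", "D"):
        fo.add_edge("R", v, 1, "chem")
    fo.add_edge("A", "E", 1, "chem")
    fo.add_edge("B", "E", 1, "chem")
    fo.add_edge("C", "F", 1, "chem")
    toys["fiber_vs_orbit_directed"] = fo

    # undirected counterexample (found by exhaustive search, synthetic): a
    # regular-ish 8-node graph whose coarsest equitable partition has 2
    # cells while the automorphism orbits split it into 4.
    fu = LocomotionNetwork()
    for i in range(8):
        fu.add_node(f"n{i}")
    for u, v in ((0, 1), (0, 2), (0, 6), (1, 2), (1, 4), (2, 3), (2, 7),
                 (3, 4), (3, 5), (3, 6), (4, 7), (5, 6), (5, 7)):
        fu.add_edge(f"n{u}", f"n{v}", 1, "gap")
    toys["fiber_vs_orbit_undirected"] = fu

    # layer-count worked example: root with in-weights {1, 2}; the two
    # layer-2 source nodes have weighted in-degrees 3 and 4, so the walk
    # counts go 1, 3, 3+4+4 = 11.
    lc = LocomotionNetwork()
    for v in ("R", "X", "Y", "A", "B"):
        lc.add_node(v)
    lc.add_edge("X", "R", 1, "chem")
    lc.add_edge("Y", "R", 2, "chem")
    lc.add_edge("A", "X", 3, "chem")
    lc.add_edge("B", "Y", 4, "chem")
    toys["layer_counts"] = lc
    return toys


# ---------------------------------------------------------------------------
# Weight perturbation (simulation test 3)


def perturb_weights(network: LocomotionNetwork, sd: float, seed: int = 0,
                    floor: float | None = 1e-6) -> LocomotionNetwork:
    """Add zero-mean Gaussian noise (std ``sd``) to every nonzero weight.

    The zero pattern is unchanged; gap pairs are perturbed jointly so the
    channel stays symmetric; weights are clipped at a small positive
    ``floor`` (pass ``None`` to allow sign flips).
    """
    if sd < 0:
        raise NetworkError("standard deviation must be nonnegative")
    rng = np.random.default_rng(seed)
    out = network.copy()
    if sd == 0:
        return out
    for u, v, data in sorted(out.graph.edges(data=True)):
        if data.get("chem", 0.0) > 0:
            w = data["chem"] + rng.normal(0.0, sd)
            data["chem"] = max(w, floor) if floor is not None else w
        gw = data.get("gap", 0.0)
        if gw > 0 and (u <= v):
            w = gw + rng.normal(0.0, sd)
            w = max(w, floor) if floor is not None else w
            data["gap"] = w
            if u != v:
                out.graph.get_edge_data(v, u)["gap"] = w
    return out


# ---------------------------------------------------------------------------
# Simulation protocols


def protocol(test_id: int, network: LocomotionNetwork, coloring: Coloring,
             overrides: dict | None = None) -> dict:
    """Run configuration for the three simulation tests.

    test 1: no stimulus; initial voltages N(V_rest, sd) with sd swept over
        0..0.1 mV, synaptic variables N(s_eq, sd) for chem type II.
    test 2: constant drive at 90% of the instability threshold plus an
        oscillation at 5% of it; 2 Hz into interneurons, 1 Hz into motor
        neurons (gap networks get a second motor-neuron drive group).
    test 3: 0.1 pA constant + 0.5 pA oscillation (2 Hz / 1 Hz) + 0.01 pA
        random-walk noise (0.61 pA max amplitude); V(0) = -35 mV,
        s(0) = s_eq; weight noise sd swept 0..0.1 in 0.01 steps, 10
        replicates averaged.
    """
    overrides = dict(overrides or {})
    if test_id not in (1, 2, 3):
        raise NetworkError(f"unknown simulation test id {test_id!r}")
    model = overrides.pop("model", "chem2")
    inter_cells = [sorted(c) for c in coloring.cells
                   if all(network.graph.nodes[v].get("role") == "interneuron" for v in c)]
    motor_cells = [sorted(c) for c in coloring.cells
                   if all(network.graph.nodes[v].get("role") == "motorneuron" for v in c)]
    config: dict = {
        "test": test_id,
        "model": model,
        "duration": overrides.pop("duration", 5.0),
        "dt": overrides.pop("dt", 1e-4),
        "seed": overrides.pop("seed", 0),
    }
    if test_id == 1:
        config.update({
            "stimulus": None,
            "init": {
                "v_mean": -35 * MV,
                "v_sd_sweep": [round(k * 0.01, 2) * MV for k in range(11)],
                "s_mean": "s_eq",
                "s_sd_sweep": [round(k * 0.01, 2) for k in range(11)],
            },
        })
    elif test_id == 2:
        i_star = overrides.pop("i_star", None)
        targets = overrides.pop("targets", inter_cells[0] if inter_cells else [])
        groups = [{"targets": targets, "frequency": 2.0,
                   "i_drive": "0.9*i_star", "i_osc": "0.05*i_star"}]
        if model == "gap" and motor_cells:
            groups.append({"targets": overrides.pop("motor_targets", motor_cells[0]),
                           "frequency": 1.0,
                           "i_drive": "0.9*i_star", "i_osc": "0.05*i_star"})
        config.update({"i_star": i_star, "stimulus_groups": groups})
    else:
        groups = [{"targets": cell, "frequency": 2.0, "i_drive": 0.1 * PA,
                   "i_osc": 0.5 * PA, "noise_amp": 0.01 * PA}
                  for cell in inter_cells[:1]]
        groups += [{"targets": cell, "frequency": 1.0, "i_drive": 0.1 * PA,
                    "i_osc": 0.5 * PA, "noise_amp": 0.01 * PA}
                   for cell in motor_cells[:1]]
        config.update({
            "stimulus_groups": groups,
            "max_drive_amplitude": 0.61 * PA,
            "weight_sd_sweep": [round(k * 0.01, 2) for k in range(11)],
            "replicates": 10,
            "init": {"v_mean": -35 * MV, "v_sd_sweep": [0.0],
                     "s_mean": "s_eq", "s_sd_sweep": [0.0]},
        })
    config.update(overrides)
    return config
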