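"""Fiber and orbit partitions of a network channel.

Fibers are computed as the *minimal balanced coloring*: the coarsest
partition in which every node's total (weighted) input, broken down by
source cell, depends only on the node's own cell.  Nodes in the same fiber
have isomorphic input trees and synchronize under any admissible dynamics.

Orbits are the equivalence classes of the automorphism group: permutations
``P`` with ``P A P^{-1} = A`` for the weighted adjacency of every channel
considered.  Every orbit is contained in a fiber; the converse fails for
directed graphs because automorphisms must also preserve out-degrees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .graph_core import CHANNELS, LocomotionNetwork, NetworkError, adjacency

DEFAULT_AUT_NODE_LIMIT = 64


class SizeLimitError(RuntimeError):
    """Raised when an exhaustive search is refused on a too-large input."""


# ---------------------------------------------------------------------------
# Coloring


@dataclass
class Coloring:
    """Partition of the node set into cells ``0..k-1``.

    Cell ids are dense and deterministic: cells are sorted by
    ``(size, lexicographically smallest member)``.
    """

    mapping: dict[str, int]
    channel: str = "both"
    weighted: bool = True

    def __post_init__(self):
        self.mapping = dict(self.mapping)
        self._normalize()

    def _normalize(self) -> None:
        groups: dict[int, list[str]] = {}
        for node, cid in self.mapping.items():
            groups.setdefault(cid, []).append(node)
        ordered = sorted(groups.values(), key=lambda ns: (len(ns), min(ns)))
        self.mapping = {node: i for i, ns in enumerate(ordered) for node in ns}

    @property
    def k(self) -> int:
        return len(set(self.mapping.values())) if self.mapping else 0

    @property
    def cells(self) -> list[frozenset[str]]:
        groups: dict[int, set[str]] = {}
        for node, cid in self.mapping.items():
            groups.setdefault(cid, set()).add(node)
        return [frozenset(groups[i]) for i in range(self.k)]

    def cell_of(self, node: str) -> frozenset[str]:
        cid = self.mapping[node]
        return frozenset(n for n, c in self.mapping.items() if c == cid)

    def as_sets(self) -> set[frozenset[str]]:
        return set(self.cells)

    def refines(self, other: "Coloring") -> bool:
        """True iff every cell of self is contained in a cell of ``other``."""
        return all(len({other.mapping[n] for n in cell}) == 1 for cell in self.cells)

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "weighted": self.weighted,
            "cells": {str(i): sorted(cell) for i, cell in enumerate(self.cells)},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Coloring":
        mapping = {n: int(cid) for cid, nodes in payload["cells"].items() for n in nodes}
        return cls(mapping, payload.get("channel", "both"), payload.get("weighted", True))

    @classmethod
    def singletons(cls, nodes, **kw) -> "Coloring":
        return cls({n: i for i, n in enumerate(sorted(nodes))}, **kw)

    @classmethod
    def trivial(cls, nodes, **kw) -> "Coloring":
        return cls({n: 0 for n in nodes}, **kw)


def _input_profile(network: LocomotionNetwork, node: str, mapping: dict[str, int],
                   channel: str, weighted: bool):
    """Total input to ``node`` keyed by (channel, source cell)."""
    wanted = CHANNELS if channel == "both" else (channel,)
    profile: dict[tuple[str, int], float] = {}
    for ch in wanted:
        for u, w, _ in network.in_edges(node, ch):
            key = (ch, mapping[u])
            profile[key] = profile.get(key, 0.0) + (w if weighted else 1.0)
    return frozenset((k, round(v, 9)) for k, v in profile.items())


def minimal_balanced_coloring(network: LocomotionNetwork, channel: str = "both",
                              weighted: bool = True,
                              initial: Coloring | None = None) -> Coloring:
    """Coarsest balanced coloring (the fiber partition) of a channel.

    Starts from the all-one-cell partition (or ``initial``, when the
    coarsest balanced refinement of a given partition is wanted) and
    iteratively splits cells by each node's input profile (total weight
    received per source cell) until a fixed point.  The fixed point is
    order-independent and coarsest.
    """
    nodes = network.nodes
    mapping = dict(initial.mapping) if initial is not None else {v: 0 for v in nodes}
    while True:
        signatures = {v: (mapping[v], _input_profile(network, v, mapping, channel, weighted))
                      for v in nodes}
        classes: dict = {}
        for v in nodes:
            classes.setdefault(signatures[v], len(classes))
        new_mapping = {v: classes[signatures[v]] for v in nodes}
        if len(set(new_mapping.values())) == len(set(mapping.values())):
            break
        mapping = new_mapping
    return Coloring(mapping, channel=channel, weighted=weighted)


def is_balanced(network: LocomotionNetwork, coloring: Coloring, channel: str = "both",
                weighted: bool = True) -> bool:
    """True iff every node of a cell receives identical total input from
    every cell (per channel)."""
    if set(coloring.mapping) != set(network.nodes):
        raise NetworkError("coloring does not cover the node set")
    for cell in coloring.cells:
        profiles = {_input_profile(network, v, coloring.mapping, channel, weighted)
                    for v in cell}
        if len(profiles) > 1:
            return False
    return True


# ---------------------------------------------------------------------------
# Input trees


@dataclass
class InputTree:
    """Layered rooted tree of all walks terminating at ``root``.

    Layer ``i`` holds one entry per walk of length ``i``; an edge of integer
    weight ``w`` contributes ``w`` parallel walk extensions.  ``a[i]`` is
    the number of entries in layer ``i`` (``a[0] == 1``).  The canonical
    ``signature`` is a label-free recursive form used for isomorphism tests.
    """

    root: str
    depth: int
    a: np.ndarray
    signature: tuple
    layers: list[list[tuple]] | None = None  # (source, in-weight, parent index)


def _tree_signature(network: LocomotionNetwork, node: str, depth: int, channel: str,
                    weighted: bool, cache: dict) -> tuple:
    key = (node, depth)
    if key in cache:
        return cache[key]
    if depth == 0:
        sig: tuple = ()
    else:
        wanted = CHANNELS if channel == "both" else (channel,)
        children = []
        for ch in wanted:
            for u, w, _ in network.in_edges(node, ch):
                mult = int(round(w)) if weighted else 1
                child = (ch if channel == "both" else "", _tree_signature(
                    network, u, depth - 1, channel, weighted, cache))
                children.extend([child] * max(mult, 1))
        sig = tuple(sorted(children))
    cache[key] = sig
    return sig


def input_tree(network: LocomotionNetwork, node: str, depth: int,
               channel: str = "both", weighted: bool = True,
               materialize_limit: int = 10_000) -> InputTree:
    """Input tree of ``node`` down to ``depth`` layers.

    Layer counts ``a_i`` follow the recurrence a_{i+1} = sum over layer-i
    entries of the (weighted) in-degree of their source node, computed by
    vector iteration so deep trees stay cheap.  Layers themselves are
    materialized only while the total entry count stays below
    ``materialize_limit``.
    """
    if node not in network.graph:
        raise NetworkError(f"unknown node {node!r}")
    if depth < 0:
        raise NetworkError("negative depth")
    order = network.nodes
    index = {v: i for i, v in enumerate(order)}
    wanted = CHANNELS if channel == "both" else (channel,)
    w_mat = np.zeros((len(order), len(order)))
    for ch in wanted:
        a = adjacency(network, ch, binary=not weighted, order=order).matrix
        w_mat += a
    # m[i] = number of layer entries whose source node is order[i]
    m = np.zeros(len(order))
    m[index[node]] = 1.0
    counts = [1.0]
    for _ in range(depth):
        m = w_mat @ m
        counts.append(float(m.sum()))

    layers: list[list[tuple]] | None = [[(node, 0.0, -1)]]
    total = 1
    for d in range(depth):
        if layers is None:
            break
        nxt: list[tuple] = []
        for parent_idx, (src, _, _) in enumerate(layers[-1]):
            for ch in wanted:
                for u, w, _ in network.in_edges(src, ch):
                    mult = int(round(w)) if weighted else 1
                    nxt.extend([(u, w, parent_idx)] * max(mult, 1))
        total += len(nxt)
        if total > materialize_limit:
            layers = None
        else:
            layers.append(nxt)

    sig = _tree_signature(network, node, depth, channel, weighted, {})
    return InputTree(node, depth, np.array(counts), sig, layers)


def trees_isomorphic(t1: InputTree, t2: InputTree) -> bool:
    """Layer-wise rooted-tree isomorphism ignoring node labels."""
    if t1.depth != t2.depth:
        raise NetworkError("input trees have different depths")
    return t1.signature == t2.signature


# ---------------------------------------------------------------------------
# Base graph (quotient under a balanced coloring)


def base_graph(network: LocomotionNetwork, coloring: Coloring,
               channel: str = "both", weighted: bool = True) -> LocomotionNetwork:
    """Collapse each cell onto one representative node.

    The base weight ``cell_j -> cell_i`` is the common total input any node
    of ``C_i`` receives from ``C_j`` (self-edges allowed), so every node's
    in-neighborhood by color equals its base node's in-neighborhood.
    """
    if not is_balanced(network, coloring, channel, weighted):
        raise NetworkError("coloring is not balanced; cannot form base graph")
    cells = coloring.cells
    reps = {i: min(cell) for i, cell in enumerate(cells)}
    base = LocomotionNetwork()
    for i, cell in enumerate(cells):
        attrs = network.graph.nodes[min(cell)]
        base.add_node(reps[i], role=attrs.get("role", "generic"),
                      vs=attrs.get("vs", 0.0), pair=attrs.get("pair"))
    wanted = CHANNELS if channel == "both" else (channel,)
    for i, cell in enumerate(cells):
        probe = min(cell)  # any member: balance guarantees equality
        for ch in wanted:
            totals: dict[int, float] = {}
            for u, w, _ in network.in_edges(probe, ch):
                j = coloring.mapping[u]
                totals[j] = totals.get(j, 0.0) + (w if weighted else 1.0)
            for j, w in totals.items():
                if ch == "gap":
                    # gap base stored directed to keep unequal quotient
                    # weights representable; symmetry holds when it can
                    base._bump(reps[j], reps[i], w, ch)
                else:
                    base.add_edge(reps[j], reps[i], w, ch)
    return base


# ---------------------------------------------------------------------------
# Automorphisms and orbits


@dataclass
class Automorphism:
    """Node permutation leaving every channel's weighted adjacency invariant."""

    mapping: dict[str, str]

    def __call__(self, node: str) -> str:
        return self.mapping[node]

    def is_valid(self, network: LocomotionNetwork, channel: str = "both",
                 weighted: bool = True) -> bool:
        order = network.nodes
        index = {v: i for i, v in enumerate(order)}
        perm = np.array([index[self.mapping[v]] for v in order])
        wanted = CHANNELS if channel == "both" else (channel,)
        for ch in wanted:
            a = adjacency(network, ch, binary=not weighted).matrix
            if not np.allclose(a[np.ix_(perm, perm)], a):
                return False
        return True


def _aut_classes(network: LocomotionNetwork, channel: str, weighted: bool) -> dict[str, int]:
    """Equitable refinement on joint in/out profiles: candidate image classes."""
    nodes = network.nodes
    mapping = {v: 0 for v in nodes}
    wanted = CHANNELS if channel == "both" else (channel,)
    while True:
        sigs = {}
        for v in nodes:
            prof: dict = {}
            for ch in wanted:
                for u, w, _ in network.in_edges(v, ch):
                    key = ("in", ch, mapping[u])
                    prof[key] = prof.get(key, 0.0) + (w if weighted else 1.0)
                for u, w, _ in network.out_edges(v, ch):
                    key = ("out", ch, mapping[u])
                    prof[key] = prof.get(key, 0.0) + (w if weighted else 1.0)
            sigs[v] = (mapping[v], frozenset((k, round(x, 9)) for k, x in prof.items()))
        classes: dict = {}
        for v in nodes:
            classes.setdefault(sigs[v], len(classes))
        new = {v: classes[sigs[v]] for v in nodes}
        if len(set(new.values())) == len(set(mapping.values())):
            return new
        mapping = new


def _weights_to(network: LocomotionNetwork, channel: str, weighted: bool):
    wanted = CHANNELS if channel == "both" else (channel,)
    table: dict[tuple[str, str], dict[str, float]] = {}
    for ch in wanted:
        for u, v, w, _ in network.edges(ch):
            table.setdefault((u, v), {})[ch] = w if weighted else 1.0
    return table


def _search_automorphisms(network: LocomotionNetwork, channel: str, weighted: bool,
                          require: tuple[str, str] | None = None,
                          first_only: bool = False, max_count: int | None = None):
    """Backtracking over class-respecting permutations; yields mappings.

    ``require=(v, u)`` restricts the search to automorphisms with v -> u.
    """
    nodes = network.nodes
    classes = _aut_classes(network, channel, weighted)
    wtab = _weights_to(network, channel, weighted)

    def compatible(assigned: dict[str, str], v: str, u: str) -> bool:
        if classes[v] != classes[u]:
            return False
        if wtab.get((v, v), {}) != wtab.get((u, u), {}):
            return False
        for x, y in assigned.items():
            if wtab.get((v, x), {}) != wtab.get((u, y), {}):
                return False
            if wtab.get((x, v), {}) != wtab.get((y, u), {}):
                return False
        return True

    order = sorted(nodes, key=lambda v: (classes[v], v))
    if require is not None and require[0] in order:
        order = [require[0]] + [v for v in order if v != require[0]]
    found: list[dict[str, str]] = []

    def backtrack(i: int, assigned: dict[str, str], used: set[str]):
        if max_count is not None and len(found) >= max_count:
            return
        if i == len(order):
            found.append(dict(assigned))
            return
        v = order[i]
        candidates = [require[1]] if (require is not None and v == require[0]) else nodes
        for u in candidates:
            if u in used or not compatible(assigned, v, u):
                continue
            assigned[v] = u
            used.add(u)
            backtrack(i + 1, assigned, used)
            del assigned[v]
            used.discard(u)
            if first_only and found:
                return

    backtrack(0, {}, set())
    return found


def automorphisms(network: LocomotionNetwork, channel: str = "both",
                  weighted: bool = True, node_limit: int = DEFAULT_AUT_NODE_LIMIT,
                  max_count: int = 100_000) -> list[Automorphism]:
    """Exhaustive automorphism group of a channel's weighted adjacency.

    Backtracking seeded by equitable refinement; every returned permutation
    satisfies ``P A P^{-1} = A`` exactly.  Refuses networks above
    ``node_limit`` nodes (whole-connectome orbit search is out of reach).
    """
    if network.n > node_limit:
        raise SizeLimitError(
            f"automorphism search refused: {network.n} nodes > limit {node_limit}")
    perms = _search_automorphisms(network, channel, weighted, max_count=max_count)
    return [Automorphism(p) for p in perms]


def orbit_coloring(network: LocomotionNetwork, channel: str = "both",
                   weighted: bool = True, node_limit: int = DEFAULT_AUT_NODE_LIMIT) -> Coloring:
    """Orbits of the automorphism group action (union-find closure).

    For each candidate pair not yet in one component, a single automorphism
    mapping one node to the other is searched; the whole permutation is then
    folded into the union-find, which keeps the closure complete without
    enumerating the full group.
    """
    if network.n > node_limit:
        raise SizeLimitError(
            f"orbit search refused: {network.n} nodes > limit {node_limit}")
    nodes = network.nodes
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    classes = _aut_classes(network, channel, weighted)
    by_class: dict[int, list[str]] = {}
    for v in nodes:
        by_class.setdefault(classes[v], []).append(v)
    for members in by_class.values():
        for v, u in itertools.combinations(members, 2):
            if find(v) == find(u):
                continue
            perms = _search_automorphisms(network, channel, weighted,
                                          require=(v, u), first_only=True)
            if perms:
                for a, b in perms[0].items():
                    union(a, b)
    roots = sorted({find(v) for v in nodes})
    mapping = {v: roots.index(find(v)) for v in nodes}
    return Coloring(mapping, channel=channel, weighted=weighted)
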