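"""Circuits, fiber building blocks (FBBs) and fiber numbers |n, l>.

A fiber's building block is the induced subgraph on (1) the fiber, (2) the
fiber's immediate in-neighbors, (3) the shortest non-self loop through a
fiber node, and (4), if those pieces are disconnected, the shortest paths
reconnecting them (a *composite* block).  Nodes feeding the block with only
outgoing edges inside it, plus fiber nodes feeding back into the fiber, are
its *regulators*.

The block's input tree is summarized by two fiber numbers: the branching
ratio ``n`` (asymptotic growth rate of layer counts, equal to the spectral
radius of the adjacency restricted to the root's in-component; irrational
values flag nested-loop "Fibonacci" blocks) and the trail count ``l``
(edge-distinct walks terminating at the collapsed root in the unweighted
base, the root's outgoing edges excluded).  Regulator counts are reported
alongside since both readings of ``l`` appear in the field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph_core import LocomotionNetwork, NetworkError, adjacency
from .partitioning import Coloring, SizeLimitError, base_graph, input_tree

BRANCHING_TOL = 1e-6
TRAIL_EDGE_LIMIT = 64


@dataclass
class FiberBuildingBlock:
    fiber: frozenset[str]
    block: LocomotionNetwork
    regulators: frozenset[str]
    composite: bool = False
    rules_applied: tuple[int, ...] = (1, 2)


@dataclass
class FiberNumbers:
    """|n, l>: branching ratio and trail/regulator counts of one block."""

    n: float
    ell_trails: int
    ell_regulators: int

    @property
    def fibonacci(self) -> bool:
        return abs(self.n - round(self.n)) > BRANCHING_TOL

    def render(self, ell: str = "trails") -> str:
        n = round(self.n) if not self.fibonacci else round(self.n, 3)
        e = self.ell_trails if ell == "trails" else self.ell_regulators
        return f"|{n},{e}>"


@dataclass
class MultilayerExpression:
    """Ordered layers of fiber numbers; ``(+)`` joins layers, ``+`` terms."""

    layers: list[list[FiberNumbers]]

    def render(self, ell: str = "trails") -> str:
        if not self.layers:
            raise NetworkError("empty multilayer expression")
        return "(+)".join("+".join(fn.render(ell) for fn in layer)
                          for layer in self.layers)


# ---------------------------------------------------------------------------


def _cell_rep(coloring: Coloring, fiber_cell) -> tuple[frozenset[str], int]:
    cell = frozenset(fiber_cell)
    for i, c in enumerate(coloring.cells):
        if c == cell:
            return cell, i
    raise NetworkError(f"unknown fiber cell {sorted(fiber_cell)}")


def extract_circuit(network: LocomotionNetwork, coloring: Coloring,
                    fiber_cell) -> LocomotionNetwork:
    """Base graph restricted to the cells appearing in the fiber's input
    tree, i.e. the cells from which the fiber is reachable (ancestors of
    the collapsed fiber node, itself included)."""
    cell, _ = _cell_rep(coloring, fiber_cell)
    base = base_graph(network, coloring, channel=coloring.channel,
                      weighted=coloring.weighted)
    root = min(cell)
    g = nx.DiGraph()
    g.add_nodes_from(base.nodes)
    g.add_edges_from((u, v) for u, v, _, _ in base.edges())
    keep = nx.ancestors(g, root) | {root}
    return base.subgraph(keep)


def _shortest_loop_nodes(network: LocomotionNetwork, through: frozenset[str]) -> set[str]:
    """Nodes on the shortest directed cycle (length >= 2) through any node
    of ``through``; BFS per node, lexicographic tie-break."""
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from((u, v) for u, v, _, _ in network.edges() if u != v)
    best: list[str] | None = None
    for v in sorted(through):
        # shortest path back to v from each successor
        for succ in sorted(g.successors(v)):
            try:
                path = nx.shortest_path(g, succ, v)
            except nx.NetworkXNoPath:
                continue
            cycle = [v] + path
            if best is None or len(cycle) < len(best) or (
                    len(cycle) == len(best) and cycle < best):
                best = cycle
    return set(best) if best else set()


def extract_fbb(network: LocomotionNetwork, coloring: Coloring,
                fiber_cell) -> FiberBuildingBlock:
    """Apply FBB rules 1-4 and identify regulator nodes."""
    cell, _ = _cell_rep(coloring, fiber_cell)
    rules = [1]
    nodes = set(cell)
    in_neighbors = {u for v in cell for u, _, _ in network.in_edges(v)}
    if in_neighbors - nodes:
        rules.append(2)
    nodes |= in_neighbors
    loop = _shortest_loop_nodes(network, cell)
    if loop - nodes:
        rules.append(3)
    nodes |= loop

    composite = False
    und = nx.Graph()
    und.add_nodes_from(network.nodes)
    und.add_edges_from((u, v) for u, v, _, _ in network.edges())
    sub = und.subgraph(nodes)
    comps = sorted((sorted(c) for c in nx.connected_components(sub)), key=lambda c: c[0])
    if len(comps) > 1:
        for ca, cb in zip(comps, comps[1:]):
            best = None
            for a in ca:
                for b in cb:
                    try:
                        path = nx.shortest_path(und, a, b)
                    except nx.NetworkXNoPath:
                        continue
                    if best is None or len(path) < len(best) or (
                            len(path) == len(best) and path < best):
                        best = path
            if best:
                nodes |= set(best)
                composite = True
        if composite:
            rules.append(4)

    block = network.subgraph(nodes)
    regulators = set()
    for v in sorted(nodes - cell):
        has_in = any(True for _ in block.in_edges(v))
        has_out = any(True for _ in block.out_edges(v))
        if has_out and not has_in:
            regulators.add(v)
    if nodes - cell:
        # fiber nodes feeding back into the fiber also regulate it; a
        # self-sustained block (fiber only, no external input) has none
        for v in sorted(cell):
            if any(head in cell for head, _, _ in network.out_edges(v)):
                regulators.add(v)
    return FiberBuildingBlock(cell, block, frozenset(regulators), composite,
                              tuple(rules))


# ---------------------------------------------------------------------------
# Fiber numbers


def _in_component(network: LocomotionNetwork, roots: set[str]) -> set[str]:
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from((u, v) for u, v, _, _ in network.edges())
    keep = set(roots)
    for r in roots:
        keep |= nx.ancestors(g, r)
    return keep


def branching_ratio(block: LocomotionNetwork, root, weighted: bool = True,
                    max_depth: int = 600, tol: float = BRANCHING_TOL) -> float:
    """Branching ratio ``n``: the limit of consecutive input-tree layer
    counts a_{i+1}/a_i of the root's input tree.

    Computed two ways and required to agree within ``tol``: (a) a k-step
    layer-count ratio at large depth and (b) the spectral radius of the
    (weighted) adjacency restricted to the root's in-component.  Returns 0
    for finite input trees (acyclic in-component).  Disagreement beyond
    ``tol`` after ``max_depth`` layers emits a warning and reports the
    spectral estimate.
    """
    roots = set(root) if isinstance(root, (set, frozenset)) else {root}
    if not roots <= set(block.nodes):
        raise NetworkError(f"unknown root {root!r}")
    keep = _in_component(block, roots)
    sub = block.subgraph(keep)
    order = sub.nodes
    a = (adjacency(sub, "chem", binary=not weighted, order=order).matrix
         + adjacency(sub, "gap", binary=not weighted, order=order).matrix)
    if a.size == 0:
        return 0.0
    spectral = float(max(abs(np.linalg.eigvals(a))))
    if spectral < tol:
        return 0.0

    # layer-count iteration: m_{i+1} = A m_i, a_i = sum(m_i)
    index = {v: i for i, v in enumerate(order)}
    m = np.zeros(len(order))
    for r in roots:
        m[index[r]] = 1.0
    k = 12  # step-k root irons out periodic layer-count oscillation
    history: list[float] = [m.sum()]
    log_scale = 0.0
    estimates: dict[int, float] = {}
    estimate = np.nan
    for i in range(max_depth):
        m = a @ m
        total = m.sum()
        if total == 0.0:
            return 0.0
        if total > 1e250:  # renormalize to dodge overflow
            m /= total
            history = [h / total for h in history]
            total = m.sum()
        history.append(total)
        if len(history) > k:
            estimate = (history[-1] / history[-1 - k]) ** (1.0 / k)
            estimates[i] = estimate
            if abs(estimate - spectral) < tol:
                return spectral
    # polynomial-times-geometric layer counts (defective dominant
    # eigenvalue) bias the plain ratio by O(1/i); Richardson-extrapolate
    half = (max_depth - 1) // 2
    if half in estimates and estimates.get(max_depth - 1, 0) > 0:
        extrap = np.exp(2 * np.log(estimates[max_depth - 1])
                        - np.log(estimates[half]))
        if abs(extrap - spectral) < max(tol, 1e-4 * spectral):
            return spectral
        estimate = extrap
    warnings.warn(
        f"branching ratio did not converge: layer estimate {estimate!r} vs "
        f"spectral {spectral!r}; reporting spectral value")
    return spectral


def trail_count(block: LocomotionNetwork, root, edge_limit: int = TRAIL_EDGE_LIMIT) -> int:
    """Number of edge-distinct walks (trails) terminating at ``root``.

    Counted in the unweighted base-style graph (edge multiplicity
    disregarded) with the root's outgoing edges removed; exhaustive
    recursive enumeration, refused above ``edge_limit`` edges.
    """
    roots = set(root) if isinstance(root, (set, frozenset)) else {root}
    edges = {(u, v) for u, v, _, _ in block.edges() if u not in roots}
    if len(edges) > edge_limit:
        raise SizeLimitError(f"trail enumeration refused: {len(edges)} edges")
    in_edges: dict[str, list[tuple[str, str]]] = {}
    for u, v in edges:
        in_edges.setdefault(v, []).append((u, v))

    def count_from(node: str, used: frozenset) -> int:
        total = 0
        for e in in_edges.get(node, ()):  # extend the trail backwards
            if e in used:
                continue
            total += 1 + count_from(e[0], used | {e})
        return total

    return sum(count_from(r, frozenset()) for r in sorted(roots))


def fiber_numbers(block: FiberBuildingBlock, coloring: Coloring) -> FiberNumbers:
    """|n, l> of one building block, computed on its collapsed base."""
    from .partitioning import minimal_balanced_coloring

    restricted = Coloring({v: coloring.mapping[v] for v in block.block.nodes},
                          channel=coloring.channel, weighted=coloring.weighted)
    # the parent coloring restricted to the block need not stay balanced
    # (regulators may lose in-edges); refine it until it is
    sub_coloring = minimal_balanced_coloring(block.block, channel=coloring.channel,
                                             weighted=coloring.weighted,
                                             initial=restricted)
    base = base_graph(block.block, sub_coloring, channel=coloring.channel,
                      weighted=coloring.weighted)
    root = min(block.fiber)
    n = branching_ratio(base, root, weighted=coloring.weighted)
    ell = trail_count(base, root)
    return FiberNumbers(n, ell, len(block.regulators))


def classify_fbb(network: LocomotionNetwork, coloring: Coloring,
                 fiber_cell) -> tuple[FiberNumbers, MultilayerExpression]:
    """Fiber numbers of the main block plus the layered decomposition.

    Layer 1 is the main fiber's elementary block; each subsequent layer
    holds the blocks of the previous layer's regulators, until every cell
    has appeared once.
    """
    cell, _ = _cell_rep(coloring, fiber_cell)
    main = extract_fbb(network, coloring, cell)
    main_numbers = fiber_numbers(main, coloring)
    layers: list[list[FiberNumbers]] = [[main_numbers]]
    seen_cells = {frozenset(cell)}
    frontier = [main]
    while frontier:
        next_cells: list[frozenset[str]] = []
        for blk in frontier:
            for reg in sorted(blk.regulators):
                reg_cell = coloring.cell_of(reg)
                if reg_cell in seen_cells:
                    continue
                seen_cells.add(reg_cell)
                next_cells.append(reg_cell)
        if not next_cells:
            break
        layer_numbers: list[FiberNumbers] = []
        frontier = []
        for reg_cell in next_cells:
            blk = extract_fbb(network, coloring, reg_cell)
            layer_numbers.append(fiber_numbers(blk, coloring))
            frontier.append(blk)
        layers.append(layer_numbers)
    return main_numbers, MultilayerExpression(layers)


def block_report(network: LocomotionNetwork, coloring: Coloring, fiber_cell) -> dict:
    """JSON-ready report for one fiber's building block."""
    blk = extract_fbb(network, coloring, fiber_cell)
    numbers, expr = classify_fbb(network, coloring, fiber_cell)
    return {
        "fiber": sorted(blk.fiber),
        "block_nodes": blk.block.nodes,
        "block_edges": [[u, v, w, ch] for u, v, w, ch in sorted(blk.block.edges())],
        "regulators": sorted(blk.regulators),
        "composite": blk.composite,
        "n": numbers.n,
        "ell_trails": numbers.ell_trails,
        "ell_regulators": numbers.ell_regulators,
        "fibonacci": numbers.fibonacci,
        "expression": expr.render(),
    }
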