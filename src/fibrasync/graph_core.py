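"""Network data model and I/O for locomotion-style neuronal circuits.

A circuit is a directed weighted multigraph with two coupling channels:
``chem`` (chemical synapses, directed) and ``gap`` (gap junctions,
electrical, undirected -- stored as two directed edges of equal weight).
Parallel edges are folded into integer (or real) weights: the weight of
``u -> v`` on a channel is exactly the edge multiplicity of the multigraph.

Matrix convention: entry ``A[j, i]`` is the total weight of edges ``j -> i``,
so column ``i`` lists the inputs of node ``i``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

CHANNELS = ("chem", "gap")

#: Reversal potentials (volts) by synaptic sign.
V_S_EXCITATORY = 0.0
V_S_INHIBITORY = -70e-3


class NetworkError(ValueError):
    """Raised for malformed or inconsistent network data."""


@dataclass
class LocomotionNetwork:
    """Directed weighted two-channel graph of a neuronal sub-network.

    Node attributes: ``role`` in {"interneuron", "motorneuron", "generic"},
    ``vs`` reversal potential in volts (0 mV excitatory, -70 mV inhibitory),
    and an optional left-right ``pair`` tag.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    # -- construction -------------------------------------------------

    def add_node(self, name: str, role: str = "generic", vs: float = V_S_EXCITATORY,
                 pair: str | None = None) -> None:
        self.graph.add_node(str(name), role=role, vs=float(vs), pair=pair)

    def add_edge(self, tail: str, head: str, weight: float, channel: str) -> None:
        """Add (accumulate) weight on ``tail -> head``.

        Gap edges are symmetrized immediately: the reverse edge of equal
        weight is added as well.
        """
        if channel not in CHANNELS:
            raise NetworkError(f"unknown channel {channel!r}")
        w = float(weight)
        if w <= 0:
            raise NetworkError(f"non-positive weight {weight!r} on {tail}->{head}")
        for node in (tail, head):
            if node not in self.graph:
                self.add_node(node)
        self._bump(tail, head, w, channel)
        if channel == "gap" and tail != head:
            self._bump(head, tail, w, channel)

    def _bump(self, tail: str, head: str, w: float, channel: str) -> None:
        data = self.graph.get_edge_data(tail, head)
        if data is None:
            self.graph.add_edge(tail, head, chem=0.0, gap=0.0)
            data = self.graph.get_edge_data(tail, head)
        data[channel] += w

    # -- views ---------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        """Node names in deterministic (lexicographic) order."""
        return sorted(self.graph.nodes)

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    def node_attr(self, name: str, attr: str):
        return self.graph.nodes[name][attr]

    def vs_vector(self, order: list[str] | None = None) -> np.ndarray:
        order = order or self.nodes
        return np.array([self.graph.nodes[v].get("vs", V_S_EXCITATORY) for v in order])

    def edges(self, channel: str | None = None):
        """Yield ``(tail, head, weight, channel)`` records with weight > 0."""
        wanted = CHANNELS if channel is None else (channel,)
        for u, v, data in self.graph.edges(data=True):
            for ch in wanted:
                w = data.get(ch, 0.0)
                if w > 0:
                    yield u, v, w, ch

    def has_channel(self, channel: str) -> bool:
        return any(True for _ in self.edges(channel))

    def in_edges(self, node: str, channel: str | None = None):
        wanted = CHANNELS if channel is None else (channel,)
        for u, _, data in self.graph.in_edges(node, data=True):
            for ch in wanted:
                w = data.get(ch, 0.0)
                if w > 0:
                    yield u, w, ch

    def out_edges(self, node: str, channel: str | None = None):
        wanted = CHANNELS if channel is None else (channel,)
        for _, v, data in self.graph.out_edges(node, data=True):
            for ch in wanted:
                w = data.get(ch, 0.0)
                if w > 0:
                    yield v, w, ch

    def subgraph(self, nodes) -> "LocomotionNetwork":
        """Induced subgraph on ``nodes`` (attributes and weights preserved)."""
        keep = set(nodes)
        sub = LocomotionNetwork()
        for v in sorted(keep):
            attrs = self.graph.nodes[v]
            sub.add_node(v, role=attrs.get("role", "generic"),
                         vs=attrs.get("vs", V_S_EXCITATORY), pair=attrs.get("pair"))
        for u, v, data in self.graph.edges(data=True):
            if u in keep and v in keep:
                sub.graph.add_edge(u, v, chem=data.get("chem", 0.0),
                                   gap=data.get("gap", 0.0))
        return sub

    def copy(self) -> "LocomotionNetwork":
        out = LocomotionNetwork()
        out.graph = self.graph.copy()
        return out

    def edge_multiset(self) -> dict:
        return {(u, v, ch): w for u, v, w, ch in self.edges()}

    def __eq__(self, other) -> bool:
        if not isinstance(other, LocomotionNetwork):
            return NotImplemented
        return (set(self.graph.nodes) == set(other.graph.nodes)
                and self.edge_multiset() == other.edge_multiset())

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        """Check invariants: positive weights and gap symmetry."""
        for u, v, w, ch in self.edges():
            if w <= 0:
                raise NetworkError(f"non-positive weight on {u}->{v} ({ch})")
            if ch == "gap" and u != v:
                back = self.graph.get_edge_data(v, u) or {}
                if not np.isclose(back.get("gap", 0.0), w):
                    raise NetworkError(
                        f"asymmetric gap pair {u}<->{v}: {w} vs {back.get('gap', 0.0)}")


@dataclass
class AdjacencyMatrix:
    """Square weight matrix with its node order; ``matrix[j, i]`` = weight j->i."""

    matrix: np.ndarray
    order: list[str]
    channel: str
    binary: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.order), len(self.order)):
            raise NetworkError("adjacency shape does not match node order")


def adjacency(network: LocomotionNetwork, channel: str, binary: bool = False,
              order: list[str] | None = None) -> AdjacencyMatrix:
    """Channel adjacency with ``A[j, i]`` = total weight of edges ``j -> i``."""
    if channel not in CHANNELS:
        raise NetworkError(f"unknown channel {channel!r}")
    order = list(order) if order is not None else network.nodes
    index = {v: i for i, v in enumerate(order)}
    a = np.zeros((len(order), len(order)))
    for u, v, w, _ in network.edges(channel):
        a[index[u], index[v]] += w
    if binary:
        a = (a > 0).astype(float)
    return AdjacencyMatrix(a, order, channel, binary)


# -- I/O ----------------------------------------------------------------

TSV_COLUMNS = ("source", "target", "weight", "channel")


def read_network(path, dialect: str = "tsv") -> LocomotionNetwork:
    """Read an edge-list TSV (columns source/target/weight/channel[/sign])
    or an adjacency CSV with node-name header row and column (chem channel).
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "csv":
        return _read_adjacency_csv(path)
    raise NetworkError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path) -> LocomotionNetwork:
    net = LocomotionNetwork()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise NetworkError(f"{path}: empty file")
        header = [h.strip().lower() for h in header]
        # tolerate a node-declaration block: lines "#node<TAB>name[<TAB>role...]"
        for missing in TSV_COLUMNS:
            if missing not in header:
                raise NetworkError(f"{path}: missing column {missing!r}")
        col = {name: header.index(name) for name in header}
        gap_seen: dict[tuple, float] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#node"):
                name = row[1].strip()
                role = row[2].strip() if len(row) > 2 and row[2].strip() else "generic"
                net.add_node(name, role=role)
                continue
            try:
                u = row[col["source"]].strip()
                v = row[col["target"]].strip()
                w = float(row[col["weight"]])
                ch = row[col["channel"]].strip()
            except (IndexError, ValueError) as exc:
                raise NetworkError(f"{path}: malformed row at line {lineno}: {row!r}") from exc
            if w <= 0:
                raise NetworkError(f"{path}: non-positive weight at line {lineno}")
            if ch not in CHANNELS:
                raise NetworkError(f"{path}: unknown channel {ch!r} at line {lineno}")
            if ch == "gap" and u != v:
                # files list each undirected gap edge once, or twice symmetrically
                key = (min(u, v), max(u, v))
                if key in gap_seen:
                    if not np.isclose(gap_seen.pop(key), w):
                        raise NetworkError(
                            f"{path}: asymmetric gap pair {u}<->{v} at line {lineno}")
                    continue
                gap_seen[key] = w
            net.add_edge(u, v, w, ch)
            if "sign" in col and len(row) > col["sign"] and row[col["sign"]].strip():
                sign = row[col["sign"]].strip().lower()
                if sign not in ("exc", "inh"):
                    raise NetworkError(f"{path}: unknown sign {sign!r} at line {lineno}")
                net.graph.nodes[u]["vs"] = V_S_INHIBITORY if sign == "inh" else V_S_EXCITATORY
    net.validate()
    return net


def _read_adjacency_csv(path: Path) -> LocomotionNetwork:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise NetworkError(f"{path}: empty file")
    names = [c.strip() for c in rows[0][1:]]
    net = LocomotionNetwork()
    for name in names:
        net.add_node(name)
    for lineno, row in enumerate(rows[1:], start=2):
        tail = row[0].strip()
        if tail not in names:
            raise NetworkError(f"{path}: unknown row node {tail!r} at line {lineno}")
        for head, cell in zip(names, row[1:]):
            w = float(cell)
            if w > 0:
                net.add_edge(tail, head, w, "chem")
    net.validate()
    return net


def write_network(network: LocomotionNetwork, path) -> None:
    """Write an edge-list TSV re-readable by :func:`read_network`.

    Undirected gap edges are written once (u <= v); isolated nodes are kept
    via ``#node`` declaration rows so the round trip preserves the node set.
    """
    network.validate()
    path = Path(path)
    connected = set()
    for u, v, _, _ in network.edges():
        connected.update((u, v))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["source", "target", "weight", "channel", "sign"])
        for name in network.nodes:
            if name not in connected:
                writer.writerow(["#node", name, network.graph.nodes[name].get("role", "generic")])
        for u, v, w, ch in sorted(network.edges()):
            if ch == "gap" and u > v:
                continue  # written once from the (min, max) side
            sign = "inh" if network.graph.nodes[u].get("vs", 0.0) < -1e-3 else "exc"
            weight = int(w) if float(w).is_integer() else repr(w)
            writer.writerow([u, v, weight, ch, sign])
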