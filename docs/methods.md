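# Methods

## Graph model

A circuit is a directed weighted multigraph over two channels: chemical
synapses (directed) and gap junctions (undirected, stored as two directed
edges of equal weight, an invariant every constructor enforces). Parallel
edges are folded into weights — the weight of `u → v` on a channel *is* the
edge multiplicity, which is exactly what every downstream formula consumes
through the adjacency matrix `Ã` (entry `(j, i)` = total weight `j → i`;
column `i` lists the inputs of neuron `i`). Node order for all matrices is
the lexicographically sorted node list unless an explicit order is passed,
and every matrix carries its order, so outputs are reproducible across
runs. Chemical sign lives on the presynaptic node as a reversal potential
`V_s` (0 mV excitatory — the default, since the studied circuits are
treated as all-excitatory — or −70 mV inhibitory).

## Fibers, input trees, orbits

The fiber partition is computed as the **minimal balanced coloring**:
starting from the all-one-cell partition, nodes are repeatedly split by
their input profile — the map (channel, source cell) → total incoming
weight — until a fixed point. The fixed point is the coarsest balanced
partition and is independent of processing order. (The classical
description colors every node uniquely and merges; both procedures have the
same fixed point, and top-down splitting is the standard formulation for
the coarsest equitable refinement.) In binary mode the profile counts edges
instead of summing weights.

Input trees are layered walk trees: layer `i` holds one entry per walk of
length `i` terminating at the root, with an integer edge weight `w`
contributing `w` parallel entries. Layer counts follow
`a_{i+1} = Σ (weighted in-degree of layer-i sources)` and are computed by
vector iteration (`m_{i+1} = Ã m_i`), so deep trees cost a matrix-vector
product per layer; explicit layers are materialized only below a size cap.
Tree isomorphism is decided by canonical forms (recursively sorted child
signatures, memoized per (node, depth)). Depth `n − 1` suffices to separate
all non-isomorphic trees, and at that depth isomorphism classes coincide
with the fibers — a property the test suite asserts on random graphs.

Automorphisms are found by exact backtracking over permutations that
preserve every channel's weighted adjacency entry-for-entry, pruned by an
equitable refinement over joint in/out profiles. The search refuses graphs
above 64 nodes (whole-connectome automorphism analysis is out of scope; the
circuits of interest have ≤ 30 neurons). Orbits are computed without
enumerating the group: for each candidate pair inside a refinement class, a
single automorphism mapping one node to the other is searched, and the
whole permutation is folded into a union-find, which yields the exact orbit
partition.

## Building blocks and fiber numbers

A fiber's building block is the induced subgraph on (1) the fiber, (2) its
immediate in-neighbors, (3) the shortest directed non-self loop through a
fiber node, and (4), if those pieces are disconnected, the shortest
reconnecting paths (the *composite* case). Shortest loops and paths come
from breadth-first search with lexicographic tie-breaks. Regulators are
block nodes with only outgoing edges inside the block, plus fiber nodes
feeding back into the fiber; a self-sustained block (the fiber alone, with
no external input) is defined to have zero regulators, which keeps the
all-internal square motif at `|2, 0⟩`.

The branching ratio `n` is computed two ways and required to agree within
1e-6: the `k`-step ratio of input-tree layer counts at large depth (k = 12
absorbs periodic oscillation of the counts) and the spectral radius of the
weighted adjacency restricted to the root's in-component. When the dominant
eigenvalue is defective the plain ratio converges only like `1/depth`; a
Richardson extrapolation over two depths removes the bias, and if agreement
still fails a warning reports both estimates and the spectral value is
returned. Acyclic in-components give `n = 0`.

The trail count `ℓ` enumerates edge-distinct walks terminating at the
collapsed root, in the unweighted base of the block with the root's
outgoing edges removed — the convention forced by the worked three-node
example whose six trails the test suite reproduces. Because the literature
uses `ℓ` both for trails and for regulator counts, both numbers
are computed and reported; renderings default to trails. Multilayer
expressions put the main block in layer 1 and each layer's regulators'
blocks in the next, until every cell appears once.

## Admissible dynamics

All quantities are SI internally (volts, seconds, amperes); the defaults
are `α_leak = 10 s⁻¹`, `α_gap = α_chem = 100 s⁻¹`, `C = 1 pF`
(`α_ext = 1/C`), `γ = 125 V⁻¹`, `a_r = 1 s⁻¹`, `a_d = 5 s⁻¹`,
`V_rest = −35 mV`. Both −35 mV and −37 mV circulate in the literature for the resting
potential; −35 mV is the default
and the parameter is configurable. The sigmoid is centered at each
neuron's threshold voltage, and `s_eq = a_r/(a_r + 2 a_d) = 1/11 ≈ 0.09`.

The equilibrium (threshold) voltages solve the linear system obtained by
setting the model right-hand side to zero with the sigmoid pinned at 1/2
(and `s = s_eq` for type II). Two printed ambiguities are resolved by
construction and validated by a machine-precision residual check of the
RHS at the solution: the off-diagonal of the system matrix is the
per-entry gap term `−(α_gap/α_leak) Ãᵍᵃᵖ_ji` (not a row sum), and the
external-current term sits inside the `1/α_leak` factor (forced by the
isolated-neuron closed form `V* = V_rest + I/(C α_leak)`). The solve is
model-aware — the gap model keeps only gap terms, the chemical models only
chemical terms — matching the single-channel right-hand sides exactly.

Integration is fixed-step RK4 at dt = 0.1 ms. The noise term is one
Gaussian random walk per driven cell (shared inside the cell so the
stimulus stays balanced), with `√dt`-scaled increments and the whole path
min-max rescaled into `[−amp, +amp]`; it is precomputed on the time grid
and held constant across the stages of each step, so a seed fixes the
trajectory bit-for-bit.

## Stability

The gap Jacobian is `−α_leak I − α_gap L` with `L` the in-weight Laplacian
of the (symmetric) gap adjacency: its spectrum is bounded above by
`−α_leak`, attained on the uniform vector, so gap circuits are stable under
any drive. The chemical Jacobians are derived by direct differentiation of
the right-hand sides at the equilibrium (`Φ = 1/2`, `Φ' = γ/4`,
`s = s_eq`); the sign of one cross term in commonly printed forms of the
type-I Jacobian conflicts with direct differentiation, so the derivation is trusted
and central finite differences are the arbiter (relative error < 1e-6 in
the suite). Instability thresholds scan the drive at 0.1 pA and bisect to
0.01 pA on the first sign change of the largest eigenvalue real part
(positive means real part > 1e-9 s⁻¹), matching the two-decimal precision
the thresholds are conventionally reported at.

## Synchrony scores

LoS uses the last second of simulated time and σ = 0.1 mV, the scale at
which a constant 0.1 mV offset scores exactly `e^{−1/2} ≈ 0.61`. The
agreement score binarizes LoS at `1 − 10⁻³` (the underlying rounding rule
— entries below 1 drop to zero — states no precision; the tolerance is a
knob) and divides the ideal-minus-binarized off-diagonal sum by
`2(n² − n)`. PLV takes instantaneous phases from the analytic (Hilbert)
signal of de-meaned traces; constant signals have no phase, so identical
constant pairs score 1 and mixed pairs 0, flagged in the matrix contract.

## Synthetic data

Planted lifts realize each base edge `x → b` of integer weight `w` by
giving every lifted node of `b` exactly `w` unit inputs with uniformly drawn
tails in fiber(x), so the planted partition is balanced by construction;
when the base's own minimal coloring is discrete ("identifiable"), the
partitioner provably recovers the planted partition, which the suite checks
over 50 seeds. Gap edges are lifted symmetrically — unit permutations
between equal-size fibers (unequal sizes are rejected: a `w`-regular
bipartite demand needs `p·w = q·w`), cycle/matching decompositions within a
fiber, and a flagged self-pairing fallback when the parity demand is
unsatisfiable.

The locomotion fixture lifts a 7-class base (interneuron left-right pairs
AVB/PVC/RIB driving motor classes DB/VB over chemical edges, with gap
coupling between the command pairs and inside motor classes) into an
18-node circuit. It emulates the repaired sub-networks' class structure,
integer weights and left-right symmetry; it does not reproduce their exact
wiring, their size (20–30 neurons) or their specific fiber counts, so
passing tests certify the algorithms and the symmetry–dynamics link, not
the biological circuits themselves. Weight perturbation adds zero-mean
Gaussian noise per edge (gap pairs jointly), preserves the zero pattern,
and floors weights at 1e-6 by default since negative conductances are
unphysical (the floor can be disabled). The perturbation is implemented as
addition; with zero mean this is equivalent to subtracting the
same zero-mean draw.

Protocol builders return declarative configurations for the three
simulation tests: (1) no stimulus, initial voltages `N(V_rest, sd)` with sd
swept 0–0.1 (read as millivolts) and
synaptic variables `N(s_eq, sd)`; (2) constant drive at 90% of the
instability threshold plus a 5% oscillation, 2 Hz into interneurons and
1 Hz into motor neurons, with a second motor drive group for gap networks;
(3) 0.1 pA constant + 0.5 pA oscillation + 0.01 pA noise (0.61 pA peak),
equilibrium initial conditions, weight-noise sd swept 0–0.1 in 0.01 steps
with 10 averaged replicates.

## Problem sizes and limitations

The suite and example runs use 2–30-node circuits, simulations of 0.2–3 s
at dt = 0.1 ms, 50-seed recovery sweeps and 20–30-case oracle comparisons;
these sizes were chosen so every structural claim can be cross-checked by
brute force (exhaustive partition merges, full permutation enumeration,
independent trail recursion). Known limitations: trail enumeration is
exponential and refuses blocks above 64 edges; the automorphism search is
exact but not a canonical-labeling tool and is refused above 64 nodes;
multigraph structure beyond summed weights (distinct parallel-edge
identities) is not represented; and dual-role neurons, inhibitory
DD/VD/AS circuitry, rectifying gap junctions and time delays are out of
scope.
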