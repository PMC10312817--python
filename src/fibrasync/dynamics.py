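"""Admissible ODE models for neuronal circuits: gap, Chem type I, Chem type II.

All three couple each neuron only through its inputs (column ``i`` of the
weighted adjacency), which is what makes them admissible: nodes in the same
fiber of the network necessarily share a synchronous solution.

State is in SI units internally (volts, seconds, amperes); convenience I/O
uses mV and pA.  Models:

    gap     V'_i = -a_leak (V_i - V_rest) - a_gap  sum_j A^gap_ji (V_i - V_j) + a_ext I_i
    chem1   V'_i = -a_leak (V_i - V_rest) - a_chem sum_j A^chem_ji Phi(V_j) (V_i - Vs_j) + a_ext I_i
    chem2   V'_i = ... s_j in place of Phi(V_j), with
            s'_i = a_r Phi(V_i) (1 - s_i) - a_d s_i

where ``Phi(V) = 1 / (1 + exp(-gamma (V - V_threshold)))`` is centered at
each neuron's equilibrium (threshold) voltage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .graph_core import LocomotionNetwork, NetworkError, adjacency
from .partitioning import Coloring

MODELS = ("gap", "chem1", "chem2")

PA = 1e-12  # pico-ampere in SI
MV = 1e-3   # millivolt in SI


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and reversal potentials of the admissible models.

    Defaults follow the standard C. elegans single-compartment values:
    leak conductance over capacitance 10 1/s, synaptic and electrical
    coupling rates 100 1/s, sigmoid steepness 125 1/V (a 0.1-to-0.9 rise
    over 36 mV), synaptic rise/decay 1 and 5 1/s, membrane capacitance
    1 pF and resting potential -35 mV.
    """

    model: str = "chem2"
    alpha_leak: float = 10.0       # 1/s
    alpha_gap: float = 100.0       # 1/s
    alpha_chem: float = 100.0      # 1/s
    capacitance: float = 1e-12     # F; alpha_ext = 1/C
    gamma: float = 125.0           # 1/V
    a_r: float = 1.0               # 1/s
    a_d: float = 5.0               # 1/s
    v_rest: float = -35e-3         # V

    def __post_init__(self):
        if self.model not in MODELS:
            raise NetworkError(f"unknown model {self.model!r}")
        for name in ("alpha_leak", "alpha_gap", "alpha_chem", "gamma",
                     "a_r", "a_d", "capacitance"):
            if getattr(self, name) <= 0:
                raise NetworkError(f"{name} must be positive")

    @property
    def alpha_ext(self) -> float:
        return 1.0 / self.capacitance

    @property
    def s_eq(self) -> float:
        """Synaptic-variable fixed point with the sigmoid at 1/2."""
        return self.a_r / (self.a_r + 2.0 * self.a_d)

    @property
    def sigmoid_gain(self) -> float:
        """Phi'(V_threshold) = gamma / 4."""
        return self.gamma / 4.0

    def with_model(self, model: str) -> "ModelParams":
        return replace(self, model=model)


# ---------------------------------------------------------------------------
# Equilibrium (threshold) voltages


def _coupling_matrices(network: LocomotionNetwork, params: ModelParams,
                       order: list[str]):
    """Channel matrices active under the given model (others are zero)."""
    n = len(order)
    a_gap = np.zeros((n, n))
    a_chem = np.zeros((n, n))
    if params.model == "gap":
        a_gap = adjacency(network, "gap", order=order).matrix
    else:
        a_chem = adjacency(network, "chem", order=order).matrix
    return a_gap, a_chem


def threshold_voltages(network: LocomotionNetwork, params: ModelParams,
                       i_drive: np.ndarray | float = 0.0,
                       order: list[str] | None = None) -> np.ndarray:
    """Equilibrium voltages V_threshold solving A V = b with the sigmoid
    pinned at 1/2 (and s at s_eq for chem2).

    A_ii = 1 + (1/a_leak) sum_j (a_gap A^gap_ji + c a_chem A^chem_ji),
    A_ij = -(a_gap/a_leak) A^gap_ji,
    b_i  = V_rest + (1/a_leak) (sum_j c a_chem A^chem_ji Vs_j + a_ext I_i),
    with c = 1/2 (chem type I) or s_eq (chem type II).  The returned vector
    is an exact zero of the model RHS at the sigmoid midpoint.
    """
    order = list(order) if order is not None else network.nodes
    n = len(order)
    i_drive = np.broadcast_to(np.asarray(i_drive, dtype=float), (n,))
    a_gap, a_chem = _coupling_matrices(network, params, order)
    c = params.s_eq if params.model == "chem2" else 0.5
    vs = network.vs_vector(order)

    in_gap = a_gap.sum(axis=0)          # sum_j A^gap_ji
    in_chem = a_chem.sum(axis=0)
    a = np.diag(1.0 + (params.alpha_gap * in_gap + c * params.alpha_chem * in_chem)
                / params.alpha_leak)
    a -= (params.alpha_gap / params.alpha_leak) * a_gap.T
    b = (params.v_rest
         + (c * params.alpha_chem * (a_chem * vs[:, None]).sum(axis=0)
            + params.alpha_ext * i_drive) / params.alpha_leak)
    try:
        v = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise NetworkError(
            f"singular threshold system for model {params.model!r}") from exc
    return v


# ---------------------------------------------------------------------------
# Right-hand sides


def sigmoid(v: np.ndarray, v_threshold: np.ndarray, params: ModelParams) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-params.gamma * (v - v_threshold)))


def rhs(model: str, state: np.ndarray, t: float, network: LocomotionNetwork,
        params: ModelParams, i_ext: np.ndarray | float = 0.0,
        v_threshold: np.ndarray | None = None,
        order: list[str] | None = None) -> np.ndarray:
    """Time derivative of the state for one admissible model.

    ``state`` has length n for gap/chem1 and 2n (voltages then synaptic
    variables) for chem2.  ``i_ext`` is the instantaneous external current
    per node (A).
    """
    params = params if params.model == model else params.with_model(model)
    order = list(order) if order is not None else network.nodes
    n = len(order)
    expected = 2 * n if model == "chem2" else n
    if state.shape[-1] != expected:
        raise NetworkError(f"state dimension {state.shape[-1]} != {expected}")
    a_gap, a_chem = _coupling_matrices(network, params, order)
    i_ext = np.broadcast_to(np.asarray(i_ext, dtype=float), (n,))
    if v_threshold is None:
        v_threshold = threshold_voltages(network, params, 0.0, order)
    vs = network.vs_vector(order)

    v = state[:n]
    leak = -params.alpha_leak * (v - params.v_rest)
    drive = params.alpha_ext * i_ext
    if model == "gap":
        # sum_j A_ji (V_i - V_j) = in-degree_i * V_i - (A^T V)_i
        coupling = params.alpha_gap * (a_gap.sum(axis=0) * v - a_gap.T @ v)
        return leak - coupling + drive
    if model == "chem1":
        phi = sigmoid(v, v_threshold, params)
        coupling = params.alpha_chem * (a_chem * phi[:, None]) .sum(axis=0) * v \
            - params.alpha_chem * ((a_chem * (phi * vs)[:, None]).sum(axis=0))
        return leak - coupling + drive
    # chem2
    s = state[n:]
    gate = a_chem * s[:, None]
    coupling = params.alpha_chem * (gate.sum(axis=0) * v - (gate * vs[:, None]).sum(axis=0))
    dv = leak - coupling + drive
    phi = sigmoid(v, v_threshold, params)
    ds = params.a_r * phi * (1.0 - s) - params.a_d * s
    return np.concatenate([dv, ds])


# ---------------------------------------------------------------------------
# External stimulus


@dataclass
class StimulusSpec:
    """Per-node external current I(t) = I_drive + I_osc sin(2 pi f t + phase)
    + I_noise, with one shared seeded random-walk noise path per driven cell.
    """

    order: list[str]
    i_drive: np.ndarray
    i_osc: np.ndarray
    frequency: np.ndarray
    noise_amp: np.ndarray
    phase: np.ndarray
    noise_groups: list[list[int]] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def zero(cls, order: list[str], seed: int = 0) -> "StimulusSpec":
        n = len(order)
        z = np.zeros(n)
        return cls(list(order), z.copy(), z.copy(), z.copy(), z.copy(), z.copy(),
                   [], seed)

    def sample(self, times: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Stimulus matrix (nodes x time) on the given grid.

        The noise term is a Gaussian random walk with sqrt(dt) increments,
        min-max rescaled into [-amp, +amp] over the run, one path per
        driven cell (shared within the cell to keep the stimulus balanced).
        """
        rng = rng or np.random.default_rng(self.seed)
        n = len(self.order)
        out = (self.i_drive[:, None]
               + self.i_osc[:, None] * np.sin(2 * np.pi * self.frequency[:, None] * times[None, :]
                                              + self.phase[:, None]))
        if times.size > 1:
            dt = float(times[1] - times[0])
            for group in self.noise_groups:
                amp = float(self.noise_amp[group[0]])
                if amp <= 0:
                    continue
                walk = np.cumsum(rng.standard_normal(times.size) * np.sqrt(dt))
                span = walk.max() - walk.min()
                if span > 0:
                    walk = 2 * amp * (walk - walk.min()) / span - amp
                out[group, :] += walk[None, :]
        return out


def make_stimulus(network: LocomotionNetwork, coloring: Coloring | None, targets,
                  i_drive: float = 0.0, i_osc: float = 0.0, frequency: float = 0.0,
                  noise_amp: float = 0.0, phase: float = 0.0, seed: int = 0,
                  balanced: bool = True,
                  per_target: dict | None = None) -> StimulusSpec:
    """Stimulus driving the given target nodes.

    In balanced mode the targets must be a union of whole fiber cells of
    ``coloring`` (a stimulus that splits a cell would break the fibration
    symmetry) and all members of a cell share one noise path.
    ``per_target`` may override (i_drive, i_osc, frequency, noise_amp,
    phase) per node name.
    """
    order = network.nodes
    targets = set(targets)
    if not targets <= set(order):
        raise NetworkError(f"unknown stimulus targets {sorted(targets - set(order))}")
    spec = StimulusSpec.zero(order, seed)
    if not targets:
        return spec
    if balanced:
        if coloring is None:
            raise NetworkError("balanced mode requires a coloring")
        for cell in coloring.cells:
            hit = cell & targets
            if hit and hit != cell:
                raise NetworkError(
                    f"stimulus splits fiber cell {sorted(cell)}: only {sorted(hit)} driven")
    index = {v: i for i, v in enumerate(order)}
    for name in targets:
        i = index[name]
        over = (per_target or {}).get(name, {})
        spec.i_drive[i] = over.get("i_drive", i_drive)
        spec.i_osc[i] = over.get("i_osc", i_osc)
        spec.frequency[i] = over.get("frequency", frequency)
        spec.noise_amp[i] = over.get("noise_amp", noise_amp)
        spec.phase[i] = over.get("phase", phase)
    if balanced and coloring is not None:
        groups = [sorted(index[v] for v in cell & targets)
                  for cell in coloring.cells if cell & targets]
    else:
        groups = [[index[v]] for v in sorted(targets)]
    spec.noise_groups = [g for g in groups if spec.noise_amp[g[0]] > 0]
    # balanced stimuli must be identical within each driven cell
    if balanced and coloring is not None:
        for cell in coloring.cells:
            idx = [index[v] for v in cell & targets]
            for arr in (spec.i_drive, spec.i_osc, spec.frequency,
                        spec.noise_amp, spec.phase):
                if idx and not np.allclose(arr[idx], arr[idx[0]]):
                    raise NetworkError(
                        f"balanced stimulus differs within cell {sorted(cell)}")
    return spec


# ---------------------------------------------------------------------------
# Integration


@dataclass
class SimulationResult:
    times: np.ndarray                 # (T,) seconds
    v: np.ndarray                     # (n, T) volts
    s: np.ndarray | None              # (n, T) for chem2, else None
    order: list[str]
    stimulus: StimulusSpec
    seed: int
    model: str


def simulate(network: LocomotionNetwork, params: ModelParams,
             stimulus: StimulusSpec | None = None,
             init_state: np.ndarray | None = None,
             duration: float = 1.0, dt: float = 1e-4, seed: int = 0,
             v_threshold: np.ndarray | None = None) -> SimulationResult:
    """Integrate one admissible model with fixed-step RK4.

    Noise-free runs are deterministic; with noise the precomputed seeded
    random-walk stimulus (sqrt(dt)-scaled increments) is held piecewise
    constant over each step, so identical seeds give identical
    trajectories.  Divergence (NaN/overflow) aborts with the time reached.
    """
    if duration <= 0:
        raise NetworkError("duration must be positive")
    order = network.nodes
    n = len(order)
    model = params.model
    stimulus = stimulus or StimulusSpec.zero(order, seed)
    steps = int(round(duration / dt))
    times = np.arange(steps + 1) * dt
    i_ext = stimulus.sample(times, np.random.default_rng(seed))
    if v_threshold is None:
        v_threshold = threshold_voltages(network, params, stimulus.i_drive, order)

    dim = 2 * n if model == "chem2" else n
    if init_state is None:
        state = np.full(n, params.v_rest)
        if model == "chem2":
            state = np.concatenate([state, np.full(n, params.s_eq)])
    else:
        state = np.asarray(init_state, dtype=float).copy()
        if state.shape != (dim,):
            raise NetworkError(f"init_state shape {state.shape} != ({dim},)")

    traj = np.empty((dim, steps + 1))
    traj[:, 0] = state

    def f(y, t, i_now):
        return rhs(model, y, t, network, params, i_now, v_threshold, order)

    for k in range(steps):
        t = times[k]
        i_now = i_ext[:, k]
        k1 = f(state, t, i_now)
        k2 = f(state + 0.5 * dt * k1, t + 0.5 * dt, i_now)
        k3 = f(state + 0.5 * dt * k2, t + 0.5 * dt, i_now)
        k4 = f(state + dt * k3, t + dt, i_now)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(f"simulation diverged at t = {t + dt:.6f} s")
        traj[:, k + 1] = state

    v = traj[:n]
    s = traj[n:] if model == "chem2" else None
    return SimulationResult(times, v, s, order, stimulus, seed, model)
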