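"""Linear stability of the admissible models at their equilibrium.

The gap Jacobian is ``-a_leak I - a_gap L`` with ``L`` the in-weight
Laplacian of the gap adjacency; it does not depend on the external drive,
so gap networks are stable for any stimulus.  The chemical Jacobians are
obtained by differentiating the model right-hand sides at the equilibrium
(sigmoid at 1/2, synaptic variables at s_eq); the drive enters through the
equilibrium voltages in the off-diagonal entries, and a large enough
constant current pushes an eigenvalue across zero -- the instability
threshold reported by :func:`instability_threshold`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import MODELS, ModelParams, threshold_voltages
from .graph_core import LocomotionNetwork, NetworkError, adjacency

PA = 1e-12

EIG_POSITIVE_TOL = 1e-9  # 1/s: real parts above this count as unstable


def jacobian(network: LocomotionNetwork, params: ModelParams,
             i_drive: np.ndarray | float = 0.0,
             order: list[str] | None = None) -> np.ndarray:
    """Analytic Jacobian of the model RHS at the equilibrium point.

    gap:    J = -a_leak I - a_gap L (drive-independent),
            L_ii = sum_j A^gap_ji, L_ij = -A^gap_ji.
    chem1:  J_ii = -a_leak - (a_chem/2) sum_j A^chem_ji,
            J_ik += -a_chem A^chem_ki Phi'(V_k)(V_i - Vs_k), Phi' = gamma/4.
    chem2:  2n x 2n block matrix over (V, s) with
            dV'_i/ds_j = -a_chem A^chem_ji (V_i - Vs_j) at V = V_threshold.
    """
    order = list(order) if order is not None else network.nodes
    n = len(order)
    model = params.model
    if model == "gap":
        a_gap = adjacency(network, "gap", order=order).matrix
        lap = np.diag(a_gap.sum(axis=0)) - a_gap.T
        return -params.alpha_leak * np.eye(n) - params.alpha_gap * lap

    a_chem = adjacency(network, "chem", order=order).matrix
    vth = threshold_voltages(network, params, i_drive, order)
    vs = network.vs_vector(order)
    in_chem = a_chem.sum(axis=0)
    gain = params.sigmoid_gain  # gamma/4
    if model == "chem1":
        j = np.diag(-params.alpha_leak - 0.5 * params.alpha_chem * in_chem)
        # d/dV_k of -a_chem A_ki Phi(V_k)(V_i - Vs_k); rows i, cols k
        j += -params.alpha_chem * gain * (vth[:, None] - vs[None, :]) * a_chem.T
        return j
    if model == "chem2":
        s_eq = params.s_eq
        jvv = np.diag(-params.alpha_leak - s_eq * params.alpha_chem * in_chem)
        jvs = -params.alpha_chem * (vth[:, None] - vs[None, :]) * a_chem.T
        jsv = np.diag(np.full(n, params.a_r * gain * (1.0 - s_eq)))
        jss = np.diag(np.full(n, -0.5 * params.a_r - params.a_d))
        return np.block([[jvv, jvs], [jsv, jss]])
    raise NetworkError(f"unknown model {model!r}")


def finite_difference_jacobian(network: LocomotionNetwork, params: ModelParams,
                               i_drive: np.ndarray | float = 0.0,
                               order: list[str] | None = None,
                               eps_v: float = 1e-7, eps_s: float = 1e-7) -> np.ndarray:
    """Central finite differences of the RHS at the equilibrium (the arbiter
    used to validate the analytic Jacobian)."""
    from .dynamics import rhs

    order = list(order) if order is not None else network.nodes
    n = len(order)
    i_vec = np.broadcast_to(np.asarray(i_drive, dtype=float), (n,))
    vth = threshold_voltages(network, params, i_vec, order)
    if params.model == "chem2":
        x0 = np.concatenate([vth, np.full(n, params.s_eq)])
        eps = np.concatenate([np.full(n, eps_v), np.full(n, eps_s)])
    else:
        x0 = vth.copy()
        eps = np.full(n, eps_v)
    dim = x0.size
    jac = np.empty((dim, dim))
    for k in range(dim):
        dx = np.zeros(dim)
        dx[k] = eps[k]
        fp = rhs(params.model, x0 + dx, 0.0, network, params, i_vec, vth, order)
        fm = rhs(params.model, x0 - dx, 0.0, network, params, i_vec, vth, order)
        jac[:, k] = (fp - fm) / (2 * eps[k])
    return jac


@dataclass
class StabilityReport:
    model: str
    targets: list[str]
    grid: np.ndarray                     # sampled I_ext (A)
    max_real_parts: np.ndarray           # max Re(lambda) per sample
    eigenvalues: list[np.ndarray] = field(repr=False, default_factory=list)
    threshold: float | None = None       # smallest unstable I_ext (A), or None
    bisection_tol: float = 0.01 * PA

    @property
    def stable_everywhere(self) -> bool:
        return self.threshold is None


def _max_real(network, params, targets_idx, n, i_value, order):
    i_vec = np.zeros(n)
    i_vec[targets_idx] = i_value
    eig = np.linalg.eigvals(jacobian(network, params, i_vec, order))
    return float(eig.real.max()), eig


def instability_threshold(network: LocomotionNetwork, params: ModelParams,
                          targets, i_max: float = 500 * PA,
                          coarse_step: float = 0.1 * PA,
                          bisection_tol: float = 0.01 * PA,
                          coloring=None) -> StabilityReport:
    """Smallest constant drive into ``targets`` producing a positive
    eigenvalue real part, by coarse scan plus bisection.

    ``targets`` should form whole fiber cells (checked when a coloring is
    given); all target nodes receive the same current.  Returns a report
    with ``threshold=None`` when the system stays stable up to ``i_max``
    -- always the case for the gap model, whose Jacobian is
    drive-independent.
    """
    order = network.nodes
    n = len(order)
    targets = sorted(set(targets))
    if not set(targets) <= set(order):
        raise NetworkError(f"unknown targets {sorted(set(targets) - set(order))}")
    if coloring is not None:
        for cell in coloring.cells:
            hit = cell & set(targets)
            if hit and hit != cell:
                raise NetworkError(f"targets split fiber cell {sorted(cell)}")
    idx = [order.index(t) for t in targets]

    if params.model == "gap":
        mr, eig = _max_real(network, params, idx, n, 0.0, order)
        grid = np.array([0.0, i_max])
        return StabilityReport(params.model, targets, grid,
                               np.array([mr, mr]), [eig, eig], None, bisection_tol)

    grid = np.arange(0.0, i_max + 0.5 * coarse_step, coarse_step)
    max_parts = np.empty(grid.size)
    eigs: list[np.ndarray] = []
    crossing = None
    for k, i_val in enumerate(grid):
        max_parts[k], eig = _max_real(network, params, idx, n, i_val, order)
        eigs.append(eig)
        if crossing is None and max_parts[k] > EIG_POSITIVE_TOL and k > 0:
            crossing = k
            grid = grid[:k + 1]
            max_parts = max_parts[:k + 1]
            break

    threshold = None
    if crossing is not None:
        lo, hi = grid[crossing - 1], grid[crossing]
        while hi - lo > bisection_tol:
            mid = 0.5 * (lo + hi)
            mr, _ = _max_real(network, params, idx, n, mid, order)
            if mr > EIG_POSITIVE_TOL:
                hi = mid
            else:
                lo = mid
        threshold = hi
    elif max_parts[0] > EIG_POSITIVE_TOL:
        threshold = 0.0
    return StabilityReport(params.model, targets, grid, max_parts, eigs,
                           threshold, bisection_tol)
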