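"""Synchrony metrics: LoS kernel, PLV, ideal partition matrices and scores.

The Level of Synchronicity (LoS) between two voltage traces is the time
average of a Gaussian kernel of their difference,
``LoS_ij = <exp(-(V_i - V_j)^2 / (2 sigma^2))>``, evaluated over a trailing
window (default the last second).  A constant offset equal to the kernel
scale sigma gives exactly ``exp(-1/2) ~ 0.61``.  The Phase Locking Value
(PLV) is the magnitude of the time-averaged unit phasor of the analytic
signal phase difference, which scores phase-locked but amplitude-detuned
pairs as synchronous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .dynamics import SimulationResult
from .graph_core import NetworkError
from .partitioning import Coloring

DEFAULT_SIGMA = 0.1e-3  # volts
DEFAULT_WINDOW = 1.0    # seconds
BINARIZE_TOL = 1e-3


@dataclass
class SynchronyMatrix:
    """Symmetric node-indexed matrix of pairwise scores in [0, 1]."""

    matrix: np.ndarray
    order: list[str]
    metric: str
    window: float = DEFAULT_WINDOW
    sigma: float | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.order), len(self.order)):
            raise NetworkError("synchrony matrix shape does not match node order")
        self.matrix = m

    def value(self, a: str, b: str) -> float:
        i, j = self.order.index(a), self.order.index(b)
        return float(self.matrix[i, j])


def _window_slice(result: SimulationResult, window: float) -> np.ndarray:
    total = float(result.times[-1] - result.times[0])
    if window > total + 1e-12:
        raise NetworkError(f"window {window} s exceeds simulated span {total} s")
    start = result.times[-1] - window
    mask = result.times >= start - 1e-12
    return result.v[:, mask]


def los_matrix(result: SimulationResult, window: float = DEFAULT_WINDOW,
               sigma: float = DEFAULT_SIGMA) -> SynchronyMatrix:
    """Pairwise LoS over the trailing ``window`` seconds."""
    v = _window_slice(result, window)
    diff = v[:, None, :] - v[None, :, :]
    los = np.exp(-diff ** 2 / (2.0 * sigma ** 2)).mean(axis=2)
    np.fill_diagonal(los, 1.0)
    return SynchronyMatrix(los, result.order, "LoS", window, sigma)


def ideal_matrix(coloring: Coloring) -> SynchronyMatrix:
    """Block matrix of the fiber partition: 1 within cells, 0 across."""
    order = sorted(coloring.mapping)
    cid = np.array([coloring.mapping[v] for v in order])
    ideal = (cid[:, None] == cid[None, :]).astype(float)
    return SynchronyMatrix(ideal, order, "ideal")


def agreement_score(los: SynchronyMatrix, ideal: SynchronyMatrix,
                    binarize_tol: float = BINARIZE_TOL) -> float:
    """Table-style agreement between a measured LoS matrix and the ideal
    partition matrix.

    The LoS matrix is binarized (entries below ``1 - binarize_tol`` drop
    to 0) and subtracted from the ideal; the sum over off-diagonal entries
    is divided by ``2 (n^2 - n)``.  Zero means perfect agreement, negative
    values mean extra cross-fiber synchrony, positive values mean missing
    within-fiber synchrony.
    """
    if los.order != ideal.order:
        raise NetworkError("node order mismatch between LoS and ideal matrices")
    n = len(los.order)
    binarized = (los.matrix >= 1.0 - binarize_tol).astype(float)
    diff = ideal.matrix - binarized
    np.fill_diagonal(diff, 0.0)
    return float(diff.sum() / (2.0 * (n * n - n)))


def masked_difference(averaged_los: SynchronyMatrix, mask: SynchronyMatrix,
                      coloring: Coloring) -> float:
    """Mean over within-cell off-diagonal entries of (mask - averaged LoS);
    the weight-perturbation degradation score."""
    if averaged_los.matrix.shape != mask.matrix.shape:
        raise NetworkError("shape mismatch between averaged LoS and mask")
    order = averaged_los.order
    cid = np.array([coloring.mapping[v] for v in order])
    within = (cid[:, None] == cid[None, :])
    np.fill_diagonal(within, False)
    if not within.any():
        return 0.0
    return float((mask.matrix[within] - averaged_los.matrix[within]).mean())


def plv_matrix(result: SimulationResult, window: float = DEFAULT_WINDOW) -> SynchronyMatrix:
    """Pairwise Phase Locking Value over the trailing window.

    Phases come from the analytic (Hilbert) signal of each de-meaned trace.
    Constant signals have no phase: identical constant pairs are reported
    as 1, mixed constant/varying pairs as 0.
    """
    v = _window_slice(result, window)
    centered = v - v.mean(axis=1, keepdims=True)
    varying = centered.std(axis=1) > 1e-15
    phase = np.zeros_like(centered)
    if varying.any():
        phase[varying] = np.angle(hilbert(centered[varying], axis=1))
    phasor = np.exp(1j * (phase[:, None, :] - phase[None, :, :]))
    plv = np.abs(phasor.mean(axis=2))
    # constant signals: equal constants are synchronous, otherwise undefined -> 0
    for i in np.flatnonzero(~varying):
        for j in range(v.shape[0]):
            if not varying[j]:
                plv[i, j] = plv[j, i] = 1.0 if np.allclose(v[i], v[j]) else 0.0
            else:
                plv[i, j] = plv[j, i] = 0.0
    np.fill_diagonal(plv, 1.0)
    return SynchronyMatrix(plv, result.order, "PLV", window)
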