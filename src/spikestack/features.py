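"""Multi-resolution B-spline feature extraction from spike windows.

A decoding window of length M ms is discretized on a fine grid
(``grid_ms`` bins; spike counts per bin). For a chosen number of
interior knots m, a uniform B-spline basis of order 0 or 3 is evaluated
on the grid; the temporal resolution of that basis is M/(m+1) ms. A
trial's feature vector is the basis-weighted spike count per neuron,

    value(n, j) = sum_tau counts[n, tau] * b_j(tau),

laid out neuron-major. Order-0 bases are disjoint indicator bins, so
their features are plain binned spike counts (the rate-coding
representation); order-3 (cubic) bases give smooth overlapping windows
and are the representation of the main model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "Basis",
    "build_basis",
    "bin_patterns",
    "extract_features",
    "feature_matrix",
    "DEFAULT_SEGMENTS",
]

# Default resolution ladder: M/(m+1) in ms for M = 2000 ->
# {2000, 1000, 500, 250, 200, 100, 50, 40, 25, 20}.
DEFAULT_SEGMENTS = (1, 2, 4, 8, 10, 20, 40, 50, 80, 100)


@dataclass(frozen=True)
class Basis:
    """An evaluable uniform B-spline basis on the window grid.

    ``segments`` = m + 1 (number of inter-knot intervals, m interior
    knots); ``resolution_ms`` = window_ms / segments; ``matrix`` has one
    column per basis function, evaluated at the grid-bin centers.
    """

    window_ms: float
    grid_ms: float
    segments: int
    order: int
    matrix: np.ndarray  # (n_grid, J)

    @property
    def knots_m(self) -> int:
        return self.segments - 1

    @property
    def resolution_ms(self) -> float:
        return self.window_ms / self.segments

    @property
    def n_basis(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_grid(self) -> int:
        return self.matrix.shape[0]

    @property
    def grid_centers(self) -> np.ndarray:
        return (np.arange(self.n_grid) + 0.5) * self.grid_ms


def build_basis(
    window_ms: float, grid_ms: float, segments: int, order: int = 3
) -> Basis:
    """Evaluate a uniform B-spline basis with ``segments - 1`` interior knots.

    Order 0 yields ``segments`` disjoint indicator bins; order 3 yields
    ``segments + 3`` clamped cubic splines. Both form a partition of
    unity on the window interior. Raises if the requested resolution is
    finer than the evaluation grid.
    """
    if order not in (0, 3):
        raise ValueError("order must be 0 or 3")
    if segments < 1:
        raise ValueError("segments (m + 1) must be >= 1")
    n_grid = int(round(window_ms / grid_ms))
    if abs(n_grid * grid_ms - window_ms) > 1e-9:
        raise ValueError("window_ms must be divisible by grid_ms")
    if window_ms / segments < grid_ms - 1e-9:
        raise ValueError("knots too dense for the evaluation grid")
    tau = (np.arange(n_grid) + 0.5) * grid_ms
    edges = np.linspace(0.0, window_ms, segments + 1)
    if order == 0:
        idx = np.minimum((tau // (window_ms / segments)).astype(int), segments - 1)
        matrix = np.zeros((n_grid, segments))
        matrix[np.arange(n_grid), idx] = 1.0
    else:
        knots = np.concatenate(
            ([0.0] * order, edges, [window_ms] * order)
        )
        matrix = BSpline.design_matrix(tau, knots, order).toarray()
    return Basis(
        window_ms=window_ms,
        grid_ms=grid_ms,
        segments=segments,
        order=order,
        matrix=matrix,
    )


def bin_patterns(ensemble, grid_ms: float) -> np.ndarray:
    """Bin an ensemble's spike times into (n_trials, n_neurons, n_grid)
    count arrays on the feature grid."""
    n_grid = int(round(ensemble.window_ms / grid_ms))
    if abs(n_grid * grid_ms - ensemble.window_ms) > 1e-9:
        raise ValueError("window_ms must be divisible by grid_ms")
    out = np.zeros((ensemble.n_trials, ensemble.n_neurons, n_grid), dtype=np.int64)
    for t in range(ensemble.n_trials):
        for n in range(ensemble.n_neurons):
            times = ensemble.spikes[t][n]
            if times.size == 0:
                continue
            if times.min() < 0 or times.max() >= ensemble.window_ms:
                raise ValueError(
                    f"spike outside [0, {ensemble.window_ms}) for trial {t}, "
                    f"neuron {n}"
                )
            idx = (times // grid_ms).astype(int)
            out[t, n] = np.bincount(idx, minlength=n_grid)
    return out


def extract_features(counts: np.ndarray, basis: Basis) -> np.ndarray:
    """Feature vector for one trial: (n_neurons * J,), neuron-major.

    ``counts`` is the (n_neurons, n_grid) spike-count matrix of one
    trial. Entry n * J + j equals sum_tau counts[n, tau] * b_j(tau).
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] != basis.n_grid:
        raise ValueError(
            f"counts shape {counts.shape} does not match basis grid "
            f"({basis.n_grid} bins)"
        )
    return (counts @ basis.matrix).ravel()


def feature_matrix(patterns: np.ndarray, basis: Basis) -> np.ndarray:
    """Stack ``extract_features`` over trials: (n_trials, n_neurons * J)."""
    patterns = np.asarray(patterns)
    if patterns.ndim != 3 or patterns.shape[2] != basis.n_grid:
        raise ValueError("patterns must be (n_trials, n_neurons, n_grid)")
    n_trials = patterns.shape[0]
    feats = np.tensordot(patterns, basis.matrix, axes=([2], [0]))
    return feats.reshape(n_trials, -1)
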