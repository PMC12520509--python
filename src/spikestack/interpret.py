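"""Model interpretation: classification surfaces, masking, sparseness.

A fitted stacked decoder can be unfolded into a sparse classification
functional matrix (SCFM): a neurons x time surface

    F'(n, tau) = logistic( w'_0 + sum_m w'_m ( w^m_0 +
                           sum_j b_j^m(tau) w^m_{n,j} ) )

evaluated on the feature grid, where w^m are a base learner's
coefficients, b_j^m the B-spline basis functions and w' the
meta-learner weights. With base intercepts folded through the stacking
path, the surface equals a constant baseline wherever no nonzero
coefficient acts, so the signed map (surface - baseline) is exactly
zero outside the model's coefficient support: positive cells mark
(neuron, time) regions where a spike raises the predicted probability
of the decoded category, negative cells where it lowers it. Surfaces
are computed per bagging replica and averaged.

From the SCFM follow the sparseness summaries (spatial: fraction of
neurons with an all-zero surface; temporal: per contributing neuron,
the fraction of the window at baseline), the inner-product masking of
spike patterns, and a ground-truth recovery score for synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SCFM",
    "SparsenessSummary",
    "compute_scfm",
    "mask_pattern",
    "sparseness",
    "scfm_recovery_score",
    "recovery_null",
]


@dataclass
class SCFM:
    """Replica-averaged classification surface for one category."""

    category: str
    surface: np.ndarray  # (n_neurons, n_grid), values in (0, 1)
    baseline: float  # replica-averaged baseline probability in (0, 1)
    signed_map: np.ndarray  # surface - baseline; exactly 0 off-support
    support_mask: np.ndarray  # bool (n_neurons, n_grid)
    grid_ms: float

    @property
    def n_neurons(self) -> int:
        return self.surface.shape[0]

    @property
    def n_grid(self) -> int:
        return self.surface.shape[1]


@dataclass(frozen=True)
class SparsenessSummary:
    spatial: float  # fraction of neurons with an all-zero surface
    temporal_per_neuron: np.ndarray  # fraction of window at baseline
    temporal_mean: float


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def compute_scfm(model, bases: dict) -> SCFM:
    """Evaluate the classification surface of a fitted model.

    ``bases`` maps each of the model's resolutions (segments) to its
    evaluated basis. One surface is computed per bagging replica with
    that replica's coefficients and the shared meta weights, then the
    replica surfaces (and baselines) are averaged; averaging
    probabilities keeps values inside (0, 1). For an unstacked
    single-resolution model the meta weight is the identity (w' = 1,
    w'_0 = 0).
    """
    segs = model.segments
    for m in segs:
        if m not in bases:
            raise ValueError(f"no basis supplied for resolution segments={m}")
    n_neurons = model.n_neurons
    n_grid = bases[segs[0]].n_grid
    if model.meta is not None:
        w_meta = np.asarray(model.meta.coef, dtype=float)
        w0_meta = float(model.meta.intercept)
    else:
        w_meta = np.ones(len(segs))
        w0_meta = 0.0

    n_replicas = len(model.banks[segs[0]])
    surface_acc = np.zeros((n_neurons, n_grid))
    baseline_acc = 0.0
    support = np.zeros((n_neurons, n_grid), dtype=bool)
    for r in range(n_replicas):
        logit = np.zeros((n_neurons, n_grid))
        base_scalar = w0_meta
        for mi, m in enumerate(segs):
            bl = model.banks[m][r]
            B = bases[m].matrix  # (n_grid, J)
            W = bl.coef.reshape(n_neurons, -1)  # (n_neurons, J)
            logit += w_meta[mi] * (W @ B.T)
            base_scalar += w_meta[mi] * bl.intercept
            if w_meta[mi] != 0.0:
                touched = (W != 0).astype(np.int8) @ (B.T != 0).astype(np.int8)
                support |= touched > 0
        surface_acc += _sigmoid(logit + base_scalar)
        baseline_acc += _sigmoid(base_scalar)
    surface = surface_acc / n_replicas
    baseline = baseline_acc / n_replicas
    signed = surface - baseline
    signed[~support] = 0.0  # exact zeros off the coefficient support
    return SCFM(
        category=model.category,
        surface=surface,
        baseline=float(baseline),
        signed_map=signed,
        support_mask=support,
        grid_ms=bases[segs[0]].grid_ms,
    )


def mask_pattern(counts: np.ndarray, scfm: SCFM) -> float:
    """Inner product of a spike pattern with the signed SCFM.

    Projects one trial's (n_neurons, n_grid) count matrix onto the
    surface: spikes in positive cells push the score up, spikes in
    negative cells push it down, spikes at baseline contribute nothing.
    """
    counts = np.asarray(counts)
    if counts.shape != scfm.signed_map.shape:
        raise ValueError(
            f"pattern shape {counts.shape} does not match SCFM "
            f"{scfm.signed_map.shape}"
        )
    return float(np.sum(counts * scfm.signed_map))


def sparseness(scfm: SCFM) -> SparsenessSummary:
    """Spatial and temporal sparseness of one category's SCFM.

    Zero cells are judged on coefficient support (L1 fits give exact
    zeros), not on a numeric tolerance. If no neuron contributes, both
    summaries are reported as 1.0 by convention.
    """
    row_active = scfm.support_mask.any(axis=1)
    spatial = 1.0 - row_active.mean()
    if not row_active.any():
        return SparsenessSummary(
            spatial=1.0,
            temporal_per_neuron=np.empty(0),
            temporal_mean=1.0,
        )
    temporal = 1.0 - scfm.support_mask[row_active].mean(axis=1)
    return SparsenessSummary(
        spatial=float(spatial),
        temporal_per_neuron=temporal,
        temporal_mean=float(temporal.mean()),
    )


def _truth_mask(
    ground_truth: dict,
    category_index: int,
    n_neurons: int,
    n_grid: int,
    grid_ms: float,
) -> np.ndarray:
    """Boolean (n_neurons, n_grid) map of positive-gain ground-truth bumps."""
    mask = np.zeros((n_neurons, n_grid), dtype=bool)
    for (n, c), bumps in ground_truth.items():
        if c != category_index:
            continue
        for b in bumps:
            if b.gain_hz <= 0:
                continue
            lo = int(np.floor(b.onset_ms / grid_ms))
            hi = int(np.ceil((b.onset_ms + b.duration_ms) / grid_ms))
            mask[n, lo:hi] = True
    return mask


def scfm_recovery_score(
    scfm: SCFM, ground_truth: dict, category_index: int
) -> float:
    """Mean per-neuron Jaccard overlap between the SCFM's positive cells
    and the injected positive bumps, over neurons that carry ground
    truth for the category. 1 = perfect recovery, ~0 = no overlap."""
    truth = _truth_mask(
        ground_truth, category_index, scfm.n_neurons, scfm.n_grid, scfm.grid_ms
    )
    signal_rows = np.nonzero(truth.any(axis=1))[0]
    if signal_rows.size == 0:
        raise ValueError("no positive ground-truth bumps for this category")
    positive = scfm.signed_map > 0
    scores = []
    for n in signal_rows:
        union = (positive[n] | truth[n]).sum()
        inter = (positive[n] & truth[n]).sum()
        scores.append(inter / union if union else 0.0)
    return float(np.mean(scores))


def recovery_null(
    scfm: SCFM,
    ground_truth: dict,
    category_index: int,
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the recovery score obtained by permuting the
    SCFM's neuron rows (breaking neuron identity, keeping structure)."""
    rng = np.random.default_rng(seed)
    scores = np.empty(n_permutations)
    base = scfm.signed_map
    for i in range(n_permutations):
        perm = rng.permutation(scfm.n_neurons)
        shuffled = SCFM(
            category=scfm.category,
            surface=scfm.surface[perm],
            baseline=scfm.baseline,
            signed_map=base[perm],
            support_mask=scfm.support_mask[perm],
            grid_ms=scfm.grid_ms,
        )
        scores[i] = scfm_recovery_score(shuffled, ground_truth, category_index)
    return scores
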