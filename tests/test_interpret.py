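"""SCFM evaluation against an independent scalar oracle, masking,
sparseness, and ground-truth recovery."""

import math

import numpy as np
import pytest

import spikestack as ss
from spikestack.decoder import BaseLearner, DecodingModel, MetaLearner
from spikestack.features import build_basis
from spikestack.interpret import (
    SCFM,
    compute_scfm,
    mask_pattern,
    recovery_null,
    scfm_recovery_score,
    sparseness,
)
from spikestack.simulate import Bump


def _hand_model(coefs_by_m, intercepts_by_m, meta_coef, meta_intercept, n_neurons):
    """Assemble a DecodingModel from explicit coefficient arrays.

    ``coefs_by_m[m]`` is a list over replicas of (n_neurons * J) arrays.
    """
    banks = {
        m: [
            BaseLearner(segments=m, replica=r, intercept=intercepts_by_m[m][r],
                        coef=np.asarray(c, dtype=float), C=1.0)
            for r, c in enumerate(reps)
        ]
        for m, reps in coefs_by_m.items()
    }
    meta = MetaLearner(intercept=meta_intercept, coef=np.asarray(meta_coef, float), C=1.0)
    return DecodingModel(
        category="hand",
        segments=tuple(coefs_by_m),
        banks=banks,
        meta=meta,
        n_neurons=n_neurons,
        selected_C={m: 1.0 for m in coefs_by_m},
    )


def _oracle_surface(model, bases):
    """Direct scalar re-evaluation of the classification surface."""
    segs = model.segments
    n_grid = bases[segs[0]].n_grid
    R = len(model.banks[segs[0]])
    out = np.zeros((model.n_neurons, n_grid))
    base = 0.0
    for r in range(R):
        for n in range(model.n_neurons):
            for g in range(n_grid):
                logit = model.meta.intercept
                for mi, m in enumerate(segs):
                    bl = model.banks[m][r]
                    J = bases[m].n_basis
                    inner = bl.intercept
                    for j in range(J):
                        inner += bases[m].matrix[g, j] * bl.coef[n * J + j]
                    logit += model.meta.coef[mi] * inner
                out[n, g] += 1.0 / (1.0 + math.exp(-logit))
        logit0 = model.meta.intercept + sum(
            model.meta.coef[mi] * model.banks[m][r].intercept
            for mi, m in enumerate(segs)
        )
        base += 1.0 / (1.0 + math.exp(-logit0))
    return out / R, base / R


def test_scfm_matches_scalar_oracle_to_1e10():
    """Two neurons, two resolutions, two replicas with asymmetric
    weights: the vectorized surface equals brute-force evaluation."""
    bases = {
        2: build_basis(100.0, 10.0, 2, order=3),  # J = 5
        5: build_basis(100.0, 10.0, 5, order=0),  # J = 5
    }
    rng = np.random.default_rng(0)
    coefs = {
        2: [rng.normal(size=10) * (rng.random(10) < 0.6) for _ in range(2)],
        5: [rng.normal(size=10) * (rng.random(10) < 0.6) for _ in range(2)],
    }
    model = _hand_model(
        coefs, {2: [0.3, -0.2], 5: [-1.0, 0.5]}, [1.2, -0.7], 0.4, n_neurons=2
    )
    scfm = compute_scfm(model, bases)
    surf, base = _oracle_surface(model, bases)
    np.testing.assert_allclose(scfm.surface, surf, atol=1e-10)
    assert scfm.baseline == pytest.approx(base, abs=1e-10)


def test_all_zero_coefficients_give_flat_baseline_surface():
    bases = {4: build_basis(200.0, 10.0, 4, order=3)}
    model = _hand_model({4: [np.zeros(2 * 7)]}, {4: [0.8]}, [2.0], -0.5, n_neurons=2)
    scfm = compute_scfm(model, bases)
    assert np.all(scfm.signed_map == 0.0)
    assert np.all(scfm.surface == pytest.approx(scfm.baseline))
    summ = sparseness(scfm)
    assert summ.spatial == 1.0 and summ.temporal_mean == 1.0


def test_zero_logit_gives_half_probability():
    bases = {1: build_basis(100.0, 10.0, 1, order=0)}  # single flat basis
    model = _hand_model({1: [np.array([1.5, 0.0])]}, {1: [-1.5]}, [1.0], 0.0,
                        n_neurons=2)
    scfm = compute_scfm(model, bases)
    # neuron 0: logit = 1.0 * (-1.5 + 1 * 1.5) = 0 -> probability 0.5
    np.testing.assert_allclose(scfm.surface[0], 0.5, atol=1e-12)


def test_signed_map_zero_exactly_off_support():
    bases = {4: build_basis(200.0, 5.0, 4, order=0)}
    coef = np.zeros(2 * 4)
    coef[4 + 1] = 2.0  # neuron 1, second 50-ms bin only
    model = _hand_model({4: [coef]}, {4: [0.1]}, [1.0], 0.0, n_neurons=2)
    scfm = compute_scfm(model, bases)
    assert np.all(scfm.signed_map[0] == 0.0)
    active = scfm.support_mask[1]
    assert active.sum() == 10  # 50 ms of 5-ms grid
    assert np.all(scfm.signed_map[1, active] > 0)
    assert np.all(scfm.signed_map[1, ~active] == 0.0)


def test_surface_monotone_in_positive_coefficient():
    bases = {4: build_basis(200.0, 5.0, 4, order=3)}
    low = np.zeros(7)
    low[2] = 0.5
    high = low.copy()
    high[2] = 1.5
    m_low = _hand_model({4: [low]}, {4: [0.0]}, [1.0], 0.0, n_neurons=1)
    m_high = _hand_model({4: [high]}, {4: [0.0]}, [1.0], 0.0, n_neurons=1)
    s_low = compute_scfm(m_low, bases)
    s_high = compute_scfm(m_high, bases)
    sup = s_low.support_mask[0]
    assert np.all(s_high.surface[0, sup] >= s_low.surface[0, sup])


def test_mask_pattern_signs_and_shapes():
    signed = np.zeros((2, 10))
    signed[0, :5] = 0.2
    signed[1, 5:] = -0.1
    scfm = SCFM(category="x", surface=signed + 0.5, baseline=0.5,
                signed_map=signed, support_mask=signed != 0, grid_ms=10.0)
    assert mask_pattern(np.zeros((2, 10)), scfm) == 0.0
    pos = np.zeros((2, 10))
    pos[0, 2] = 3
    assert mask_pattern(pos, scfm) > 0
    neg = np.zeros((2, 10))
    neg[1, 7] = 2
    assert mask_pattern(neg, scfm) < 0
    with pytest.raises(ValueError):
        mask_pattern(np.zeros((3, 10)), scfm)


def test_masked_scores_separate_categories_when_counts_do_not(
    temporal_ensemble, temporal_result
):
    """Inner products with the decoded category's SCFM separate its
    trials from the rest even though total spike counts do not differ
    (the injected code is count-neutral)."""
    from spikestack.features import bin_patterns

    patterns = bin_patterns(temporal_ensemble, temporal_result.config.grid_ms)
    totals = patterns.sum(axis=(1, 2))
    cat = temporal_result.categories[0]
    scfm = ss.compute_scfm(cat.full_model, temporal_result.bases)
    scores = np.array([mask_pattern(patterns[t], scfm) for t in range(len(totals))])
    pos = cat.y_true == 1
    # spike counts carry no category information...
    t_counts = abs(totals[pos].mean() - totals[~pos].mean()) / totals.std()
    assert t_counts < 0.5
    # ...but the masked scores do
    from scipy import stats

    t, p = stats.ttest_ind(scores[pos], scores[~pos])
    assert t > 2.0 and p < 0.05


def test_sparseness_counts_empty_rows():
    support = np.zeros((10, 20), dtype=bool)
    support[3:, :5] = True  # 7 contributing neurons, 25% of window each
    scfm = SCFM(category="x", surface=np.full((10, 20), 0.5), baseline=0.5,
                signed_map=support.astype(float), support_mask=support, grid_ms=10.0)
    summ = sparseness(scfm)
    assert summ.spatial == pytest.approx(0.3)
    assert summ.temporal_mean == pytest.approx(0.75)
    assert len(summ.temporal_per_neuron) == 7


def test_strong_regularization_yields_temporally_sparse_maps(temporal_ensemble):
    """With signal in ~24% of each coding neuron's window and a strongly
    regularized fit, SCFM support is confined: temporal sparseness well
    above one half."""
    dc = ss.DecoderConfig(
        segments=(20, 100), grid_ms=5.0, n_replicas=2, outer_folds=5,
        inner_folds=3, l1_grid=(0.005, 0.02), seed=3,
    )
    res = ss.nested_cv_fit_predict(temporal_ensemble, dc)
    vals = []
    for cat in res.categories:
        summ = sparseness(ss.compute_scfm(cat.full_model, res.bases))
        vals.append(summ.temporal_mean)
    assert np.mean(vals) > 0.5


def test_recovery_score_extremes():
    truth = {(0, 0): (Bump(0.0, 50.0, 10.0),)}
    signed = np.zeros((2, 20))
    signed[0, :5] = 0.3  # exactly the 50-ms bump on a 10-ms grid
    scfm = SCFM(category="x", surface=signed + 0.5, baseline=0.5,
                signed_map=signed, support_mask=signed != 0, grid_ms=10.0)
    assert scfm_recovery_score(scfm, truth, 0) == pytest.approx(1.0)
    miss = SCFM(category="x", surface=np.full((2, 20), 0.5), baseline=0.5,
                signed_map=np.zeros((2, 20)),
                support_mask=np.zeros((2, 20), bool), grid_ms=10.0)
    assert scfm_recovery_score(miss, truth, 0) == 0.0
    with pytest.raises(ValueError):
        scfm_recovery_score(scfm, truth, 1)


def test_recovery_beats_permuted_row_null(temporal_ensemble, temporal_result):
    margins = []
    for c_idx, cat in enumerate(temporal_result.categories):
        scfm = ss.compute_scfm(cat.full_model, temporal_result.bases)
        score = scfm_recovery_score(scfm, temporal_ensemble.ground_truth, c_idx)
        null = recovery_null(scfm, temporal_ensemble.ground_truth, c_idx,
                             n_permutations=100, seed=5)
        margins.append(score - np.percentile(null, 95))
    assert np.mean(margins) > 0
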