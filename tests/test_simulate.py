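"""Generator contracts: determinism, signal placement, transforms."""

import numpy as np
import pytest

import spikestack as ss
from spikestack.simulate import Bump, SimulationConfig, default_regions


def _count_matrix(ens):
    return np.array(
        [[len(ens.spikes[t][n]) for n in range(ens.n_neurons)]
         for t in range(ens.n_trials)]
    )


def test_identical_seed_gives_bit_identical_ensembles():
    cfg = ss.temporal_code_config(n_neurons=8, n_trials=30, seed=4)
    a, b = ss.simulate_ensemble(cfg), ss.simulate_ensemble(cfg)
    assert np.array_equal(a.labels, b.labels)
    for t in range(a.n_trials):
        for n in range(a.n_neurons):
            assert np.array_equal(a.spikes[t][n], b.spikes[t][n])


def test_background_only_counts_match_poisson_mean():
    """5 Hz background over 2 s -> 10 expected spikes per neuron-trial."""
    cfg = SimulationConfig(n_neurons=10, n_trials=150, rng_seed=0)
    ens = ss.simulate_ensemble(cfg)
    counts = _count_matrix(ens)
    mean = counts.mean()
    sem = counts.std() / np.sqrt(counts.size)
    assert abs(mean - 10.0) < 4 * sem + 1e-9


def test_no_signal_means_no_category_count_differences():
    cfg = SimulationConfig(n_neurons=6, n_trials=200, rng_seed=2)
    ens = ss.simulate_ensemble(cfg)
    totals = _count_matrix(ens).sum(axis=1)
    for c in range(ens.n_categories):
        pos = totals[ens.labels[:, c] == 1]
        neg = totals[ens.labels[:, c] == 0]
        pooled = np.sqrt(pos.var() / len(pos) + neg.var() / len(neg))
        assert abs(pos.mean() - neg.mean()) < 4 * pooled


def test_degenerate_background_confines_spikes_to_bump():
    cfg = SimulationConfig(
        n_neurons=5,
        n_trials=60,
        background_rate_hz=0.0,
        signal_windows={(3, 0): (Bump(500.0, 100.0, 40.0),)},
        rng_seed=9,
    )
    ens = ss.simulate_ensemble(cfg)
    for t in range(ens.n_trials):
        for n in range(ens.n_neurons):
            times = ens.spikes[t][n]
            if n == 3 and ens.labels[t, 0] == 1:
                assert np.all((times >= 500.0) & (times < 600.0))
            else:
                assert times.size == 0


def test_negative_rate_and_out_of_window_bumps_rejected():
    with pytest.raises(ValueError, match="negative instantaneous rate"):
        ss.simulate_ensemble(
            SimulationConfig(
                n_neurons=2,
                n_trials=10,
                background_rate_hz=2.0,
                signal_windows={(0, 0): (Bump(0.0, 100.0, -5.0),)},
                rng_seed=0,
            )
        )
    with pytest.raises(ValueError, match="outside the window"):
        SimulationConfig(
            n_neurons=2,
            n_trials=10,
            signal_windows={(0, 0): (Bump(1950.0, 100.0, 5.0),)},
        )


def test_exclusive_labels_are_one_of_n_and_balanced():
    cfg = SimulationConfig(n_neurons=2, n_trials=100, rng_seed=1)
    ens = ss.simulate_ensemble(cfg)
    assert (ens.labels.sum(axis=1) == 1).all()
    assert set(ens.labels.sum(axis=0)) == {20}


@pytest.mark.parametrize("transform", ["time_shift", "label_shuffle", "circular", "jitter"])
def test_transforms_preserve_shape(transform, temporal_ensemble):
    ens = temporal_ensemble
    out = {
        "time_shift": lambda: ss.time_shift_control(ens),
        "label_shuffle": lambda: ss.label_shuffle_control(ens, seed=3),
        "circular": lambda: ss.circular_shift_surrogate(ens, seed=3),
        "jitter": lambda: ss.jitter_surrogate(ens, seed=3),
    }[transform]()
    assert out.n_trials == ens.n_trials
    assert out.n_neurons == ens.n_neurons
    assert out.window_ms == ens.window_ms


def test_time_shift_control_drops_signal_keeps_labels(temporal_ensemble):
    out = ss.time_shift_control(temporal_ensemble)
    assert np.array_equal(out.labels, temporal_ensemble.labels)
    assert out.ground_truth == {}
    assert out.event_type == "PreSample"
    stripped = temporal_ensemble.copy()
    stripped.presample_spikes = None
    with pytest.raises(ValueError):
        ss.time_shift_control(stripped)


def test_label_shuffle_preserves_label_multiset(temporal_ensemble):
    out = ss.label_shuffle_control(temporal_ensemble, seed=12)
    orig = sorted(map(tuple, temporal_ensemble.labels.tolist()))
    new = sorted(map(tuple, out.labels.tolist()))
    assert orig == new
    assert not np.array_equal(out.labels, temporal_ensemble.labels)
    again = ss.label_shuffle_control(temporal_ensemble, seed=12)
    assert np.array_equal(out.labels, again.labels)


def test_circular_shift_preserves_counts_and_circular_isis(temporal_ensemble):
    out = ss.circular_shift_surrogate(temporal_ensemble, seed=8)
    M = temporal_ensemble.window_ms
    for t in range(0, temporal_ensemble.n_trials, 17):
        for n in range(temporal_ensemble.n_neurons):
            a = temporal_ensemble.spikes[t][n]
            b = out.spikes[t][n]
            assert a.size == b.size
            if a.size >= 2:
                isi_a = np.sort(np.diff(np.r_[a, a[0] + M]))
                isi_b = np.sort(np.diff(np.r_[b, b[0] + M]))
                assert np.allclose(isi_a, isi_b, atol=1e-9)


def test_jitter_preserves_counts_and_mean_displacement(temporal_ensemble):
    a = 20.0
    out = ss.jitter_surrogate(temporal_ensemble, max_jitter_ms=a, seed=8)
    disps = []
    for t in range(temporal_ensemble.n_trials):
        for n in range(temporal_ensemble.n_neurons):
            assert out.spikes[t][n].size == temporal_ensemble.spikes[t][n].size
            orig = temporal_ensemble.spikes[t][n]
            # displacement of the sorted trains bounds the true one; away
            # from edges, matching sorted order recovers it
            if orig.size:
                disps.append(np.abs(np.sort(out.spikes[t][n]) - np.sort(orig)))
    mean_disp = np.concatenate(disps).mean()
    # E|U(-a, a)| = a / 2; sorted matching only shrinks displacements
    assert 0.3 * a < mean_disp <= 0.5 * a + 0.5
    assert all(
        (s >= 0).all() and (s < temporal_ensemble.window_ms).all()
        for trial in out.spikes
        for s in trial
    )


def test_jitter_requires_positive_width(temporal_ensemble):
    with pytest.raises(ValueError):
        ss.jitter_surrogate(temporal_ensemble, max_jitter_ms=0.0, seed=1)


def test_default_regions_follow_probe_layout():
    regions = default_regions(15)
    assert regions[:10] == ("CA3",) * 6 + ("CA1",) * 4
    assert regions.count("CA3") == 11  # 6 + 5 of the second probe


def test_redundant_drive_scales_ca1_rate():
    """rho = 1 with a bijective pairing duplicates driver trains into CA1."""
    cfg = ss.region_coding_config(
        n_neurons=10, n_trials=40, seed=6, ca1_mode="copied", drivers_per_category=3
    )
    ens = ss.simulate_ensemble(cfg)
    counts = _count_matrix(ens)
    ca3 = [i for i, r in enumerate(ens.regions) if r == "CA3"]
    ca1 = [i for i, r in enumerate(ens.regions) if r == "CA1"]
    # paired CA1 neurons inherit their driver's full train: mean rates match
    assert counts[:, ca1].mean() == pytest.approx(counts[:, ca3[:4]].mean(), rel=0.2)
    # ground truth records the inherited bumps on CA1 neurons
    assert any(n in ca1 for (n, _c) in ens.ground_truth)
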