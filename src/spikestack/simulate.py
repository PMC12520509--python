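"""Synthetic spike-ensemble generation and surrogate/control transforms.

The generator emulates the structure of human hippocampal ensemble
recordings collected during a delayed match-to-sample task: ~30 neurons
per subject recorded on a 6:4 CA3:CA1 electrode split, ~150 trials with
one-of-five near-mutually-exclusive image-category labels, and 2-s
decoding windows anchored to task events. Spikes are drawn from an
inhomogeneous Poisson process on a 1-ms grid whose rate is a constant
background plus category-specific rectangular "bumps" assigned per
(neuron, category); the injected bumps are retained as ground truth so
that recovery of the coding structure can be tested.

Control and surrogate transforms mirror the standard null cases:
pre-event (background-only) windows, label shuffling, per-neuron
circular time shifts, and +/- spike-time jitter.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Bump",
    "SimulationConfig",
    "SpikeEnsemble",
    "simulate_ensemble",
    "time_shift_control",
    "label_shuffle_control",
    "circular_shift_surrogate",
    "jitter_surrogate",
    "default_regions",
    "temporal_code_config",
    "rate_code_config",
    "region_coding_config",
    "DEFAULT_CATEGORIES",
]

DEFAULT_CATEGORIES = ("Animal", "Building", "Plant", "Tool", "Vehicle")


@dataclass(frozen=True)
class Bump:
    """Rectangular firing-rate modulation: ``gain_hz`` added on
    ``[onset_ms, onset_ms + duration_ms)``. Negative gains model
    suppression; the summed rate must stay nonnegative."""

    onset_ms: float
    duration_ms: float
    gain_hz: float


def default_regions(n_neurons: int) -> tuple[str, ...]:
    """6:4 CA3:CA1 assignment, repeating the 10-microelectrode probe layout."""
    probe = ("CA3",) * 6 + ("CA1",) * 4
    return tuple(probe[i % 10] for i in range(n_neurons))


@dataclass
class SimulationConfig:
    n_neurons: int
    n_trials: int
    n_categories: int = 5
    window_ms: float = 2000.0
    bin_ms: float = 1.0
    background_rate_hz: float = 5.0
    regions: tuple[str, ...] | None = None
    # (neuron_index, category_index) -> tuple of Bumps
    signal_windows: dict = field(default_factory=dict)
    redundancy_rho: float = 0.0
    copy_jitter_ms: float = 3.0  # synaptic jitter of the inherited CA1 drive
    diffuse_drivers: int = 1  # CA3 drivers pooled by each paired CA1 neuron
    exclusive_labels: bool = True
    category_names: tuple[str, ...] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if self.background_rate_hz < 0:
            raise ValueError("background rate must be nonnegative")
        if self.n_categories < 2:
            raise ValueError("need at least two categories")
        if not 0.0 <= self.redundancy_rho <= 1.0:
            raise ValueError("redundancy_rho must lie in [0, 1]")
        if self.regions is None:
            self.regions = default_regions(self.n_neurons)
        if len(self.regions) != self.n_neurons:
            raise ValueError("one region tag per neuron required")
        if self.category_names is None:
            if self.n_categories == 5:
                self.category_names = DEFAULT_CATEGORIES
            else:
                self.category_names = tuple(
                    f"cat{i}" for i in range(self.n_categories)
                )
        for (n, c), bumps in self.signal_windows.items():
            if not (0 <= n < self.n_neurons and 0 <= c < self.n_categories):
                raise ValueError(f"signal window references unknown ({n}, {c})")
            for b in bumps:
                if b.onset_ms < 0 or b.onset_ms + b.duration_ms > self.window_ms:
                    raise ValueError(
                        f"bump {b} for ({n}, {c}) lies outside the window"
                    )


@dataclass
class SpikeEnsemble:
    """Event-time records for all neurons and trials of one dataset.

    ``spikes[t][n]`` is a sorted array of spike times in ms, relative to
    the start of trial ``t``'s decoding window, half-open ``[0, window_ms)``.
    ``presample_spikes`` holds matching background-only windows recorded
    before stimulus onset (used by the time-shifted control).
    """

    window_ms: float
    category_names: tuple[str, ...]
    regions: tuple[str, ...]
    labels: np.ndarray  # (n_trials, n_categories) of {0,1}
    spikes: list  # [trial][neuron] -> np.ndarray of times (ms)
    presample_spikes: list | None = None
    event_type: str = "SampleResponse"
    ground_truth: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.spikes)

    @property
    def n_neurons(self) -> int:
        return len(self.regions)

    @property
    def n_categories(self) -> int:
        return len(self.category_names)

    def copy(self) -> "SpikeEnsemble":
        return _copy.deepcopy(self)


def redundancy_pairing(config: SimulationConfig) -> dict:
    """CA1 target -> tuple of CA3 drivers pooled by the feedforward drive.

    Drivers are the CA3 neurons that carry signal windows; each CA1
    neuron pools ``diffuse_drivers`` consecutive drivers (cycling in
    index order), mirroring the diffuse CA3->CA1 projection. Empty when
    ``redundancy_rho`` is 0 or either side is missing.
    """
    if config.redundancy_rho == 0.0:
        return {}
    drivers = sorted(
        {n for (n, _c) in config.signal_windows if config.regions[n] == "CA3"}
    )
    ca1 = [i for i, r in enumerate(config.regions) if r == "CA1"]
    if not drivers or not ca1:
        return {}
    k = max(1, min(config.diffuse_drivers, len(drivers)))
    return {
        target: tuple(drivers[(i + j) % len(drivers)] for j in range(k))
        for i, target in enumerate(ca1)
    }


def effective_signal_windows(config: SimulationConfig) -> dict:
    """Ground-truth signal windows including the inherited CA1 drive.

    A CA1 neuron pooling k drivers inherits each driver's bump set
    scaled by ``redundancy_rho / k`` (its expected rate is background +
    (rho/k) * sum of driver bumps; see :func:`simulate_ensemble` for the
    trial-correlated realization).
    """
    windows = {k_: tuple(v) for k_, v in config.signal_windows.items()}
    rho = config.redundancy_rho
    for target, drivers in redundancy_pairing(config).items():
        scale = rho / len(drivers)
        for src in drivers:
            for c in range(config.n_categories):
                bumps = windows.get((src, c), ())
                if not bumps:
                    continue
                scaled = tuple(
                    Bump(b.onset_ms, b.duration_ms, scale * b.gain_hz)
                    for b in bumps
                )
                existing = windows.get((target, c), ())
                windows[(target, c)] = tuple(existing) + scaled
    return windows


def _draw_labels(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    labels = np.zeros((config.n_trials, config.n_categories), dtype=np.int8)
    if config.exclusive_labels:
        cats = np.resize(np.arange(config.n_categories), config.n_trials)
        cats = rng.permutation(cats)
        labels[np.arange(config.n_trials), cats] = 1
    else:
        labels[:] = rng.random((config.n_trials, config.n_categories)) < (
            1.0 / config.n_categories
        )
    return labels


def simulate_ensemble(config: SimulationConfig) -> SpikeEnsemble:
    """Draw a labelled spike ensemble from the configured point process.

    Neurons fire as inhomogeneous Poisson processes (background plus the
    active categories' bumps). A CA1 neuron paired with a CA3 driver
    (``redundancy_rho`` > 0) additionally inherits a thinned,
    few-ms-jittered copy of the driver's realized spike train — a
    feedforward drive that makes the two regions' category information
    redundant at the single-trial level — while its own background is
    scaled by (1 - rho) to keep its mean rate comparable.

    Deterministic given ``config.rng_seed``. Raises ``ValueError`` if
    any trial's summed rate profile would be negative (overlapping
    negative bumps exceeding the background).
    """
    rng = np.random.default_rng(config.rng_seed)
    n_bins = int(round(config.window_ms / config.bin_ms))
    M = config.window_ms
    pairing = redundancy_pairing(config)
    rho = config.redundancy_rho

    # per-(neuron, category) rate increments on the generation grid
    deltas: dict[tuple[int, int], np.ndarray] = {}
    for (n, c), bumps in config.signal_windows.items():
        d = np.zeros(n_bins)
        for b in bumps:
            lo = int(round(b.onset_ms / config.bin_ms))
            hi = int(round((b.onset_ms + b.duration_ms) / config.bin_ms))
            d[lo:hi] += b.gain_hz
        deltas[(n, c)] = d

    labels = _draw_labels(config, rng)
    dt_s = config.bin_ms / 1000.0
    bin_starts = np.arange(n_bins) * config.bin_ms

    def _draw_window(rate: np.ndarray) -> np.ndarray:
        counts = rng.poisson(rate * dt_s)
        idx = np.nonzero(counts)[0]
        if idx.size == 0:
            return np.empty(0)
        starts = np.repeat(bin_starts[idx], counts[idx])
        times = starts + rng.random(starts.size) * config.bin_ms
        return np.sort(times)

    def _reflect(times: np.ndarray) -> np.ndarray:
        folded = np.mod(times, 2.0 * M)
        folded = np.where(folded > M, 2.0 * M - folded, folded)
        return np.minimum(folded, np.nextafter(M, 0.0))

    spikes, presample = [], []
    bg = np.full(n_bins, config.background_rate_hz)
    for t in range(config.n_trials):
        active = np.nonzero(labels[t])[0]
        trial_spikes: list = [None] * config.n_neurons
        for n in range(config.n_neurons):
            rate = bg * (1.0 - rho) if n in pairing else bg.copy()
            for c in active:
                d = deltas.get((n, int(c)))
                if d is not None:
                    rate = rate + d
            if rate.min() < -1e-9:
                raise ValueError(
                    f"negative instantaneous rate for neuron {n}, trial {t}: "
                    "bump gains exceed the background rate"
                )
            trial_spikes[n] = _draw_window(np.clip(rate, 0.0, None))
        # the drive shared by a CA3 driver and its CA1 targets is a
        # latent train; each region observes it with independent
        # few-ms timing jitter, so neither copy is systematically
        # cleaner than the other
        def _jit(times: np.ndarray) -> np.ndarray:
            if times.size == 0 or config.copy_jitter_ms <= 0:
                return times
            return np.sort(
                _reflect(
                    times
                    + rng.uniform(
                        -config.copy_jitter_ms, config.copy_jitter_ms, times.size
                    )
                )
            )

        latents = {
            src: trial_spikes[src]
            for drivers in pairing.values()
            for src in drivers
        }
        for target, drivers in pairing.items():
            inherited = [trial_spikes[target]]
            thin = rho / len(drivers)
            for src in drivers:
                latent = latents[src]
                inherited.append(_jit(latent[rng.random(latent.size) < thin]))
            trial_spikes[target] = np.sort(np.concatenate(inherited))
        for src, latent in latents.items():
            trial_spikes[src] = _jit(latent)
        spikes.append(trial_spikes)
        presample.append([_draw_window(bg) for _ in range(config.n_neurons)])

    return SpikeEnsemble(
        window_ms=config.window_ms,
        category_names=tuple(config.category_names),
        regions=tuple(config.regions),
        labels=labels,
        spikes=spikes,
        presample_spikes=presample,
        event_type="SampleResponse",
        ground_truth=effective_signal_windows(config),
        provenance={"rng_seed": config.rng_seed, "case": "sample"},
    )


# ---------------------------------------------------------------------------
# control / surrogate transforms
# ---------------------------------------------------------------------------


def time_shift_control(ensemble: SpikeEnsemble) -> SpikeEnsemble:
    """Replace decoding windows with pre-stimulus (background-only) windows.

    Labels are kept, so the inputs carry no category information: decoding
    the result should land at chance.
    """
    if ensemble.presample_spikes is None:
        raise ValueError("ensemble carries no pre-sample windows")
    out = ensemble.copy()
    out.spikes = out.presample_spikes
    out.presample_spikes = None
    out.event_type = "PreSample"
    out.ground_truth = {}
    out.provenance = {**ensemble.provenance, "case": "time_shifted"}
    return out


def label_shuffle_control(ensemble: SpikeEnsemble, seed: int) -> SpikeEnsemble:
    """Permute label vectors across trials; spikes untouched."""
    if ensemble.n_trials < 2:
        raise ValueError("need at least two trials to shuffle labels")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ensemble.n_trials)
    out = ensemble.copy()
    out.labels = ensemble.labels[perm].copy()
    out.provenance = {
        **ensemble.provenance,
        "case": "label_shuffled",
        "shuffle_seed": seed,
    }
    return out


def circular_shift_surrogate(ensemble: SpikeEnsemble, seed: int) -> SpikeEnsemble:
    """Circularly shift each neuron's spike train by an independent offset.

    Offsets are drawn per (trial, neuron) and applied modulo the window
    length, preserving each train's spike count and circular inter-spike
    interval multiset while destroying timing relative to the task event
    and across neurons.
    """
    rng = np.random.default_rng(seed)
    out = ensemble.copy()
    M = ensemble.window_ms
    for t in range(ensemble.n_trials):
        for n in range(ensemble.n_neurons):
            times = ensemble.spikes[t][n]
            if times.size == 0:
                out.spikes[t][n] = times.copy()
                continue
            off = rng.uniform(0.0, M)
            out.spikes[t][n] = np.sort(np.mod(times + off, M))
    out.ground_truth = {}
    out.provenance = {
        **ensemble.provenance,
        "case": "circular_shift",
        "surrogate_seed": seed,
    }
    return out


def jitter_surrogate(
    ensemble: SpikeEnsemble, max_jitter_ms: float = 20.0, seed: int = 0
) -> SpikeEnsemble:
    """Jitter every spike by U(-max_jitter_ms, +max_jitter_ms).

    Spikes pushed past a window edge are reflected back inside, so
    per-trial and per-neuron spike counts are preserved exactly while
    fine temporal precision is destroyed.
    """
    if max_jitter_ms <= 0:
        raise ValueError("max_jitter_ms must be positive")
    rng = np.random.default_rng(seed)
    out = ensemble.copy()
    M = ensemble.window_ms
    for t in range(ensemble.n_trials):
        for n in range(ensemble.n_neurons):
            times = ensemble.spikes[t][n]
            if times.size == 0:
                out.spikes[t][n] = times.copy()
                continue
            jittered = times + rng.uniform(-max_jitter_ms, max_jitter_ms, times.size)
            folded = np.mod(jittered, 2.0 * M)
            folded = np.where(folded > M, 2.0 * M - folded, folded)
            folded = np.minimum(folded, np.nextafter(M, 0.0))
            out.spikes[t][n] = np.sort(folded)
    out.provenance = {
        **ensemble.provenance,
        "case": "jitter",
        "surrogate_seed": seed,
        "max_jitter_ms": max_jitter_ms,
    }
    return out


# ---------------------------------------------------------------------------
# study-condition presets
# ---------------------------------------------------------------------------


def _place_motifs(
    rng: np.random.Generator,
    window_ms: float,
    span_ms: float,
    n_motifs: int,
) -> list[float]:
    """Non-overlapping motif onsets on a lattice of span-sized slots."""
    n_slots = int(window_ms // span_ms)
    if n_motifs > n_slots:
        raise ValueError("too many motifs for the window")
    slots = rng.choice(n_slots, size=n_motifs, replace=False)
    return [float(s * span_ms) for s in np.sort(slots)]


def temporal_code_config(
    n_neurons: int = 30,
    n_trials: int = 150,
    n_categories: int = 5,
    seed: int = 0,
    neurons_per_category: int = 8,
    motifs_per_neuron: int = 4,
    bump_ms: float = 20.0,
    gap_ms: float = 100.0,
    bump_gain_hz: float = 25.0,
    background_rate_hz: float = 5.0,
    regions: tuple[str, ...] | None = None,
    signal_pool: list[int] | None = None,
) -> SimulationConfig:
    """Purely temporal category code: rate dipoles, zero net rate change.

    Each signal neuron carries, per coded category, ``motifs_per_neuron``
    motifs at category-specific times. A motif is a brief high-gain bump
    (``bump_ms`` at ``+bump_gain_hz``) followed by a silent gap whose
    deficit exactly cancels the bump's extra spikes, so the expected
    spike count of every neuron is identical across categories: the code
    lives entirely in spike timing at the ``bump_ms`` scale.
    """
    rng = np.random.default_rng(seed)
    span = bump_ms + gap_ms
    gap_gain = -bump_gain_hz * bump_ms / gap_ms
    if background_rate_hz + gap_gain < -1e-9:
        raise ValueError("gap deficit exceeds the background rate")
    pool = list(range(n_neurons)) if signal_pool is None else list(signal_pool)
    windows: dict = {}
    for c in range(n_categories):
        chosen = rng.choice(pool, size=min(neurons_per_category, len(pool)), replace=False)
        for n in np.sort(chosen):
            onsets = _place_motifs(rng, 2000.0, span, motifs_per_neuron)
            bumps = []
            for o in onsets:
                bumps.append(Bump(o, bump_ms, bump_gain_hz))
                bumps.append(Bump(o + bump_ms, gap_ms, gap_gain))
            windows[(int(n), c)] = tuple(bumps)
    return SimulationConfig(
        n_neurons=n_neurons,
        n_trials=n_trials,
        n_categories=n_categories,
        background_rate_hz=background_rate_hz,
        regions=regions,
        signal_windows=windows,
        rng_seed=seed,
    )


def rate_code_config(
    n_neurons: int = 30,
    n_trials: int = 150,
    n_categories: int = 5,
    seed: int = 0,
    neurons_per_category: int = 8,
    rate_gain_hz: float = 3.0,
    background_rate_hz: float = 5.0,
) -> SimulationConfig:
    """Pure rate code: category scales a neuron's rate uniformly over the
    whole window, so total spike counts — and nothing finer — carry the
    category information."""
    rng = np.random.default_rng(seed)
    windows: dict = {}
    for c in range(n_categories):
        chosen = rng.choice(n_neurons, size=neurons_per_category, replace=False)
        for n in np.sort(chosen):
            windows[(int(n), c)] = (Bump(0.0, 2000.0, rate_gain_hz),)
    return SimulationConfig(
        n_neurons=n_neurons,
        n_trials=n_trials,
        n_categories=n_categories,
        background_rate_hz=background_rate_hz,
        signal_windows=windows,
        rng_seed=seed,
    )


def region_coding_config(
    n_neurons: int = 30,
    n_trials: int = 150,
    n_categories: int = 5,
    seed: int = 0,
    ca1_mode: str = "copied",
    drivers_per_category: int = 6,
    **motif_kwargs,
) -> SimulationConfig:
    """Temporal code carried by CA3 drivers, with CA1 either duplicating it
    (``ca1_mode='copied'``, redundancy_rho = 1) or carrying its own
    independent category code (``ca1_mode='independent'``)."""
    regions = default_regions(n_neurons)
    ca3 = [i for i, r in enumerate(regions) if r == "CA3"]
    ca1 = [i for i, r in enumerate(regions) if r == "CA1"]
    # restrict drivers to a pool the CA1 targets can cover 1:1, so that
    # 'copied' mode duplicates *all* of the CA3 category signal
    driver_pool = ca3[: min(len(ca3), len(ca1))]
    base = temporal_code_config(
        n_neurons=n_neurons,
        n_trials=n_trials,
        n_categories=n_categories,
        seed=seed,
        neurons_per_category=drivers_per_category,
        regions=regions,
        signal_pool=driver_pool,
        **motif_kwargs,
    )
    if ca1_mode == "copied":
        return replace(base, redundancy_rho=1.0)
    if ca1_mode == "independent":
        extra = temporal_code_config(
            n_neurons=n_neurons,
            n_trials=n_trials,
            n_categories=n_categories,
            seed=seed + 1,
            neurons_per_category=min(drivers_per_category, len(ca1)),
            regions=regions,
            signal_pool=ca1,
            **motif_kwargs,
        )
        merged = dict(base.signal_windows)
        merged.update(extra.signal_windows)
        return replace(base, signal_windows=merged, redundancy_rho=0.0)
    raise ValueError("ca1_mode must be 'copied' or 'independent'")
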