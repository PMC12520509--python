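# Methods

This note records the modeling choices behind `spikestack`: the
generative model of the synthetic data, the decoder and its defaults,
the interpretation machinery, and the places where the design was
genuinely open and a choice had to be made.

## Synthetic spike ensembles

**Generative model.** Each neuron fires as an inhomogeneous Poisson
process on a 1-ms grid over a 2000-ms decoding window. The rate is a
constant background (default 5 Hz, giving ~10 spikes per neuron-trial)
plus rectangular category-specific "bumps" assigned per (neuron,
category): on trials whose label includes category *c*, the bumps for
(*n*, *c*) add to neuron *n*'s rate. Spike times are drawn per-bin
(Poisson counts, uniform placement within the bin). A configuration
whose summed rate would be negative anywhere is rejected. Generation is
bit-reproducible from the configuration seed. Labels default to
one-of-five with exact balance (a flag allows independent per-category
Bernoulli labels). Every ensemble also carries matching
background-only *pre-sample* windows, used by the time-shifted control.

**Temporal-code preset** (`temporal_code_config`). Per coded category a
signal neuron receives a few *count-neutral dipole motifs*: a brief
high-gain bump (default 20 ms at +25 Hz) followed by a silent gap
(100 ms at −background) whose deficit exactly cancels the bump's extra
spikes. Expected spike counts are therefore identical across categories
at every timescale coarser than the motif — the code is purely
temporal, which is what makes the full-window rate baseline a true
chance-level control. Default strength (8 signal neurons per category,
4 motifs each) was chosen so that a 30-neuron/150-trial dataset decodes
in the MCC ≈ 0.4–0.7 range, comparable to real recordings of this kind.
For surrogate-degradation experiments a 10-ms/+50-Hz variant puts the
injected precision *below* the ±20-ms jitter scale, so jittering can
actually destroy it; 20-ms motifs are only attenuated.

**Rate-code preset** (`rate_code_config`) scales a signal neuron's rate
uniformly over the whole window (default +3 Hz on 5 Hz), so spike
counts — and nothing finer — carry the category.

**CA3→CA1 redundancy** (`redundancy_rho`). Regions follow the
10-microelectrode probe layout (6 CA3 : 4 CA1, repeating). A paired CA1
neuron inherits a ρ-thinned copy of its CA3 driver's *realized* spike
train; both the driver's retained train and the inherited copy receive
independent few-ms timing jitter (default ±3 ms), modeling a shared
latent drive observed twice, and the CA1 neuron's own background is
scaled by (1 − ρ) to keep mean rates comparable. The copy is
trial-correlated by construction. We first implemented the simpler
alternative — copying the *rate profile* and realizing it
independently — and rejected it: independent realizations make the two
regions' features merely rate-correlated, their fitted contributions
combine additively, and no loss-based decomposition can register the
duplication as redundancy. Trial-level correlation is also the
physiological picture (strong, diffuse feedforward CA3→CA1
projections). `region_coding_config` builds the two contrasting study
conditions: `copied` (ρ = 1, drivers restricted to a pool the CA1
targets cover one-to-one, so all CA3 signal is duplicated) and
`independent` (each region carries its own temporal code, ρ = 0).

**Transforms.** *Time-shifted*: swap in the pre-sample windows, keep
labels (no signal by construction). *Label-shuffled*: permute label
vectors across trials. *Circular shift*: rotate each (trial, neuron)
train by an independent uniform offset modulo the window — preserves
counts and circular inter-spike intervals, destroys event-locked and
cross-neuron timing. *Jitter*: displace every spike by U(−20, +20) ms,
reflecting at the window edges so counts are preserved exactly.

**What the generator does not emulate:** non-Poisson spiking
(refractoriness, bursting), slow nonstationarities, behavioral
covariates, correlated noise beyond the explicit feedforward drive, and
electrode artifacts. Tests passing on these data show the pipeline
recovers what it claims to recover under its stated model; they do not
certify performance on clinical recordings.

## Features

Spike trains are binned on a fine grid (`grid_ms`, default 2 ms; the
desk-scale configurations below use 4–5 ms) and projected onto uniform
B-spline bases evaluated at bin centers via
`scipy.interpolate.BSpline.design_matrix`. For `segments = m + 1`
inter-knot intervals the temporal resolution is `window / segments`.
Order 0 gives disjoint indicator bins (J = segments; features are exact
binned counts — the rate-coding representation); order 3 gives clamped
cubic splines (J = segments + 3). Both form a partition of unity, and
feature extraction is linear in the spike pattern: entry (n, j) is
Σ_τ counts[n, τ]·b_j(τ), laid out neuron-major. Features are not
standardized; the L1 penalty handles scale. The default resolution
ladder is segments ∈ {1, 2, 4, 8, 10, 20, 40, 50, 80, 100}, i.e.
2000 → 20 ms, bracketing the rate-baseline bins {2000, 100, 50, 20} ms.

## Decoder

One independent binary model per category (one-vs-rest). Within each
outer training set:

1. **Penalty selection.** For every resolution, a stratified inner CV
   (default 4-fold) scores an L1 grid (default 7 points, C from 0.01
   to 10) by out-of-fold cross-entropy and applies the
   **one-standard-error rule**: the strongest penalty within one SE of
   the minimum wins. Besides being the conventional choice for sparse
   models, this lets fits on label-independent data collapse to the
   intercept-only model, whose constant prediction yields MCC exactly 0
   under the degenerate convention — the behavior expected of the
   control cases. (Plain argmin selection leaves weak nonzero
   coefficients whose cross-validated predictions are slightly
   *anti*-correlated with held-out labels, biasing null-case MCC to
   about −0.05.)
2. **Stacking.** The inner-CV out-of-fold probabilities at the selected
   penalties (one column per resolution, so the stacked dimension is
   the number of resolutions Q) train the L1-logistic meta-learner,
   with its own small penalty grid selected the same way. Stacked
   inputs are never in-fold predictions.
3. **Bagging.** R replicas (default 20) of every base learner are fit
   at the selected penalties on bootstrap resamples of the training
   trials (resampled to original size; the same resample is shared
   across resolutions within a replica). Prediction averages the R
   per-resolution probabilities before the meta-learner.

Outer CV is stratified 5-fold; every reported MCC is computed on
out-of-fold predictions only. Fits use scikit-learn's liblinear solver
(`intercept_scaling = 100` so the intercept is effectively
unpenalized; deterministic given data and settings; non-convergence
raises rather than passing silently). A run is reproducible
bit-for-bit from the decoder seed, which drives fold plans and
bootstraps through spawned integer seeds. Hard labels threshold the
probability at 0.5 with ties going to the negative class. Rate-coding
baselines reuse this exact path with a single order-0 resolution and no
stacking layer, so model comparisons isolate the input representation.

## SCFM and sparseness

The classification surface for one category is evaluated per bagging
replica as

F′(n, τ) = logistic( w′₀ + Σ_m w′_m ( w^m₀ + Σ_j b_j^m(τ) w^m_{n,j} ) )

with that replica's base coefficients w^m and the shared meta weights
w′, then averaged over replicas (averaging probabilities keeps values
in (0, 1)). Base intercepts are folded through the stacking path, so
the baseline — the same expression with every basis term zeroed,
logistic(w′₀ + Σ_m w′_m w^m₀) — satisfies an exact identity: the
surface equals the baseline wherever no nonzero coefficient (with
nonzero meta weight) touches the cell. The signed map
(surface − baseline) is therefore exactly zero off the coefficient
support, with no numeric tolerance; positive cells are where a spike
raises the category probability. Coefficients are indexed per base
learner: that is the only dimensionally consistent reading of the
stacked expansion.

*Spatial sparseness* is the fraction of neurons whose support row is
empty; *temporal sparseness* is, per contributing neuron, the fraction
of the window off-support (an all-zero surface reports 1.0 for both by
convention). Zeros are judged on coefficient support because L1 fits
produce exact zeros. *Masking* a pattern is the inner product
Σ counts·signed_map — a scalar that separates decoded-category trials
from others even when raw counts do not. *Recovery* scores the mean
per-neuron Jaccard overlap between positive signed-map cells and the
generator's positive ground-truth bumps, compared against a null built
by permuting the surface's neuron rows.

## Permutation importance and the region decomposition

The importance of a feature group (a resolution, a neuron, or a
region) is the mean increase in out-of-fold cross-entropy when the
group's features are permuted jointly across each outer fold's held-out
trials and predictions are re-propagated through the fitted fold
models (default 50 draws; negative deltas are floored at zero for
normalized shares, raw values retained). Because feature extraction is
linear per neuron, permuting a neuron's feature block is identical to
permuting its spike-pattern rows and re-extracting. For resolution
groups the permutation acts on that resolution's stacked input, which
is equivalent and cheaper. Per-resolution shares are normalized to sum
to one within a category and then averaged across categories.

For the CA3/CA1 analysis the three damages D_CA3, D_CA1, D_both are
converted to **sole-region contributions** by inclusion-exclusion:
C_CA3 = D_both − D_CA1 (the loss reduction attributable to CA3's intact
features relative to fully permuted inputs), symmetrically C_CA1, and
C_both = D_both; then redundancy = C_CA3 + C_CA1 − C_both and
unique_X = C_X − redundancy, so unique_CA3 + unique_CA1 + redundancy =
C_both exactly. The raw damages themselves cannot serve as the
contributions here: a controlled toy (two duplicated features, even
weights, logistic loss) shows that remove-one damages make the
"redundancy" of perfectly duplicated inputs strictly negative, because
cross-entropy is convex in the corrupted logit. Under the
inclusion-exclusion form, duplicated regions — either of which alone
supports decoding — show large redundancy and small unique terms, and
independent codes show near-zero redundancy, which is the behavior the
decomposition exists to detect. Note the estimate quantifies the
*fitted model's* reliance: a sparse fit may lean on one of two
duplicated copies, which caps measurable redundancy below its
information-theoretic value. Per-neuron contributions divide each
region's C by its neuron count; region means are compared with a
paired two-sided t-test (reported, never gating).

## Metrics

MCC follows the confusion-matrix formula with the convention that any
zero factor in the denominator (single-class predictions or labels)
yields 0. Informedness (TPR + TNR − 1) and Markedness
(PPV + NPV − 1) treat degenerate ratios as contributing 0; on
non-degenerate matrices MCC² = Informedness × Markedness, which the
tests verify numerically along with agreement with an independent MCC
implementation. The chance-level null simulates label-independent
coin-flip predictors against balanced labels.

## Problem sizes and numerical choices

The test suite and acceptance script run the study-scale condition
(30 neurons / 150 trials) with a 7-resolution ladder
{2000, 1000, 500, 200, 100, 50, 20} ms, 5 bagging replicas, a 5-point
penalty grid, 5×3 nested folds and a 4-ms grid; unit tests use smaller
ensembles (10–20 neurons, 50–100 trials) and 2–4 resolutions. These are
desk-scale working sizes — the defaults (10 resolutions, R = 20, 2-ms
grid, 7-point grid, 5×4 folds) run the same code paths. Solver
tolerance is 1e−5 with a 5000-iteration cap; SCFM oracle agreement is
asserted to 1e−10; bootstrap resamples are redrawn (up to 100×) if they
lose a class; stratified folds require at least one positive per outer
fold and fail loudly otherwise.

## Known limitations

- Poisson spiking without refractoriness or bursting; surrogate
  contrasts may be sharper on real, history-dependent trains.
- The redundancy estimate is model-mediated (see above) and inherits
  permutation sampling noise; shares are reported with raw deltas so
  the flooring is auditable.
- One-vs-rest ignores the (mild) negative coupling among exclusive
  labels.
- The ±20-ms jitter surrogate only degrades codes near or below that
  scale; on the 20-ms-motif preset it attenuates rather than abolishes
  decoding, which is the expected physics, not a pipeline failure.
- Serialization covers ensembles and result tables; fitted models are
  deterministic re-fits from (data, config, seed) rather than pickled
  artifacts.
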