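# Methods

This note documents the models, estimators and numerical choices behind
`statecode`, what the synthetic generator does and does not emulate,
and the decisions taken where the design was genuinely open.

## Oscillation-state model

Band envelopes of the LFP (theta 3–8, beta 10–30, low gamma 30–50,
high gamma 50–80 Hz; order-11 Butterworth band-passes applied
forward–backward, analytic-signal magnitude, 30 ms bin means) are
modeled with a hidden Markov model with diagonal-Gaussian emissions,
fit by Baum–Welch.  Filtering is zero phase so envelope features do not
lag state boundaries; the effective magnitude response is the square of
the design order.  The Hilbert transform gets 1 s of reflection padding,
trimmed afterwards.  Bins are half-open, `[k·30 ms, (k+1)·30 ms)`,
anchored at session start.

**Fitting.** `GaussianStateHMM` runs 5 EM restarts (k-means-based
initialization, tolerance 1e-4, at most 500 iterations) and keeps the
best training log-likelihood.  Hard labels are the argmax of the
forward–backward posterior, not the Viterbi path: the downstream
statistics (dwell times, transition intervals defined by posterior
confidence) are posterior-native.

**State-count selection.** For each M in [2, 6] we compute (i) the mean
held-out log-likelihood per sample under contiguous-block k-fold
cross-validation (blocks, not shuffled bins, because the observations
are strongly autocorrelated; k = 3 by default) and (ii) λ₁, the top
eigenvalue of the covariance of the M × n_bands state-definition matrix
(row = a state's mean power per band).  λ₁ is the maximum variance
across state definitions; small λ₁ means near-collinear, redundant
states.  Both metrics are min–max normalized to [−1, 1] over the grid.

Two score modes exist.  The *ratio* mode divides normalized LL by
normalized λ₁ over the sub-grid with strictly positive denominators
(falling back to the product with a warning when none is positive).
The *product* mode multiplies them, rewarding models that are
simultaneously likely and have dissimilar states.  On 3-state
validation simulations (60,000 samples × 10 dims, randomized emission
scales) the ratio mode degenerates: cross-validated LL plateaus from
M = 3 upward while λ₁ is maximal at M = 2, so after normalization only
M = 2 retains a positive denominator and the ratio always selects it.
The product mode selects M = 3 in the clear majority of runs (λ₁ peaks
at the true M within the LL plateau).  The product is therefore the
default; ties break toward the smaller M.  This selection behaviour is
itself a tested property (the recovery benchmark in the acceptance
suite), not an assumption.

**Semantic labels.** With M = 3, the state whose definition row has the
largest mean gamma (low + high) power is S_H, the largest theta power
S_L, the remainder S_I; a state winning both contests is an explicit
labeling error rather than an arbitrary choice.

**Dynamics.** Dwell times are hard-label run lengths × 30 ms.  A
transition interval is the maximal span around a label change in which
the maximum posterior stays below 0.8 (configurable).  k-step sequence
probabilities (k = 2, 3) are empirical frequencies of consecutive state
tuples after collapsing runs.

## Variability metrics

**Shared variance.** Factor analysis (EM with SVD-based initialization,
as implemented in scikit-learn) splits the spike-count covariance into
a shared part `L Lᵀ` and independent variances `Ψ`; the per-unit
percentage is `100 · L_k L_kᵀ / (L_k L_kᵀ + Ψ_k)`.  The factor count m
maximizes 3-fold cross-validated likelihood.  Constant units are
dropped with a warning (they carry no covariance signal and make the
fit singular).

**State matching.** Because FA is sensitive to sample size, per-state
estimates subsample every state to the scarcest state's occupancy
(without replacement inside each of 20 bootstrap repeats, refitting m
per repeat) and average.

**ISI-CV.** ISIs are taken from spikes in a state's bins and capped at
2.5 s so that dwell-time differences cannot stretch the ISI range.
Per-state rates are equalized to the unit's lowest across-state rate by
i.i.d. Bernoulli spike deletion (thinning preserves Poisson statistics,
so the manipulation is unbiased for CV = 1 processes), averaged over 20
repeats.

**Fano factor.** Counts in non-overlapping 150 ms windows tiled from
trial start; a window contributes to state s only if ≥ 10 trials spent
the *entire* window in s (the strictest reading of the single-state
rule; every 30 ms bin of the window must carry the label).  Sample
sizes are matched by subsampling qualifying windows to the scarcest
state and rates equalized by binomial thinning of counts, 20 repeats.
The optional gaze control clusters 2-D gaze coordinates (Ward linkage,
5 clusters) and applies the trial rule within each cluster.

## Matrix-based mutual information

Entropy is estimated without density estimation from the eigenspectrum
of the normalized Gram matrix A of a Schoenberg kernel,
`S_α(A) = log₂(Σ λ_j(A)^α)/(1−α)` in bits, α = 1.01 (near-Shannon while
numerically stable for sparse counts).  Joint entropy is the entropy of
`A∘B / trace(A∘B)`.  MI is normalized by `√(S(A)·S(B))`, bounding it by
1 up to floating-point slack; eigenvalues are clipped at 0 and
renormalized before powering (Gram matrices are PSD in exact
arithmetic; clipping absorbs round-off).

**Kernel width.** Scott's rule gives a per-dimension bandwidth
`w = mean(SD_m) · N^(−1/(d+4))`.  The kernel exponent sums squared
differences over all d dimensions, so the exponent scale is
`σ_κ = 2·d·w²`: without the factor d the Gram matrix collapses toward
the identity for high-dimensional inputs (flattened movie frames have
d ≈ 600) and the normalized MI saturates at a dependence-independent
ceiling — the shuffle-null control fails.  With the factor, the 1-D
case reduces to the classical `2w²` and the frame-MI shuffle control
behaves correctly.  Degenerate zero-variance inputs fall back to
σ_κ = 1 (the Gram matrix of identical points is width-independent).

**State–behavior MI** one-hot encodes the discrete labels before kernel
evaluation.  **Trialwise stimulus MI** pairs population count vectors
with 5×-downsampled flattened frames within each (trial, state),
requiring at least 3 s of dwell in the trial.

## Stimulus features

Per frame: mean, SD, Pearson (non-excess) kurtosis `m₄/σ⁴` (undefined
for constant frames), pixel-value entropy over the 0–255 histogram,
temporal energy `Σ|I_t − I_{t−1}|` (missing for the first frame,
imputed as 0 at design-matrix assembly), and the Canny edge fraction.
The Canny detector is implemented directly: 5×5 Gaussian smoothing
(σ = 1 px), Sobel gradients, direction quantized to {0°, 45°, 90°,
135°}, non-maximum suppression (ties broken toward a single surviving
pixel: strictly greater than one directional neighbour, at least equal
to the other, so an ideal step edge yields a one-pixel line), and
double-threshold hysteresis with 8-connectivity to sure edges.
Thresholds default to Otsu's method on the gradient magnitude for the
high threshold and half of it for the low.

## Encoding models

Feature blocks carry a category: stimulus, behavior, internal-lfp,
internal-population.  Columns are centered; behavioral features are
QR-orthogonalized among themselves; under the full scheme internal
features are additionally orthogonalized against all preceding columns
(stimulus stays raw).  QR runs *before* lag expansion so each feature's
temporal structure survives; each feature then becomes `τ·30` Toeplitz
lag columns and the incomplete leading rows are dropped.  The
orthogonality guarantees hold exactly on the pre-lag feature matrix
(exposed as `features_pre_lag`); lagged copies of orthogonal features
are only approximately orthogonal at nonzero relative lag, which is
inherent to lagging after decorrelation.  Single-category contribution
models use the unique-category scheme (within-group orthogonalization
only) to avoid partial decorrelation against unmodeled signals.

One regressor per state, trained only on that state's rows (hard
labels).  Population targets use ridge; single neurons use an
L2-penalized Poisson GLM (log link, unpenalized intercept) — both via
scikit-learn solvers behind the `StateConditionedRegression` surface.
Standardization statistics come from the training rows of each state
only and are applied to test rows.  λ is selected per state from 13
log-spaced values in [1e-2, 1e4]: identity link by 3-fold CV of R² on a
random 30% subset of the state's rows (drawn within each state);
log link by nested 5-fold CV.  Cross-validation folds are
state-balanced: each state's bins are split into k contiguous chunks
and chunk j joins fold j, so every fold matches the global state
composition to within rounding.  Explained variance follows
`R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²` per fold with state predictions
concatenated; per-state R² pools out-of-fold predictions restricted to
that state's rows.  Single-neuron targets may be smoothed with a 50 ms
Gaussian before scoring.

Unit quality filters use strict inequalities (presence ratio > 0.9, or
> 0.95 for encoding; ISI violations < 0.5; amplitude cutoff < 0.1;
rate > 1 spk/s in every state; receptive-field center ≥ 20° inside the
screen extent).

## Encoding-profile clustering

Each unit's profile is [cvR² stimulus, behavior, same-area LFP,
other-area population, #categories > 10%].  200 repeats (default) of
UMAP (min_dist ∈ [0.02, 0.5], n_neighbors ∈ [5, 10], n_components ∈
[2, 5], randomized per repeat) followed by mean-shift produce a
co-association matrix; average-linkage hierarchical clustering on
1 − co-association is cut at the elbow of the silhouette curve
(argmax fallback when the curve has no elbow, logged).  The mean-shift
bandwidth comes from scikit-learn's quantile estimate with the quantile
drawn from [0.25, 0.5] per repeat: quantiles below ≈ 0.2 make the
bandwidth a within-blob scale and systematically shatter tight,
well-separated groups, destroying the co-association contrast the
method relies on; the chosen range recovers planted partitions cleanly.
Clusters whose mean profile shares a dominant category and whose
second-largest category stays below the 10% threshold are merged
(the reproducible codification of a judgment-based merging step); a
manual merge map can be supplied instead.

## Synthetic sessions

The generator reproduces the statistical structure the analysis
assumes: a 3-state Markov chain (self-transition 0.97 → ≈ 1 s dwells)
whose states scale band-limited noise (filtered with the same
Butterworth bank as the analysis, so in-band energy is guaranteed) —
gamma-dominant, flat, theta-dominant rows with a default 3× contrast;
behavior traces as state-dependent mean shifts (coupling ∈ [0, 1])
plus unit Gaussian noise; spikes from gamma-renewal processes
(shape 1 = Poisson) with state-dependent rates, rates drawn
log-uniformly in [2, 12] spk/s, and a shared log-rate Gaussian factor
(mean-preserving, default strength 0.2) to plant co-fluctuations;
movie frames as spatio-temporally filtered noise quantized to [0, 255]
at 96 × 152 px; encoding targets generated from per-state weight
vectors through the identity or log link.  LFP is synthesized at
1250 Hz — half the acquisition rate of typical datasets but comfortably
above twice the highest analysis band.

Not emulated: biophysical LFP generation, eye-position-dependent
retinal transforms of the stimulus, spike-sorting artifacts, slow
drift.  Passing tests therefore certify the estimators and their
matching procedures, not robustness to those real-data complications.
The spiking model (renewal + shared factor) is a stand-in chosen to
give the variability metrics known ground truth; real data makes no
such renewal assumption.

## Problem sizes and runtime choices

Desk-scale defaults keep every stage runnable on one CPU: the pipeline
default is a 5-minute session with 40 units; tests use 1–4 minute
sessions; the state-count recovery benchmark uses 10 simulation seeds
at the full N = 60,000 × 10 size with 3-fold selection, single-restart
fits capped at 50 EM iterations (selection needs LL *differences*
between M values, which stabilize long before full convergence).  The
state–behavior MI estimator is O(N³) in the sample count and is
evaluated on an even stride of at most ~1000 bins inside the pipeline.

## Known limitations

- The ratio score mode is retained for comparability but is degenerate
  under min–max normalization (see above); the product mode is the
  operational criterion.
- Transition-adjacent bins are systematically harder to decode because
  narrow-band envelopes smear state switches by roughly the filter
  ring-down time (~0.3 s for theta); per-bin decode agreement saturates
  near 95%, not 100%, on synthetic sessions.
- Consensus clustering is deterministic only under a fixed master seed;
  co-association values for borderline units vary between seeds.
- `compare_state_sequences` reports Pearson correlation after Hungarian
  label alignment; for M > 2 the numeric coding of labels still imposes
  an arbitrary metric on state identity, as in the source analyses.
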