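# statecode

State-conditioned analysis of cortical population recordings.

Cortical activity is not stationary: the local field potential (LFP)
moves between oscillation regimes — a gamma-dominant high-frequency
state, a theta-dominant low-frequency state, and an intermediate state —
and single-neuron variability, stimulus information and the apparent
"sources" of spiking variance all change with the regime.  `statecode`
implements the full analysis chain for quantifying this on Neuropixels-
style sessions (multichannel LFP, spike-sorted units, behavior traces,
a repeated natural-movie stimulus), together with a synthetic session
generator that provides ground truth for every stage.

The pipeline:

1. **LFP preprocessing** (`statecode.lfp`) — zero-phase Butterworth
   band-pass filters for theta (3–8 Hz), beta (10–30 Hz), low gamma
   (30–50 Hz) and high gamma (50–80 Hz); Hilbert envelopes averaged in
   30 ms bins; z-scored spectrograms; current-source-density maps
   (`D = (s̄(r+h) − 2s̄(r) + s̄(r−h)) / h²`) and sink-based cortical
   layer assignment.
2. **Oscillation states** (`statecode.states`) — a diagonal-Gaussian
   hidden Markov model over band envelopes (`GaussianStateHMM`, a
   scikit-learn-style estimator).  The state count M is chosen by a
   penalized criterion combining k-fold cross-validated log-likelihood
   with λ₁, the top eigenvalue of the state-definition matrix (mean
   band power per state), both min–max normalized to [−1, 1] over
   M ∈ [2, 6].  States are labeled S_H / S_I / S_L from their band
   profiles; dwell times, transition intervals and k-step sequence
   statistics follow.
3. **Variability** (`statecode.variability`) — factor-analysis shared
   variance (`% shared = 100·L_k L_kᵀ / (L_k L_kᵀ + Ψ_k)`), ISI
   coefficient of variation (ISIs capped at 2.5 s), and the Fano factor
   in 150 ms windows with a ≥ 10-trial rule — each with occupancy
   matching and firing-rate equalization across states (n = 20
   bootstrap repeats), plus a gaze-cluster control.
4. **Mutual information** (`statecode.information`) — matrix-based
   Rényi α-order entropy (α = 1.01) from the eigenspectrum of a
   normalized Schoenberg-kernel Gram matrix,
   `S_α(A) = log₂(Σ_j λ_j(A)^α) / (1 − α)`; joint entropy from the
   Hadamard product; MI normalized by the geometric mean of the
   marginal entropies, so it lives in [0, 1].  Includes per-trial,
   state-conditioned MI between population activity and movie frames.
5. **Stimulus features** (`statecode.stimfeat`) — per-frame intensity,
   contrast, Pearson kurtosis, pixel entropy, temporal energy and the
   Canny edge fraction.
6. **Encoding models** (`statecode.encoding`) — QR-orthogonalized,
   Toeplitz-lagged design matrices over stimulus / behavior / internal
   brain-activity categories; state-balanced cross-validation folds;
   per-state ridge regression (population targets) and L2-penalized
   Poisson GLMs (single neurons) via `StateConditionedRegression`;
   cross-validated explained variance and per-category / incremental
   variance partitioning.
7. **Encoding-profile clustering** (`statecode.clusters`) — consensus
   clustering (randomized UMAP + mean-shift repeats → co-association
   matrix → hierarchical cut at the silhouette elbow → dominant-category
   merging) of five-element encoding profiles.
8. **Orchestration** (`statecode.workflow`) — `run_pipeline(config, out)`
   executes the stages in dependency order and writes every stage table
   with config-hash/seed provenance.

## Worked example

```python
import numpy as np
from statecode import lfp, states, synthetic

gt = synthetic.default_ground_truth()          # 3 states, gamma/flat/theta
labels, _ = synthetic.simulate_state_sequence(gt, n_bins=4000, seed=0)
sig, behavior = synthetic.simulate_lfp_and_behavior(
    labels, gt.band_power_profile, coupling=1.0, seed=1, n_channels=3)

env = lfp.band_envelopes(sig, fs=1250.0)       # (3 ch, 4 bands, 30 ms bins)
obs = env.to_observations()
fit = states.fit_hmm(obs, n_states=3, seed=0)
seq = states.decode_and_label(fit, obs, band_index=env.band_index())

aligned = states.align_labels(labels[: seq.labels.size], seq.labels)
print("decode agreement:", (aligned == labels[: seq.labels.size]).mean())
print("semantic labels:", seq.semantic)
dyn = states.state_dynamics(seq)
print("mean dwell (s):", {s: round(float(np.mean(d)), 2)
                          for s, d in dyn.dwell_times.items()})
```

Output:

```
decode agreement: 0.9525
semantic labels: {2: 'S_H', 1: 'S_I', 0: 'S_L'}
mean dwell (s): {0: 1.01, 1: 0.67, 2: 0.96}
```

The decoded hard labels recover the generator's state path (95%
agreement after label alignment; disagreements sit at state
boundaries, where narrow-band envelopes smear transitions); the state
with elevated gamma power is named S_H, the theta-dominant one S_L;
dwell times reflect the generator's self-transition probability
(0.97 → ≈ 1 s).

A full desk-scale run (5-minute session, 40 units) is one call:

```python
from statecode.workflow import PipelineConfig, run_pipeline
art = run_pipeline(PipelineConfig(seed=0), "out/")
```

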