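# Methods

## Model

The circuit is an N × N lattice of conductance-based leaky
integrate-and-fire neurons with periodic boundaries (minimal-image
distances everywhere). Neurons at gridpoints with both coordinates odd are
inhibitory — exactly 25% for even N — and class determines only which
conductance a neuron's spikes feed: excitatory spikes increment the
targets' g^E through the Gaussian kernel, inhibitory spikes increment g^I
through the uniform kernel. Both kernels are cut off at D = 30 gridpoints,
so every neuron receives 2820 afferent connections (the number of integer
lattice points in the punctured disc of radius 30).

Fixed physical constants: g_L = 25 nS, C = 0.5 nF (τ_m = 20 ms),
V_L = V_R = −70 mV, V_E = 0 mV, V_I = −80 mV, V_th = −55 mV,
τ_ref = 5 ms, τ_E = τ_I = 2 ms, background drive I_0 = 0.4 nA, stimulus
onset t_S = 2 s, RoI radius 15 gridpoints, lattice spacing 40 μm,
dt = 0.05 ms. The localized stimulus is a spatial Gaussian of amplitude
W_S and width σ_S = 7.5 gridpoints, gated by a Heaviside step (exactly
zero before onset); it is not truncated at the RoI boundary — the RoI is
an analysis region only.

### Calibrated coupling parameters

Three parameters are calibrated rather than measured: the kernel
amplitudes W_E = 3.0 nS, W_I = 2.0 nS (at a fixed 3:2 E:I ratio) and the
excitatory decay σ_E = 4.0 gridpoints (160 μm, consistent with
pyramidal-to-pyramidal projection ranges). The calibration target is the
regime the model is built to study: spontaneous activity that
self-organizes into coexisting propagating waves and localized patches at
a per-neuron rate near 9 Hz, with the synchronous-state signatures
(membrane potential ~11 mV below threshold with positive skew,
heavy-tailed g^E).

Two mean-field facts anchor the choice. First, with uniform inhibition the
spontaneous mean potential is pinned near the zero-crossing of the net
synaptic current,

    V̄ ≈ V_I · ΣK_I / (ΣK_E + ΣK_I),

where ΣK_E ≈ 0.75 · W_E · 2πσ_E² and ΣK_I = 0.25 · 2820 · W_I are the
summed afferent weights. σ_E = 4.0 puts this crossing near −67 mV; at
σ_E ≥ 5 it rises above −64 mV and the spontaneous membrane-potential skew
turns negative (the depolarized tail is clipped by threshold). Second, the
synaptic terms must dominate the leak for the balance to control the
dynamics at all: amplitudes must be of order 1 nS. Amplitudes much below
that leave every neuron at the isolated-LIF operating point (16.5 Hz under
I_0 = 0.4 nA, no pattern formation); amplitudes much above 5 nS drive
runaway fluctuation-triggered firing (>25 Hz). Within the workable region
the desk-scale statistics were evaluated over a small grid of (amplitude
scale, σ_E) and the default pair reproduces the reference values of rate
(≈9 Hz), pattern speed (≈44 mm/s), ⟨V⟩−V_th, and the skewness contrasts to
within ~25% or better; the package treats these two knobs as fixed
constants thereafter.

## Integration scheme

Explicit Euler with a fixed update order, which is part of the model
definition because it affects bit-level results:

1. spikes fired on the previous step deposit K on every target within the
   cutoff (translation-invariant stencil accumulation; `np.add.at` handles
   the self-overlap when the lattice is smaller than the stencil);
2. conductances decay by (1 − dt/τ);
3. non-refractory membranes take one Euler step; refractory neurons are
   clamped at V_R and ignore synaptic input while their conductances keep
   evolving;
4. neurons at or above threshold spike, reset, and start a τ_ref countdown.

A presynaptic spike therefore increments the target conductance by K
instantaneously (conductance-jump convention for the Dirac delta) and takes
effect on the next Euler step; there are no conduction delays. The
alternative normalization (jump K/τ) is a one-line change in
`build_kernels`. Initial potentials are i.i.d. uniform on [V_R, V_th);
conductances start at zero. Trials are 3.5 s with the first 1 s excluded
as burn-in. One `numpy` `default_rng(seed)` per trial; all seeds are
recorded in the outputs, and identical (configuration, seed) pairs produce
bit-identical recordings.

The offline conductance reconstruction (`patterns.reconstruct_conductance`)
replays the same scheme — same jump convention, same step alignment — from
the afferent spike record alone, and reproduces the simulator's recorded
g^E trace to floating-point round-off; this identity is the bookkeeping
test of the coupling implementation, checked against a brute-force
afferent double sum on small lattices.

## Analysis estimators

**Epochs.** Spontaneous: 1.0–2.0 s (after burn-in, before onset — the gate
is exactly zero before t_S, so pre-onset stimulated trials are spontaneous
activity). Evoked: 2.25–3.5 s, excluding 250 ms of post-onset transient.
Sliding windows advance in 50 ms steps; windows straddling onset belong to
neither epoch.

**Per-neuron statistics.** ⟨V⟩ − V_th is the time average of V_th − V over
an epoch (positive below threshold). Skewness is the bias-uncorrected
third standardized central moment (the adjusted estimator is selectable);
zero-variance samples are flagged NaN, not raised. Summaries follow the
median-across-trials-then-mean-across-neurons convention throughout.
Membrane samples include reset/refractory values; at high evoked rates the
refractory clamp at V_R biases ⟨V⟩ downwards, which is the main reason the
desk-scale evoked ⟨V⟩ − V_th runs ~25% above its reference value.

**Firing rate.** Spike counts in 250 ms sliding windows divided by the
window. For the spontaneous-rate summary the counts are pooled over the
whole lattice rather than the RoI disc: before onset the network is
statistically homogeneous, so both estimators target the same quantity,
but the 709-neuron disc average over a handful of trials carries ±2.5 Hz
of pattern-occupancy noise while the lattice-pooled estimate is stable to
~0.3 Hz.

**LFP and stLFP.** The temporal LFP component per site is
|g^E (V − V_E)| + |g^I (V − V_I)| (pA; a signed-sum variant is available),
convolved spatially with a normalized periodic Gaussian of width
σ_lfp = 2.5 gridpoints (100 μm). The stLFP triggers on spikes of RoI
neurons; electrodes are full rings of lattice sites at radii in steps of 5
gridpoints (200 μm) from the RoI centre — a ring average rather than a
single radial arm, for isotropy and variance reduction. Trigger averages
use a ±50 ms window; the baseline is the mean over −50…−25 ms, and the
amplitude is the maximum absolute deflection. The space constant comes
from a bounded nonlinear least-squares fit of M e^{−d/λ} + B
(initialization: M = amplitude range, B = minimum, λ = half-range
distance); a flat curve raises an unidentifiable-λ error.

**Pattern detection and tracking.** Per 1 ms frame the spike-count grid is
smoothed with a periodic Gaussian (σ = 2 gridpoints), thresholded at
mean + 2·std, and segmented into wrap-aware connected components;
components under 10 gridpoints are dropped. These thresholds are fixed
defaults validated on blob fixtures, all configurable. Tracks are greedy
nearest-centroid links (max jump 10 gridpoints/frame, termination after 3
missed frames, no merging); centroids are unwrapped by accumulating
minimal-image displacements. A track is a wave if its net unwrapped
displacement exceeds the RoI radius, else a patch. Speed is the mean
displacement over a 10-frame lag divided by the lag (mm/s): the lag-1
estimate is inflated by √2 × the centroid-localization jitter per frame,
which the lag suppresses while leaving true translocation unchanged;
recovery of fixture blob speeds is within 5% over 10–80 mm/s. MSD
exponents are the log–log slope over lags 1–25 frames.

**Fano factors.** Raw FF: across-trial variance/mean of per-neuron window
counts. Mean-matching follows the floor-histogram/random-discard scheme:
per-neuron mean counts are histogrammed on common bin edges at every
window, the element-wise minimum histogram across windows defines how many
neurons per bin survive, neurons are discarded at random to match it, and
the kept neurons' FFs are averaged over 50 seeded resamples. An empty
common histogram falls back to the raw FF with a warning flag. At a
handful of trials the matched onset contrast is dominated by estimator
noise (the variance estimate has ~3 degrees of freedom per neuron); the
raw-FF drop, the matched evoked level, and the window-size dependence are
the stable desk-scale readouts, and the qualitative effects do not depend
on matching.

## Synthetic fixtures

`wavepatch.fixtures` generates spike fields with known ground truth:
Gaussian-envelope blobs (σ = 3 gridpoints) thinned to Poisson spikes per
millisecond, moving ballistically or confined; homogeneous Poisson grids;
and Markov-modulated (two-state) rate-switching grids. They emulate the
geometry and event format of network recordings — enough to validate
detection, tracking, rate, skewness-sign and Fano estimators against
generator truth — but none of the network's self-organized features
(refractory wakes, E/I balance, pattern interactions), so fixture-passing
establishes estimator correctness, not network behaviour.

## Problem sizes

The reference (full) protocol is N = 300 with 500 trials of 3.5 s. The
package's desk-scale protocol, used by the test suite and the acceptance
script, is N = 120 — four times the coupling cutoff, so no
self-interaction through the periodic boundary — with 4–6 trials; the
`reproduce` workflows expose both presets. Quantities that need the full
protocol are measured at desk scale as ordering properties (e.g.
λ_evoked < λ_spont) rather than absolute values.

## Known limitations

- The desk-scale stLFP space-constant *ratio* (~1.4) is far below the
  full-scale reference (~4.7): on a 120-lattice the longest electrode ring
  is 2.2 mm and a single trial's trigger set is small, which compresses
  the fitted spontaneous λ. The ordering is robust; the ratio is not.
- The evoked state at W_S = 1.2 nA fires fast enough (~80 Hz at the patch
  centre) that raw evoked spike counts are strongly sub-Poisson
  (refractory-regularized), and the refractory clamp biases the evoked
  ⟨V⟩ − V_th upwards; both effects shrink at weaker drive.
- Uniform inhibition is the only inhibitory kernel shipped; the kernel
  constructor is the single place a distance-decaying variant would plug
  in.
- No synaptic delays, plasticity, or adaptive time-stepping; dt is fixed
  and the update order is part of the model contract.
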