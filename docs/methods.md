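# Methods

`mtuforce` implements a complete high-density surface EMG (HD-sEMG)
processing chain: blind separation of the electrode-grid recording into
muscle sources, localization of the underlying muscle–tendon units (MTUs)
on the grid, and regression of muscle force from the separated sources with
a small backpropagation network. Because no public HD-sEMG dataset with
per-compartment ground truth exists for this protocol, the package ships a
ground-truthed simulator; every downstream stage is validated against it.

## Signal model and simulator

The recording is modelled as an instantaneous linear mixture

    x(t) = A s(t) + n(t)

with `s(t)` the per-MTU source signals, `A` the channel-by-source mixing
matrix and `n(t)` additive noise.

**Sources.** Each source is white Gaussian noise band-pass filtered to the
sEMG energy band (20–450 Hz) and multiplied by a nonnegative activation
envelope. Amplitude modulation makes the marginal distribution
super-Gaussian (positive excess kurtosis), which is exactly the property
the separation stage exploits; the carriers are drawn from independently
spawned random streams so sources are mutually independent and
reproducible under one seed. The simulator makes no attempt to model
physiological motor-unit action-potential shapes, volume conduction or
fatigue; what passing tests show is that the *pipeline machinery* recovers
a known linear-mixture ground truth, not that it resolves real anatomical
compartments.

**Activation envelopes.** The elbow-flexion protocol is emulated as five
raised-cosine bursts of 3 s separated by 5 s of rest. Posture sets a gain
gradient across the compartments: in the neutral posture (N) the lateral
source (index 0) has peak gain 1.0 and the medial source
`dominance_gain = 0.4`; the supinated posture (S) reverses the gradient.
Within each cycle, compartment onsets are staggered across a phase span of
two thirds of the burst (capped by the rest interval). The stagger is a
deliberate modelling choice with a statistical justification: if all
sources share one identical envelope, their amplitudes are co-modulated
and the *empirical* joint distribution is no longer independent — in that
regime neither this package's estimator nor established ICA
implementations can separate the mixture (matched |r| saturates around
0.6–0.85 even noiselessly). Sequential compartment recruitment through the
movement restores empirical independence and is physiologically plausible
for a multi-compartment muscle moving through a joint-angle range.

**Mixing.** `A[i, j] = exp(−d²(electrode_i, source_j) / 2σ_j²)` with σ the
source's spatial spread (default one electrode pitch, 10 mm on the default
8×8 grid). Columns are max-normalized to 1, which pins the scale that ICA
leaves undetermined. **Noise** is white Gaussian at a configurable SNR
(default 20 dB against the clean mixture) plus an optional common
power-line sinusoid (default 50 Hz, amplitude 0; configurable to 60 Hz).

**Force.** Ground-truth force is the gain-weighted sum of the activation
envelopes (default 40 N per source at full activation, peak total near
120 N — the range of moderate elbow flexion), clipped at zero, with
optional Gaussian measurement noise (default off, so rest intervals are
exactly 0 N). How force "should" be measured is outside the model; the
linear envelope→force map is an assumption that makes the regression
target well defined.

## Preprocessing

Filtering is zero-phase and applied in the frequency domain: real FFT,
multiplication by the Butterworth *magnitude*

    |H(f)| = [1 + (low/f)^2n]^−1/2 · [1 + (f/high)^2n]^−1/2

(first factor dropped at `low = 0`, giving a pure low-pass), inverse FFT.
Defaults: 20–450 Hz, order n = 4. |H| ≤ 1 everywhere, so filtering never
adds energy; the half-power point at the cutoff and the analytic order-4
roll-off are asserted in the tests. An optional spectral notch
(± 2 Hz around the line frequency) is off by default. Analysis windows are
0.5 s advanced in 0.2 s steps, half-open 0-based sample intervals kept
while the full window fits. MVC normalization divides a signal by the
largest RMS over the supplied maximal-contraction trials; in simulator
runs, where no separate MVC recording exists, each separated source is
normalized by its own full-trace RMS (the degenerate single-trial case of
the same rule).

## Separation (maximum-likelihood ICA)

Centering removes the per-channel mean. Whitening eigendecomposes the
channel covariance and projects onto the top `n_components` (default 5)
eigenpairs scaled by the inverse square-root eigenvalues, so the whitened
data has identity covariance; dimension reduction happens here. The square
separation matrix W is then estimated by maximizing

    L(W) = Σ_t Σ_i log p(y_i(t)) + T log|det W|,    y = W Z,

under a hyperbolic-secant source prior `p(u) = 1/(π cosh u)`, whose score
is `g(u) = −tanh(u)`. The Jacobian term `T log|det W|` is required for the
likelihood to have a maximizer at all and is always included. Ascent uses
the natural gradient, `ΔW = η (I + g(y) yᵀ/T) W`, with η = 0.020; the run
stops when ‖ΔW‖_F < 1e-4 or after 1000 iterations. W is initialized at
identity plus seeded N(0, 0.01²) perturbation. The per-iteration
log-likelihood is recorded and is non-decreasing at the default step size
(asserted with 1e-9 slack). The mixing matrix is estimated as the
pseudo-inverse of the overall unmixing `W W_Z`.

Numerical and convention choices: components are canonicalized by
descending reconstructed-contribution variance `‖â_i‖² var(s_i)`, with
each source sign-flipped so its largest-magnitude sample is positive;
rank-deficiency below the requested component count raises an error naming
the rank; non-whitened input (covariance off identity by more than 1e-3)
is rejected. A fixed super-Gaussian prior cannot separate sub-Gaussian
sources (e.g. uniform-distributed signals) — a standard property of this
estimator family, irrelevant for sEMG but worth knowing when reusing the
module.

## Component classification and localization

Each recovered component's power spectrum (Welch, 0.5 s segments, 50%
overlap) is summarized by its EMG-band fraction: power inside 20–450 Hz,
excluding ± 2 Hz around the power-line frequency, over total power.
Components at or above a 0.7 fraction are labelled `emg_source`, the rest
`noise`. The rule is aimed at the dominant real-world contaminants —
baseline drift, movement artefact and line interference, all of which
concentrate power outside the (notched) band; broadband white noise is not
separable from EMG by band fraction alone.

EMG components are localized by treating `w_i = |Â[i, j]|` as electrode
weights: the estimate is the weighted centroid of electrode positions, the
peak electrode is `argmax w` (ties to the lowest row-major index), and
confidence is the peak's share of the column mass. The centroid is
invariant to positive rescaling of a column, degrades continuously with
noise, and is exact for one-hot columns. Estimated-to-true matching for
evaluation is greedy on minimal Euclidean distance; the electrode pitch is
the natural error unit.

## Force regression (backpropagation network)

Features are the windowed RMS amplitudes (0.5 s / 0.2 s) of the
EMG-labelled sources; the target is the window-averaged force. Both are
min–max scaled to [0, 1] with scalers fitted on the training split only.
The network has two hidden layers of five logistic-sigmoid units and a
linear output. Training is full-batch gradient descent on the MSE loss
with classical momentum, `v ← 0.9 v − 0.3 ∇L`, `w ← w + v`; at zero
momentum this reduces exactly to plain gradient descent. Stopping: epoch
loss ≤ 0.001 (on the scaled problem) or 1000 epochs. Gradients are exact
chain-rule backpropagation, verified against central finite differences to
relative error < 1e-5. Weights start at seeded uniform(−1/√fan_in,
+1/√fan_in), biases at zero.

## Evaluation protocol

Pearson correlation uses sample (n−1) denominators throughout. Per-sample
relative error is |actual − predicted| / actual × 100, rounded to one
decimal, with zero-actual samples excluded (with a warning). Because this
quantity diverges as the denominator approaches zero, the pipeline reports
mean/max relative error over held-out windows whose actual force exceeds
5% of the peak actual force — rest and transition windows contribute to
the PCC and MSE but not to relative error. Data splits: seeded shuffled
8:2 train/test, with 5-fold cross-validation inside the training set.
An optional recall/F1 wrapper binarizes actual and predicted force at a
caller-chosen %MVC threshold (not part of the core protocol, since
classification of a continuous force signal requires an arbitrary
threshold).

## Problem sizes used in the shipped checks

The acceptance checks run the simulator at the full two-posture, 5-cycle
protocol (≈ 37 s at 1000 Hz, 8×8 grid) for force prediction, a noiseless
5-source/64-channel mixture of T = 20 000 samples for separation quality,
and fifty 2-cycle trials at 20 dB SNR for the localization Monte Carlo —
sizes at which all the asserted statistics are stable while a full run of
the suite stays in the minutes range on one CPU.

## Known limitations

- The simulator's sources are modulated noise, not physiological MUAP
  trains; localization accuracy on real tissue (volume conduction,
  innervation-zone effects) is not addressed.
- The spectral classifier cannot tell broadband noise from EMG.
- The ICA prior is fixed super-Gaussian; sub-Gaussian interference would
  need an adaptive score function.
- Relative-error figures depend on the activity threshold; they are
  reported alongside PCC and MSE, never alone.
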