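# Methods

This note documents the models and procedures `trfsize` implements, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic-data results do and do not say about
real recordings.

## Encoding model and estimation

The forward model is linear in time-lagged stimulus features:
`EEG(t,n) = Σ_f Σ_τ w(f,τ,n) s(f,t−τ) + ε(t,n)`, with delays τ from 0 to
600 ms sampled at the EEG rate (77 delays at 128 Hz; the count is
`floor(0.6·rate) + 1`, covering both endpoints). Designs are built per
trial with zero stimulus history before each trial onset — trials are
independent presentations — and stacked, so no information crosses trial
boundaries.

Weights solve the ridge normal equations `(XᵀX + αI) w = XᵀY` per channel.
Because the per-trial Gram matrices add (`XᵀX = Σᵢ XᵢᵀXᵢ`), subset fits in
the learning-curve sweep reuse cached per-trial blocks, and the
cross-validation sweep reuses one eigendecomposition of the Gram matrix
across the whole alpha grid. The tested contract is equality with the
explicit normal-equation solution (to 1e−8 on random instances), not any
particular factorization.

**Regularization.** The grid is 15 log-spaced values from 1e2 to 1e8.
Validation correlation is averaged over channels first, then over the
contiguous cross-validation folds (5 by default); ties break toward the
stronger regularization. One alpha is selected on the *full* training pool
and reused at every training-set size, so learning-curve differences
reflect data quantity, not re-tuning. Note a structural property of
correlation-scored validation: Pearson r is scale-invariant, so heavy
shrinkage costs nothing in scale and often wins by reducing variance — on
the synthetic datasets the selected alpha typically sits at the top of the
grid. This is a property of the scoring rule, not a bug; the grid bounds
are part of the protocol.

**Scoring.** Per-channel Pearson correlation between predicted and actual
EEG over time, averaged (unweighted) across channels. Channels with zero
variance are flagged undefined and excluded from the mean. For
repeated-test designs the target is the EEG averaged across the repeats of
each test stimulus; predictions and responses are concatenated over test
stimuli before correlating.

## Learning curves and bootstrap semantics

Training sets grow from `start_size` (default 10) in steps of `step` up to
the pool size. Each of `n_boot = 10` bootstrap replicates draws one random
permutation of the pool; its subset at size x is the permutation's first x
trials. Marginally, every subset is a uniform random size-x subset drawn
without replacement; consecutive sizes within a replicate are *nested*
(the training set is "gradually increased by one random trial at a time"),
which is what makes weight comparisons at size x vs x+1 meaningful and
keeps the sweep at O(pool) Gram updates per replicate. An independent
with-replacement mode is available behind a flag. The designated first
replicate's model sequence is retained for the stability analysis. The
curve records all replicate scores per size, their mean, and the bootstrap
standard error; sizes are reported both in trials and in seconds (size ×
mean trial duration).

## Knee-point detection

The knee of the mean learning curve f(x) is the size maximizing the
curvature magnitude `|K| = |f″| / (1 + f′²)^1.5`. Two numerical choices
matter:

- **Unit-square normalization.** Both axes are rescaled to [0, 1] before
  differentiating. In raw units any gently sloped saturating curve has
  `1 + f′² ≈ 1`, so |K| ∝ |f″| is monotone decreasing and the argmax sits
  at the first grid point — no interior knee exists. Normalization (the
  convention of the knee-detection literature this follows) restores an
  interior maximum at the bend. The knee is reported in original units.
- **Savitzky–Golay derivatives.** f′ and f″ come from a local quadratic
  fit over `smooth_window` points (default: ~31% of the series length,
  odd, minimum 5). Second differences of noisy curves are extremely
  noise-sensitive; the wide quadratic window is what makes knees of
  bootstrap-mean curves with a few percent noise reproducible. On
  noiseless analytic curves the detected knee matches a dense
  finite-difference curvature oracle to within one grid step (tested for
  parabola, saturating exponential, and logistic curves), and on noisy
  saturating curves with time constants 5/15/40 grid units the detected
  knees preserve the rank order of the time constants in ≥ 18/20 seeds.

The argmax is searched over the interior of the grid, excluding a
`boundary_margin` (default 5%) at each end where smoothed derivative
estimates are unreliable. A result is **invalid** — mirroring subjects for
whom no knee can be computed — when the interior argmax hugs the margin,
when the curve is flat (zero range; a straight line also fails on
numerically zero curvature). Validity uses the curve's range rather than
its end-to-start rise so that non-monotone but genuinely curved inputs
(e.g. a parabola) keep their knee. Grand averages are taken over valid
per-subject knees only, with invalid subjects counted and reported, never
imputed.

## Weight stability

For the nested model sequence, adjacent weights are the flattened weight
arrays of models at consecutive sizes; their Pearson correlation is
reported per size together with the first size after which it stays at or
above a threshold (default 0.9). On noiseless synthetic data adjacent
correlations exceed 0.95 everywhere past the knee and approach 1.0,
reproducing the qualitative signature of a stabilized receptive field.

## Synthetic data generator

The generator is the package's ground truth and defines its study
conditions: 128 Hz EEG, ~2-s trials (durations uniform on
[0.75, 1.25] × mean), a repeated-test design of 10 stimuli × 10 repeats
whose averaged response is the test target (an 80/20 continuous split is
also available), and the 16-row stimulus model (envelope + pitch + 14
binary phonological onset features).

- **Receptive fields**: gamma-shaped causal kernels
  `(t/L)^p e^{p(1−t/L)}` peaking at latency L (80–200 ms) with width
  parameter controlling p — smooth, speech-cortex-like latencies; kernels
  must fit inside the 600 ms window (latency + 2.5 widths) or are
  rejected. Channels receive the kernel through a smooth sinusoidal
  topographic gain bounded in [0.2, 1.0], giving channel diversity without
  modeling electrode geometry.
- **Stimuli**: the envelope row is squared low-passed noise (nonnegative,
  spectral content well below 25 Hz); pitch alternates voiced glides
  (100–250 Hz) with unvoiced zeros; phonological rows place onset
  impulses of a random ARPAbet phoneme sequence (50–150 ms segments)
  through the shipped phoneme→feature table.
- **Noise**: pink (1/f) by default, white available for oracle tests.
  Noise is scaled *per channel* so the realized SNR equals the requested
  `snr_db` exactly; channels carrying no signal receive unit-variance
  noise. `snr_db = inf` returns the noiseless convolution bit-exactly
  (it equals a brute-force double-loop lagged sum to < 1e−10).
- **Default SNR for end-to-end runs**: −10 dB per channel. With the
  10-repeat averaged test set this yields channel-mean test correlations
  around 0.4 and clearly saturating learning curves over a 60-trial pool
  — the qualitative regime of a well-performing subject. The SNR of real
  recordings varies widely; it is an explicit argument everywhere.

What the generator does **not** emulate: eye blinks, motion or muscle
artifacts, electrode drift, nonstationary attention effects, or any
nonlinearity between stimulus and response — the ground truth *is* the
linear model. Passing tests therefore demonstrate correctness of the
estimation and sufficiency machinery, not that real EEG satisfies the
model; real-data knee points depend on recording quality and cannot be
predicted from these simulations.

## Preprocessing

Standard chain: notch at the native rate (zero-phase IIR notch, quality
factor 60 so the response 5 Hz away stays within 3% of unity after
forward–backward filtering), then a 1–15 Hz Hamming-window FIR band-pass
applied forward–backward (taps from the Hamming design rule for a one
low-edge-bandwidth transition, ~53 dB stopband attenuation per pass),
then polyphase resampling to 128 Hz. Notching before decimation keeps
line noise from aliasing into the band. Filters are zero-phase (no lag
between input and output) and linear to numerical precision; recordings
shorter than three filter lengths are rejected with guidance rather than
silently padded.

## Feature extraction from real inputs

Envelope: magnitude of the Hilbert analytic signal, 3rd-order Butterworth
25 Hz low-pass (zero phase), polyphase resampling, negative ripple clipped
to zero. Phonological onsets: a 1 at the sample nearest each phoneme's
start (ties round down) in every feature row activated by the shipped
ARPAbet → 14-feature table (`trfsize/data/arpabet_features.csv`); the
table is one documented convention for place/manner classes, loadable and
overridable from file, not ground truth. Onset-only coding is the default;
features are binary impulses, not sustained values. Pitch tracks are
ingested (not computed) and sampled-and-held onto the target grid; unvoiced
spans stay zero. Continuous features can be z-scored using training-set
statistics only (`zscore_continuous`); the synthetic pipeline runs without
normalization so fitted weights remain directly comparable to the
generating ground truth. Match-filter alignment slides the presented
stimulus along the recorded audio channel and takes the argmax of the
normalized cross-correlation; onsets are recovered to ±1 sample at 10 dB
SNR, and peaks below the score threshold return an explicit "not found"
outcome rather than a guess.

## Problem sizes used by the tests and the acceptance script

The test suite validates solver exactness on small random instances,
ground-truth recovery on a 150-trial noiseless 16-feature dataset, protocol
fidelity on a 60-trial pool, and knee detection against brute-force
curvature oracles. The acceptance script simulates three subjects with
60-trial training pools at −10 dB and reports their grand-average knee.
These sizes are the package's chosen working scale for synthetic
validation; all machinery is size-generic.

## Known limitations

- Correlation-based alpha selection saturates at strong regularization
  (see above); users wanting interior alpha optima should score with a
  scale-sensitive loss, which the package does not currently implement.
- The knee is a property of the *smoothed, normalized* curve; very short
  curves (< ~15 sizes) leave little room between the smoothing window and
  the boundary margins, and knees there should be read cautiously.
- "10-fold bootstrapping" is implemented as 10 random subsets per size
  (nested within replicate, without replacement inside a subset); this is
  one reading of a protocol that admits several.
- ICA/ocular-artifact removal, manual artifact rejection, mixed-effects
  inference on knee differences, and noise-ceiling corrections are out of
  scope; the preprocessing chain expects artifact handling to have
  happened upstream.
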