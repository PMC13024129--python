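# Methods

`radarbp` implements an end-to-end pipeline for contactless blood-pressure
(BP) estimation from frequency-modulated continuous-wave (FMCW) radar:
a radar DSP front-end that turns raw I/Q chirp cubes into standardized
radar pulse-wave (RPW) windows, an unsupervised VAE-based signal-quality
index (VAE-SQI) that screens corrupted windows, label-preserving
augmentation, a Mamba-enhanced multi-task U-Net regressing systolic and
diastolic pressure (SBP/DBP) while reconstructing the arterial pressure
(ABP) waveform, and an evaluation harness with the device-grading metrics
used in the BP literature (AAMI, BHS, Bland-Altman).  Because real
synchronized radar/ABP recordings are private clinical data, every input is
produced by a bundled synthetic generator; all quantitative statements the
test suite makes are statements about that generator's study conditions.

## Radar model and DSP front-end

The simulator transmits linear chirps (defaults: 77 GHz carrier, 3 GHz
sweep = 50 MHz/us x 60 us, 64 fast-time samples at 2 MHz, 4 receive
channels) at an effective frame rate of 200 Hz.  A chest target at range
R(t) = R0 + x(t) contributes an IF tone whose fast-time frequency encodes
range and whose slow-time phase follows the displacement map

    phi(t) = 4 * pi * x(t) / lambda,

the analytic oracle for the whole DSP module.  Chest motion is a cardiac
component (0.1-0.5 mm, default 0.2 mm at 0.8-3 Hz) superposed on
respiratory drift (default 1.5 mm at 0.25 Hz — shallow sternum breathing;
larger excursions push the target across range bins, which the
single-bin pipeline deliberately does not model).  A uniform linear
half-wavelength array imposes the geometric phase
`exp(-j 2 pi d n sin(theta) / lambda)` on channel n; stationary clutter is
chirp-invariant; receiver DC offsets are per-channel complex constants.

Processing chain and the numerical choices in it:

1. **Clutter suppression** — slow-time mean subtraction per fast-time
   bin/channel.  Removes any chirp-invariant component exactly and is
   idempotent.
2. **Range compression** — plain fast-time FFT (no window); candidate
   ranges are FFT bins.
3. **Beamforming** — conjugate-weighted channel sum with unit-modulus
   steering weights.
4. **Range/angle selection** — for each candidate (bin, steering angle)
   the demodulated phase is scored by heart-band (0.8-3 Hz) spectral peak
   power divided by the variance of the linearly detrended phase, *scaled
   by the mean beamformed power at that bin*.  The power factor is needed
   because the periodicity ratio alone is amplitude-invariant: a target's
   phase looks equally periodic at every non-null steering angle, so the
   ratio cannot localize the angle on a noiseless cube.  Ties resolve to
   the lowest bin, then the smallest |theta|.
5. **DC removal** — centered sliding-window mean with full-length windows
   shifted inward at the edges.  In the assembled chain the window is the
   whole series: a short (seconds) local mean tracks the respiratory I/Q
   loop and measurably distorts the demodulated phase (recovery r dropped
   from >=0.995 to ~0.94 in our simulations), while true receiver DC is
   chirp-invariant and already gone after step 1.
6. **Circle-fit recentering** — an algebraic (Kasa) circle fit of the
   beamformed I/Q samples, subtracting the fitted centre.  Step 1
   necessarily removes the *target's own* mean phasor as well; unless the
   respiratory phase swing spans many radians, that leaves the I/Q arc
   off-centre and the demodulated phase badly distorted (measured r
   0.95-0.98 without recentering, >=0.995 with it).  This is the standard
   DC-compensation step in phase-based vital-sign radar.
7. **Extended DACM demodulation** — Phi[0] = 0 and
   Phi[n] = sum_{k<=n} (I dQ - Q dI) / (I^2 + Q^2).  On unit-circle data
   the increment equals sin(dphi), so the method is exact for constant
   steps up to the accumulated O(dphi^3) discretization error; it is
   wrap-free by construction.  Equivalence with the unwrapped arctangent
   at the 1e-3 rad level therefore holds for radar-realistic step sizes
   (|dphi| of a few hundredths of a radian at 200 Hz), not for arbitrary
   steps up to the 0.3 rad validity cap.
8. **Pulse extraction** — 4th-order Butterworth band-pass 0.8-10 Hz,
   applied forward-backward (zero phase, preserving upstroke and
   dicrotic-notch timing), then polyphase resampling to 100 Hz.
9. **Windowing and standardization** — overlapped windows of L = 1000
   samples (10 s) at 50% overlap; each window standardized as
   (x - mean) / (sd + eps) with eps = 1e-8; windows with sd < 10 eps map
   to zeros.

## Hemodynamic generator

Each cardiac cycle is a dimensionless template: a systolic Gaussian bump
at cycle fraction u1, a dicrotic Gaussian bump at u1 + delay, and an
exponential diastolic tail, normalized per cycle so the sampled maximum /
minimum land on the requested SBP/DBP within 1 mmHg at 100 Hz.  The RPW is
the amplitude-normalized, zero-phase low-pass-smoothed (12 Hz) ABP plus
Gaussian sensor noise — morphology (peak and notch timing) is preserved
within 2 samples.

Blood pressure is tied to morphology through a smooth invertible map:

| waveform feature          | driven by | range                 |
|---------------------------|-----------|-----------------------|
| systolic upstroke fraction| SBP       | 0.25 -> 0.10 of cycle |
| dicrotic notch depth      | DBP       | 0.45 -> 0.05 of pulse |
| systolic-to-dicrotic delay| DBP       | 0.10 -> 0.28 of cycle |
| diastolic decay constant  | DBP       | 0.15 -> 0.60 of cycle |

Higher SBP gives an earlier, sharper peak; higher DBP a later, shallower
notch and slower decay (a peripheral-resistance effect).  This map is what
the regression network must invert from shape alone — window
standardization removes absolute amplitude, so amplitude itself carries no
label information.  Cohort conditions: per subject SBP ~ U[95, 165] mmHg,
DBP ~ U[55, 100] mmHg with pulse pressure >= 30 mmHg, heart rate
~ U[0.8, 1.8] Hz; within a session SBP and DBP are modulated by slow
+-10 / +-6 mmHg sinusoids with *independent* phases (neither target is a
within-subject affine function of the other), plus optional Gaussian
observation noise on the labels.  Corruption (spikes >= 5 sd, low-frequency
drift, localized noise bursts, zeroed dropouts, FFT phase scrambling) is
injected into exactly `round(fraction x N)` windows with ground-truth
labels retained for SQI evaluation.

What the generator deliberately does not emulate: body scattering and
multipath, sensor repositioning, inter-subject morphology families beyond
the parametric template, arrhythmias, and any real coupling between
cardiovascular state and waveform shape.  Passing tests therefore
demonstrate that each algorithm does what it claims under controlled,
recoverable conditions — not clinical accuracy on human data.

## VAE-SQI

Standardized windows are pre-screened by six [0, 1] indicators (the
formulas are this package's, since only the indicator names are standard):
autocorrelation peak in the 0.33-1.5 s lag band; spectral energy fraction
in 0.8-3 Hz; 1 - 20x the fraction of first-difference robust-z outliers
(|z| > 6); 1 - energy fraction below 0.4 Hz; 1 - coefficient of variation
of inter-peak intervals; 1 - energy fraction above 10 Hz.  Their unweighted
mean is the pre-screen score s_p; a constant window scores 0.

The 1-D convolutional VAE (encoder stages 32/64/128/256 channels, kernel
7, stride 2, batch-norm + LeakyReLU(0.2) + one residual block per stage;
latent 64; mirrored transposed-convolution decoder with final Tanh) is
trained in two stages: 100 epochs on the top 35% of windows by s_p at
learning rate 3e-4, then 60 epochs on all windows at 1.5e-5, with the KL
weight beta warmed up linearly 0.01 -> 0.5 over the first 30 epochs.  The
reconstruction term is ||x - x_hat||^2 / L per window.  A width-reduced
profile (8/16/32/64 channels, latent 16) ships for single-CPU runs and is
what the test suite trains; the full profile is the library default.

Component scores: S_R = exp(-e / median e) on the reconstruction error,
S_L = exp(-d / median d) on the latent distance to the high-quality centre
(the mean encoder mu over the stage-1 subset; medians frozen from that
subset after training), S_M = mean of (plausible peak count for the window
duration at 0.66-3 Hz, fraction of input peaks preserved within +-3
samples in the reconstruction, 1 - second-difference energy ratio
normalized by 6x the variance — the white-noise expectation), and
S_P = s_p.  Fusion uses weights 0.35/0.15/0.30/0.20; the threshold is the
score of the ceil(0.8 N)-th ranked window, ties retained; retained
training-window scores rescaled to mean 1 become sample weights.
Scoring is always a forward pass of the frozen scorer; guards raise if the
scorer's training subjects intersect a validation/test split.

## Augmentation

Five operators, each applied independently with probability 0.5 in the
fixed order shift -> scale -> warp -> noise -> wander: circular time shift
up to +-10% of the window, amplitude gain U[0.9, 1.1], time warp by a
single uniform ratio in [0.95, 1.05] with linear re-interpolation to L,
Gaussian noise at 0.02 of the window sd, and a 0.05-amplitude 0.5 Hz
sinusoidal baseline wander.  Three augmented copies join each original
(4x the window count), restricted to the training split by a guard.

## Network

Input: (RPW, velocity RPW, acceleration RPW) — central differences scaled
by the sampling rate, one-sided at the edges — each channel L2-normalized.
Encoder: five stages of residual blocks (two kernel-3 conv-BN-ReLU layers,
1x1 projection shortcut on channel change; 1/2/2/2/1 blocks per stage)
with channels base x (1, 2, 4, 8, 16) and kernel-3 stride-2 downsampling
convolutions between stages, so the bottleneck runs at L/16.  The
bottleneck fuses kernel-1/3/5 branches (each conv-BN-ReLU + channel-
temporal attention) by a pointwise convolution, then a bidirectional Mamba
block, then dropout 0.1.

Channel-temporal attention (CTA): a shared two-layer perceptron (reduction
4) over global average- and max-pooled channel descriptors, sigmoid-gated;
a kernel-7 convolution over the channel-pooled average/max stack for the
temporal gate; the input is multiplied by both.  The squeeze MLP uses GELU
rather than ReLU: at tiny widths its hidden layer is 1-2 units and a hard
ReLU can die permanently.

The Mamba branch follows the canonical selective-SSM formulation (the
cited architecture leaves internals unspecified): input projection to
expand x d_model plus a gate, causal depthwise convolution of width 4,
input-dependent step size via softplus (dt_rank = d_model/16), diagonal
state matrix A = -exp(A_log) with S4D-real initialization (A_n = -n),
zero-order-hold discretization, SiLU gating, output projection; state size
16.  The scan is an explicit per-timestep recurrence — linear in T, checked
against a brute-force loop oracle — so no compiled kernel is required.
The bidirectional block runs two independent branches on the sequence and
its reversal and fuses them as LN(GELU(Linear([h_f; h_b])) + input).

Decoder: four up-stages of linear 2x interpolation (the 1-D case of
bilinear image upsampling), CTA-refined skip concatenation and one
residual block, ending at base channels and full length.  Heads: global
average pooling -> FC(base -> max(base/2, 8)) -> ReLU -> dropout -> FC(-> 2)
for (SBP, DBP); and three convolutions (kernels 3, 3, 1; channels
base -> base/2 -> base/4 -> 1) for the ABP waveform.  The final projection
has no bias: the reconstruction loss instance-normalizes the waveform, so
an output offset is unidentifiable and would never receive gradient.
Skip-connection CTAs do not share weights with bottleneck CTAs.

The full-size profile (base 64, d_model 1024) matches the described
architecture; the `tiny` profile (base 4, L = 256) trains in minutes on
one CPU and is what every training test uses.

## Objective

L = L_BP + lambda_ABP * L_ABP with lambda_ABP = 0.01;
L_BP = lambda_SBP * Huber_delta(SBP) + Huber_delta(DBP) with
lambda_SBP = 2.0 and delta = 1 mmHg.  The Huber linear branch uses the
standard continuous form delta|e| - delta^2/2 (at delta = 1 it coincides
with the variant that subtracts delta/2).  L_ABP instance-normalizes both
waveforms (per-sample zero mean / unit variance) before a Smooth-L1 with
transition beta = 1, making it invariant to per-sample affine rescaling of
either waveform.  Quality sample weights multiply both the BP and the
waveform term per window, without renormalization, before the batch mean.

## Training and evaluation protocol

Subject-wise 70/10/20 split (largest-remainder rounding, seeded shuffle);
AdamW (weight decay 1e-5) with cosine annealing; early stopping on total
validation loss with patience 20 (the monitored quantity is a choice — the
alternative of BP-only loss is equally defensible); best-validation
weights restored.  Full-profile defaults are lr 1e-3, batch 512, up to 120
epochs.  The tiny profile uses batch 32, <= 30 epochs and lr 3e-3 — the
larger rate compensates for the narrow network and small batches.  The
regression-head bias is initialized at the training-label mean, so the
mmHg-scale Huber loss (whose gradients are magnitude-capped at delta)
starts centred instead of spending its budget travelling ~100 mmHg.

Metrics use the error convention predicted - reference; SD is the sample
(n-1) standard deviation, so RMSE^2 = ME^2 + SD^2 (n-1)/n.  AAMI: |ME| <=
5 mmHg and SD <= 8 mmHg, boundaries inclusive.  BHS: best grade whose
cumulative |error| percentages within 5/10/15 mmHg meet 60/85/95 (A),
50/75/90 (B) or 40/65/85 (C), inclusive, else D.  Pearson r of a constant
prediction is reported as NaN with a warning.  Ablation runners (auxiliary
loss-weight sweep over {0, 0.01, 0.05, 0.1, 0.2, 0.5}, SQI retention over
{1.0, 0.9, 0.8, 0.7}, temporal module, bottleneck variant) train identical
seeds on a shared subject split and emit one metrics row per variant.

## Problem sizes

Everything the test suite and the acceptance script run fits one CPU:
DSP recovery uses a 20 s cube (4000 chirps x 64 samples x 4 channels);
SQI discrimination uses 20 subjects x 30 windows of 10 s at the reduced
VAE profile with 30 + 15 training epochs; parameter recovery uses 45
subjects x 25 windows of 2.56 s (a cohort close to the 55-subject study
scale, large enough that subject-split variance does not dominate) with
the tiny network and <= 30 epochs;
the two-stage full-profile VAE and the base-64 network are constructed and
shape-checked but never trained in tests.

## Known limitations

- The generator's BP-to-morphology map is one plausible choice; real
  RPW-BP coupling is subtler, so recovery results bound what the
  architecture can learn, not what radar can measure.
- Range migration (respiration beyond ~3 mm at the default geometry) and
  moving subjects are out of scope for the single-bin DSP chain.
- **Multi-task representation collapse at tiny scale.**  Under joint
  training the tiny (base-width-4) trunk converges onto systolic features:
  SBP is recovered almost perfectly (held-out MAE ~3 mmHg, r ~0.97-0.99),
  while the DBP readout plateaus near r ~0.3-0.5 — and a linear probe of
  the final decoder features finds essentially no diastolic information in
  the trunk at all (probe r ~0.5 vs ~0.99 for SBP).  The failure is not in
  the data: a single-task control (systolic term switched off) learns DBP
  from the same windows to held-out r ~0.88 within 15 epochs.  The
  collapse is robust to seeds, 60-epoch schedules, learning rate (1e-3 /
  3e-3), Huber threshold, batch size, base width 8, wider readout heads,
  augmentation, CTA/temporal-module ablations, task weighting
  (lambda_SBP in {1, 2}) and auxiliary-reconstruction weighting — i.e. it
  is a property of joint optimization at this width and data scale, not of
  any single hyperparameter.  Diastolic recovery results from the reduced
  profile therefore do not transfer to the full-width model.
- The numpy autodiff core favours clarity over speed; the full-size
  profile is practical to construct but not to train in this package.
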