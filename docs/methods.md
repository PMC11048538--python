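# Methods

`eegaug` implements a data-augmentation pipeline for two-class (left vs
right hand) motor-imagery EEG: raw 3-channel trials are converted into
32×32 time–frequency images, a class-conditional deep-convolutional GAN
trained with the Wasserstein gradient-penalty objective (DCGAN-GP)
learns the image distribution per class, and ResNet classifiers measure
whether mixing generated images into the training set improves held-out
accuracy.  This note records the models, the parameters that matter, and
the design choices made where more than one construction was defensible.

## Synthetic trial model

Real motor-imagery EEG shows mu (8–13 Hz) and beta (13–30 Hz) rhythms
over sensorimotor cortex whose power drops on the hemisphere
contralateral to the imagined hand (event-related desynchronisation,
ERD).  The synthetic generator reproduces exactly this structure and
nothing more:

- per trial, one mu and one beta sinusoid, frequency drawn uniformly in
  the band, uniform random phase, amplitudes `mu_amp` (default 1.0) and
  `beta_amp` (default 0.5);
- the channel contralateral to the label (right hand → C3, left → C4)
  carries the rhythm scaled by `1 − erd_depth` (default `erd_depth` 0.6,
  a deep but physiological desynchronisation); the ipsilateral channel
  carries it unscaled and Cz at half amplitude;
- each channel adds independent 1/f^α background noise (α = 1, the
  canonical EEG spectral slope), synthesised by shaping white Gaussian
  noise in the frequency domain and normalised to unit RMS before
  scaling by `noise_amp` (default 1.0);
- 4.0 s at 250 Hz per trial (the imagery-segment length is a package
  default; published recordings are epoched by the `window` argument of
  the reader).

ERD is applied over the whole trial — no onset dynamics — because the
image pipeline integrates whole-trial windows anyway.  No artifacts
(blinks, EMG), no inter-subject variability.  Consequently, passing
tests show that the *pipeline* preserves and the GAN reproduces the ERD
class signature; they say nothing about robustness to artifacts or
subject shift in real recordings.

Random-stream discipline: each trial draws from a substream keyed by
(class index, trial counter) spawned from the root seed, so enlarging a
dataset never reshuffles earlier trials.

## Trial → image pipeline

1. Zero-phase band-pass 0.5–40 Hz.  Implemented in the frequency domain
   with raised-cosine transitions (default: lo/2 below the low edge,
   5 Hz above the high edge) rather than an IIR filter: on 4-s epochs,
   forward–backward IIR filtering leaves start/end transients that
   dominate the RMS of stop-band tones, while spectral weighting gives
   clean stop-band suppression and exact zero phase.  A 50 Hz notch of
   the same construction (±2 Hz raised-cosine) is applied only when
   reading real recordings; synthetic data has no mains interference.
2. Per channel, STFT magnitude with 128-sample Hann windows, 75 %
   overlap (hop 32) and 512 FFT points; frames start at hop multiples
   with no padding, so 1000 samples give 28 frames, and bin k maps to
   k·fs/512 Hz.  Magnitudes pass through log(1 + m) by default —
   linear magnitude compresses the beta band into invisibility; the
   flag `log_power` restores linear if wanted.
3. Crop to bins with 0.5 ≤ k·fs/512 ≤ 40 (bins 2…81 at 250 Hz, 80 rows).
4. Bilinear resize (separable, endpoint-aligned, so constant maps stay
   constant and same-shape targets are identity) to 11×33 per channel.
5. Stack C3, Cz, C4 vertically (33×33), bilinear-resize to 32×32, and
   min–max normalise per image to [0, 1]; a constant image maps to 0.5.

Two under-determined points were resolved as follows: the 33-row stack
becomes 32 rows by resizing (not by cropping a row, which would discard
one channel's edge); and per-channel maps are (frequency rows × time
columns), since 33 matches the frame count and 11 the reduced frequency
axis.  `row_band_map` traces this chain to report which of the 32 final
rows carry each channel's mu/beta content (with defaults: C3 mu → rows
2–3, C4 mu → rows 23–24), which is what the quantitative image
comparison and the class-signature checks use.

## Conditional DCGAN-GP

Generator: z ∈ R¹⁰⁰ ~ N(0, I) concatenated with a 2-d one-hot label →
fully connected to 8·8·128, layer-normalised, Leaky ReLU (slope 0.2) →
reshape → two stride-2 transposed convolutions (kernel 4) 128→64→1 with
layer norm + Leaky ReLU after the hidden stage → tanh, giving one
32×32 image in [−1, 1].  Critic: the image plus one constant label
plane (+1/−1) → three stride-2 convolutions (kernel 4) 2→64→128→256,
layer norm after all but the first, Leaky ReLU → linear head to a
single unbounded score (no sigmoid — it is a Wasserstein critic).
Parameters initialise from N(0, 0.02); these widths satisfy the
architecture's stated constraints (100-d Gaussian input, wide FC +
reshape, transposed convolutions, layer norm, Leaky ReLU, 32×32 output)
where exact numbers were not published.

Losses, in minimisation form:

    L_G = −E[D(G(z))]
    L_D =  E[D(G(z))] − E[D(x)] + λ·E[(‖∇_x̂ D(x̂)‖₂ − 1)²]

with x̂ = ε·x + (1−ε)·G(z), ε ~ U[0,1] per sample.  (The critic
objective is sometimes printed in maximisation orientation with the
penalty added; the form above is the standard one actually minimised.)
Training: per outer iteration, k = 5 critic Adam steps (fresh real
minibatch, fresh latents, interpolation, penalty) then one generator
Adam step; λ = 10, batch 64, Adam lr 2·10⁻⁴, β₁ = 0.5, β₂ = 0.9,
2000 iterations at full scale.  λ, k, m and β₂ follow common WGAN-GP
practice and are all configurable.  The Wasserstein estimate logged to
the history is mean(real) − mean(fake).

Label conditioning is the minimal concatenation scheme; during critic
updates the fake batch reuses the real batch's labels so every
interpolated sample has a well-defined label plane.  Setting
`conditional=False` on both specs yields unconditional networks; two
per-class models can then be trained on class-filtered image sets.

Everything runs on a small in-package reverse-mode autodiff engine over
numpy (`eegaug.autodiff`).  Backward rules are themselves compositions
of primitive operations, so the parameter gradient of the penalty — a
gradient of a gradient — comes from the same machinery
(`create_graph=True`), and is verified against central finite
differences.  Convolutions are im2col/col2im GEMMs (the two primitives
are exact adjoints, which is also how the transposed convolution is
built); col2im's overlap-add is a numba kernel.  Networks run in
float32; gradient-check tests run the same code in float64.

## Evaluation classifiers

ResNet-10 and ResNet-18 for 32×32×1 inputs, built exactly to their
stage tables: a 3×3 stem convolution (64 maps), for ResNet-10 a 2×2
max-pool then four residual blocks (64, 128, 256, 512) each halving the
spatial size; for ResNet-18 no stem pool and pairs of blocks per width
with the first of each pair (after the first pair) striding.  Blocks
are two 3×3 convolutions with identity shortcuts, or 1×1 stride-2
projections where shape changes; global average pooling and a 2-way
softmax head close both nets.  No batch normalisation — the tables list
none, and its absence keeps evaluation deterministic.

Classifier training hyperparameters are not pinned by the protocol;
the package defaults are Adam (lr 10⁻³), batch 32, 30 epochs, a 10 %
validation split and restoration of the best-validation-accuracy epoch.
Generated images are barred from evaluation sets (`evaluate` raises),
so accuracy is always measured on real data only.

## Augmentation protocol

Per seed: disjoint synthetic train/test trial sets (independent
substreams; the harness asserts no trial-id overlap), preprocessing,
GAN training on training images only, generation of a pool of 2× the
largest requested ratio (so mixtures sample without replacement), then
per ratio r: all real training images plus round(r·n_real) generated
ones, class-allocated by largest-remainder rounding to the real class
proportions, shuffled, used to train a fresh classifier that is scored
on the real test images.  The report stores one accuracy per (ratio,
seed, variant) with per-ratio mean/min/max and deltas against the
ratio-0 baseline; deltas are recomputed from the stored accuracies.

Desk-scale study sizes (chosen once for the shipped tests and the
acceptance script): the generative study trains 300 iterations at batch
32 on 400 images (200 per class, erd_depth 0.6) and compares 200
generated images per class against the real set over three generation
seeds; the mixing study uses ratios {0, 1.0}, three protocol seeds,
ResNet-10, an 80-iteration batch-16 GAN and 6-epoch classifiers on
48 train / 48 test trials per class.  At this scale the generated
images reproduce the contralateral-mu class signature with the correct
sign and the 1:1 mixture's mean accuracy stays within a 2-percentage-
point band of the real-only baseline; the published full-scale
accuracies require the external BCI Competition IV 2b recordings and
full-scale (2000-iteration) training, which the same harness supports
via the GDF/EDF reader.

## Numerical notes and limitations

- Degenerate inputs: constant images normalise to mid-gray; zero
  signals produce zero spectrograms; max-pool splits gradient equally
  across ties; the penalty's gradient norm is computed as sqrt of a sum
  of squares and is non-differentiable only at exactly zero gradient.
- Determinism: every public entry point takes a seed; trials, GAN
  training, sampling and classifier training are bit-reproducible on a
  fixed BLAS configuration (single-threaded linear algebra).
- PNG image sets quantise pixels to 8 bits (max error 1/255); a
  lossless float archive can be written alongside for exactness-
  sensitive work.
- The synthetic ERD model is stationary and artifact-free; results on
  it bound nothing about inter-subject transfer on real recordings.
- The reader maps BCI IV 2b cue codes (769/770) to left/right in one
  table constant; other dialects are a one-line extension.
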