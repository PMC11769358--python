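# Methods

## Problem and model

Scalp EEG (scEEG) is attenuated and mixed by the head, so most interictal
epileptiform discharges (IEDs) that are obvious on intracranial (iEEG)
recordings — here, foramen-ovale electrodes resting on mesial temporal
structures — are invisible at the scalp.  This package implements a
translation model that estimates the iEEG segment from the concurrent scEEG
segment, and a downstream IED detector that operates on the estimates.

Let X ∈ R^{L×M} be a scalp segment (L time samples, M sensors) and
Y ∈ R^{L×M̄} the concurrent intracranial segment.  The observation model is
X = F(Y) + noise with F an unknown, possibly nonlinear mixing.  The
translation model inverts this relationship generatively:

- an encoder E maps X to a Gaussian posterior (μ, σ) over a latent code
  z ∈ R^Z (Z = 256 at full scale), sampled via the reparameterization
  z = μ + ε ⊙ σ, ε ~ N(0, I);
- a generator G(X, z) produces the estimate Ỹ.  The latent code is projected
  by a dense layer onto a coarse (L/2^I_up × M̄) grid and refined by I_up
  stages of SPADE residual blocks and ×2 temporal upsampling; a two-layer
  LSTM over the L time steps and a time-distributed dense layer with tanh
  produce the bounded output.  Each SPADE block normalizes its activation per
  (channel, sensor) over batch and time, then denormalizes it with per-element
  scale γ and shift β predicted from X downsampled (average pooling) to the
  stage's temporal resolution — this is what keeps the scalp's sensor
  structure in the generation path;
- a Markovian (patch) discriminator D of strided temporal convolutions emits
  one unbounded realness score per intracranial sensor (patch size 1×M̄); its
  last convolution has no normalization or activation.

Training alternates two updates per batch.  D minimizes the two-sided hinge
loss; E and G jointly minimize

    L_G = L_Gh + λ1·L_KL + λ2·L_L1 + λ3·L_FM

with L_Gh the hinge adversarial term (−E[D(Ỹ)]), L_KL the KL divergence of
the posterior from N(0, I), L_L1 the mean absolute reconstruction error, and
L_FM the feature-matching distance over D's intermediate maps.  The estimate
fed to D in its own update is detached, so the discriminator step never
updates E or G and vice versa.

## Parameters that matter

| parameter | default | units / meaning |
|---|---|---|
| L, M, M̄ | 64, 20, 12 | segment geometry: 320 ms at 200 Hz, 20 scalp / 12 FO sensors |
| Z (latent_dim) | 256 | latent posterior dimension |
| I_E, l_e, C_e | 4, 5, 16 | encoder depth, temporal filter length, base filter count (doubling per layer) |
| I_up | 4 | generator stages (starting temporal length L/16) |
| l_d, I_D | 5, 4 | discriminator filter length and depth |
| λ1, λ2, λ3 | 0.05, 100, 1 | KL / L1 / feature-matching weights |
| lr (G, D) | 2e-4 | Adam, betas (0.5, 0.999) |
| batch size | 16 | |

Layer depths and filter counts are free parameters of the architecture
family (the original study does not pin them); they are all exposed in
`ArchitectureConfig`.  The σ head outputs log-variance (σ = exp(½ logvar))
to guarantee positivity.  Temporal upsampling is nearest-neighbour repeat
followed by a convolution, avoiding transposed-convolution artifacts.  The
discriminator is unconditional (it sees only Y or Ỹ).

Two normalization conventions are fixed and documented because the loss
definitions leave them open: expectations are realized as means over batch
and elements; the feature-matching norm sums absolute differences over all
elements of a map and divides by its channel count F_i.  Under that
convention a feature-matching weight of 10 makes the term ~25× the L1 term
while being largely scale-blind (features pass through instance
normalization); desk-scale experiments showed it stalls amplitude recovery,
so the package default is λ3 = 1.

The *hinge* losses and Eq-style composite above are the only adversarial
objectives implemented; a cross-entropy GAN loss is not provided because the
method replaces it with the hinge loss.

## Losses as testable functions

Every loss is a standalone function over arrays (or autodiff tensors, for
training) and is verified against independent oracles: the KL term against
numerically integrated Gaussian KL, the hinge/L1/feature-matching terms
against explicit Python loops, with exact closed-form spot values
(KL(N(0,I)‖N(0,I)) = 0; hinge-D at zero scores = 2).

## Mapping metrics

Per sensor trace: MSE = (1/L)Σ(y−ỹ)², cosine similarity with square-rooted
norms in the denominator (the stated range [−1, 1] requires them), and
Pearson correlation with the population (1/L) convention (the convention
cancels).  Aggregation order is sensors → segments → subjects; "Mean" rows of
exported tables are recomputed from the table's own column values with
half-away-from-zero rounding.  A per-time-sample ordinary least squares map
(scalp vector + intercept → each intracranial sensor) is included as a
sanity baseline, falling back to the minimum-norm solution when
rank-deficient.

## IED classifier and protocols

The detector is a compact convolutional network in the EEGNet family —
temporal convolution (8 filters, kernel 17), depthwise spatial convolution
across all sensors (depth multiplier 2), separable convolution (depthwise
kernel 9 + pointwise), dense sigmoid head — with two deliberate structural
changes: **no normalization layers** and **max pooling** (4×, twice) instead
of average pooling.  Dropout 0.25, Adam lr 1e-3, binary cross entropy; when
a validation split is available the epoch with the best validation accuracy
is kept.

Intra-subject protocol: stratified seeded 70/10/20 train/validation/test
split of one subject's segments; the classifier is trained on *estimated*
iEEG (the subject's scalp segments translated with the deterministic
mean-latent mode), mirroring deployment where only scEEG exists.
Inter-subject protocol: subjects whose intra-subject accuracy is strictly
above 70% form the ensemble; a held-out subject's scalp data is mapped
through each selected subject's translation model, scored by that subject's
classifier, and the N probability vectors are averaged (average voting) with
≥ 0.5 classified as IED.  The decision threshold and tie rule are package
choices.

## Synthetic cohort

The clinical recordings are not public, so the generator emulates their
structure; the published per-subject summary tables (IED counts,
scalp-visible rates, mapping and accuracy aggregates) ship in
`eegtranslate.reported` as calibration references.

- **IED morphology**: a biphasic spike (sharp lobe + shallower rebound,
  width ~40–70 ms) whose peak magnitude equals `spike_amplitude`
  (0.55–0.65 on the normalized scale), followed from the end of the lobe by
  a damped oscillation a·e^{−t/τ}·sin(2πft) with a = 0.5·amplitude,
  f = 6–10 Hz, τ = 60–100 ms.  Parameters are visually plausible choices, not
  measured clinical values, and are exposed in `IedTemplate`.  The onset sits
  at sample 32 of the 64-sample window.
- **Background**: AR(1)-filtered white noise (pole 0.9, a 1/f-like spectrum)
  with a 15% shared component for channel correlation, RMS 0.06.
- **Forward model**: scalp = attenuation · F(Y_source · mixingᵀ) + noise.
  The mixing matrix is a smooth nonnegative spatial falloff between evenly
  spread sensor positions, rows normalized to unit L1 norm; F is the identity
  or a tanh saturation.  Each IED's discharge reaches the scalp with an extra
  log-normal gain (σ = 0.9, median 1), modeling source-depth heterogeneity.
- **Noise floor**: fixed per subject at the level that realizes the
  configured SNR against the *unattenuated* clean projection.  Consequently
  the realized scalp SNR equals `snr_db` at attenuation 1, and lowering the
  attenuation sinks the signal into a constant sensor-noise floor — which is
  what makes attenuation a monotone lever for scalp visibility.
- **Visibility**: the clinical visible/invisible annotation was a
  neurologist's reading, which cannot be simulated; the stated proxy is a
  fixed detector that flags an IED as scalp-visible when some sensor's peak
  amplitude in the onset window exceeds 5× that sensor's off-window RMS.
  The median attenuation is calibrated by log-space bisection on ~600 probe
  IED segments so the detector reproduces a target visible fraction (default
  18.8%, the reference cohort's mean).
- Non-IED segments are pure background; labels are balanced exactly.

Everything is a pure function of (config, forward model, templates, seed).

What the generator does *not* emulate: biophysical lead fields, artifacts,
non-stationary background, ictal activity, variable IED onset latency within
the window, or inter-subject morphology families.  Passing tests on this
cohort therefore demonstrate that the implementation learns and evaluates
the mapping it was built for under its stated assumptions — not clinical
performance on real recordings.

## Desk-scale study sizes

The numerical backend is a compact numpy autodiff engine, so problem sizes
are chosen for minutes-scale single-CPU runs (`eegtranslate.demo`): the
*recovery* study uses 8 scalp / 4 intracranial sensors, 96 segments per
subject at 15 dB SNR with unit attenuation and homogeneous propagation,
reduced widths (Z = 16, C_e = 4, I_up = 2, LSTM 16), 30 epochs, batch 8,
generator lr 2e-3 / discriminator lr 1e-3.  Under this recipe training
reduces the training-set L1 by well over half from its initialization value
and held-out PCORR reaches ~0.8–0.9, clearly separating the full model from
both an untrained model and the convolution-only (no-SPADE-ResNet) ablation.
Full-geometry configurations are exercised for shape/contract correctness
rather than trained to convergence.

Two desk-scale cohorts serve different questions.  The *easy* cohort
(high SNR, unit attenuation, homogeneous propagation) makes the mapping
learnable quickly and is used for the recovery and ablation comparisons; on
it the raw scalp is nearly as informative as the translation output, so it
says nothing about the method's motivation.  The *degraded* cohort (5 dB
scalp SNR, median attenuation 0.35 with log-normal per-IED spread) emulates
the clinical situation where most discharges are buried at the scalp; there,
a detector trained on translated segments consistently outperforms one
trained on the raw scalp segments — the directional analogue of the method's
premise, and the comparison the package reports.

## Numerical choices, degenerate inputs, limitations

- float64 throughout; forward passes and training trajectories are
  bit-deterministic functions of their seeds (pure numpy, single-threaded
  semantics).
- Instance/sensor normalization epsilon 1e-5; Adam epsilon 1e-8; classifier
  probabilities clipped to (1e-7, 1−1e-7) inside the cross entropy.
- Zero-norm or zero-variance traces make cosine similarity / Pearson
  correlation undefined; the functions raise instead of returning 0.
  Single-class ground truth yields NaN for the undefined metric (SEN or SPC,
  and AUC) rather than a silent value.
- Non-finite losses or numerically collapsed posteriors abort training with
  the epoch/batch context (`TrainingDivergedError`).
- The ±1 amplitude clip guarantees stored segments satisfy the normalized
  range; the exact linear-oracle identity (scalp = attenuation·Y·mixingᵀ)
  holds when the projection stays inside the clip range and per-segment gain
  spread is disabled.
- Known limitations: no multi-scale discriminator or spectral normalization;
  no artifact rejection (inputs are assumed artifact-free); EDF import only,
  without resampling of mixed-rate files; the published per-subject accuracy
  tables are not reproducible numerically because the original architecture
  depths and training hyperparameters are unpublished and the recordings are
  private — only the printed-table aggregates and the directional/structural
  properties above are verified.
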