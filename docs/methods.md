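# Methods

## Model

`varcnn` classifies Alzheimer's disease (AD) versus normal controls (NC) from
T1-weighted structural MRI by fusing two feature streams:

1. **Deep semantic features.** An 80×100×80 patch enclosing both hippocampi is
   cropped from the template-registered volume and passed through a 3-D CNN of
   five blocks (Conv3d 3³/stride 1 → BatchNorm3d → ReLU → ceil-mode max-pool
   /2), widths 8→16→32→64→128, producing 128 feature maps of size (3, 4, 3).
   The flattened vector h (4608 values) feeds two dense maps: μ = f_m(h) and
   log σ² = f_s(h). During training the bottleneck features are sampled with
   the reparameterization trick, Z = ε ⊙ σ + μ with ε ~ N(0, 1), keeping the
   sampling step differentiable. At inference Z = μ, so evaluation is
   deterministic (sampled inference is available behind a flag).
2. **Morphological metrics.** A per-subject vector of tissue volumes
   (gray matter, white matter, CSF — computed upstream by a VBM pipeline and
   consumed here as a numeric table), z-scored with training-split statistics.

The concatenation [Z ‖ morph] enters an MLP (hidden layers 64, 32, ReLU,
softmax). The loss is

    l = l_ce + α · l_kl,

where l_ce is mean cross-entropy and l_kl = ½ Σ_j (μ_j² + σ_j² − 1 − log σ_j²)
is the closed-form KL divergence of each diagonal-Gaussian latent against the
N(0, 1) prior, averaged over the batch (the mean keeps α's meaning independent
of batch size). α trades classification fit against latent compression: large
α collapses redundant latent dimensions onto the prior so only genuinely
discriminative features keep non-trivial means.

**Receptive-field arithmetic.** For a flattened layer stack, the input span of
one output unit follows l_k = l_{k−1} + (f_k − 1)·Π_{i<k} s_i with l_0 = 1.
Applied to the five-stage pooling (downsampling) stack alone — five kernel-2 /
stride-2 layers — this gives 32, i.e. each output voxel of the downsampling
chain summarises a 32³ input region; including the 3³ convolutions the full
stack reaches 94. The calculator accepts any (kernel, stride) list so both
readings are computable.

**Shape conventions.** Convolutions preserve extent (stride 1, pad (k−1)/2).
Pooling is ceil-mode: odd extents are padded on the high side so the output
extent is ⌈extent/2⌉. This is the only convention that maps 80→3 and 100→4 in
five halvings, which fixes both choices. Flattening is channel-major:
element (c, z, y, x) lands at ((c·D + z)·H + y)·W + x.

## Training protocol

Adam (β₁ 0.9, β₂ 0.999), base learning rate 5·10⁻⁴, batch 32, 120 epochs.
The rate ramps linearly from 0 over the first two epochs (per optimizer step),
plateaus, and is divided by 5 every 40 epochs (i.e. at epochs 40 and 80).
Splits are stratified by label with floor-rounding per class (80/20 by
default); class imbalance is handled by weighted sampling with replacement at
inverse class frequency, so the expected drawn ratio is 1:1. Every source of
randomness — weight init, oversampling draws, reparameterization noise —
derives from the single run seed, making runs bitwise reproducible; repeated
cross-validation re-runs the whole protocol over a seed list and reports
mean ± SD per metric.

**Weight decay.** All convolution and dense weights (not biases or batch-norm
parameters) carry an L2 penalty added to the Adam gradient, default λ = 0.05.
The paper-scale protocol is silent on regularization; a ridge penalty is
standard for fusion models trained on a few hundred subjects, and it is also
the mechanism that makes the first-layer MLP weights of *uninformative* latent
inputs actually converge to zero: once a strong KL constraint reduces a latent
dimension to prior noise, the cross-entropy gradient through its weight has
zero mean and the decay term dominates, shrinking the weight at a rate of
roughly lr·λ·|w|/rms(g) per step. The weight-sparsification diagnostic
(fraction of first-layer latent profiles with max-|w| below 0.05) therefore
needs a step budget at least of order |w₀|·rms(g)/(lr·λ) to express the
effect; the shipped experiment schedules respect that bound.

**Numerical choices.** Engine precision is float32 (batch-norm moments
accumulated in float64). Cross-entropy floors probabilities at 10⁻¹² inside
the log. The KL closed form is clamped at 0 against float round-off near the
prior. Score ties at the decision threshold predict positive, fixing confusion
counts bit-reproducibly; AUC is the Mann-Whitney rank statistic with ties
counted ½, exact under ties. Divergent (non-finite) losses abort with a
diagnostic rather than continuing.

The neural-network engine itself (3-D convolution via per-kernel-offset GEMMs,
batch normalisation, ceil-mode pooling, dense layers, Adam) is implemented in
NumPy with hand-derived gradients; every gradient is verified against central
finite differences in the test-suite at float64.

## Synthetic phantoms

Gated cohort data cannot ship with the package, so a phantom generator
reproduces the statistical structure the method assumes:

- background Gaussian noise (SD 0.5) on the patch grid;
- a handful (default 6) of class-independent bright ellipsoids at random
  positions — redundant structure the network must learn to ignore;
- two bilateral "hippocampus" ellipsoids (semi-axes r, 1.25r, 0.8r; default
  r = 8 voxels at the 80×100×80 default shape) whose radius shrinks by the
  atrophy fraction (default 0.3) in the AD class — the localized volumetric
  class signal;
- morphological vectors drawn N(label·effect, 1), default effect
  (−1.5, −0.8, +1.2) SD for (GM, WM, CSF): gray matter down, CSF up, the
  direction seen in real atrophy.

Each sample draws from its own seed substream keyed by (seed, label, index),
so cohorts are bitwise reproducible and order-independent. The phantoms model
*none* of: scanner physics, bias fields, anatomy, multi-site effects. Passing
tests therefore demonstrate that the implementation recovers planted signals
of the assumed form — not clinical performance on real MRI.

## Scaled study conditions used by the test-suite

The shipped experiments are sized for a single CPU:

- architecture widths (2, 4, 8, 8, 16) instead of (8, …, 128); latent J = 16;
- the KL-ordering experiment: 200 phantoms at 32×40×32 (signal radius 4),
  30 epochs;
- signal-recovery, chance-level, and weight-sparsification experiments:
  200 phantoms at 16×20×16 (signal radius 2), 60 epochs — the longer schedule
  satisfies the decay time-constant bound above;
- batch 8 with base rate 3·10⁻³, chosen so total optimizer travel
  (steps × lr) at a few hundred steps matches the full-scale 120-epoch
  protocol.

Stochastic checks use fixed seed lists and majority or mean criteria as
stated in each test.

## Known limitations

- Stride-1 convolutions and kernel = stride pooling only — exactly what the
  architecture needs; other configurations raise explicitly.
- No decoder: the bottleneck is an encoder-only regularizer, not a generative
  model.
- The default crop corner (50, 52, 16) for the MNI152 181×217×181 grid is a
  shipped config value, not an anatomical ground truth; studies should verify
  hippocampal coverage for their registration.
- Baseline comparators (SVM, random forest, gradient boosting) are out of
  scope; the J = 0 degenerate path provides the metrics-only MLP baseline.
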