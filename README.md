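# varcnn

**Variational-bottleneck 3D CNN for AD/NC discrimination from structural MRI.**

`varcnn` is a tool for researchers classifying Alzheimer's disease (AD) versus
normal controls (NC) from T1-weighted structural MRI. Deep CNN features from
an MRI patch are highly redundant and correlated; this package implements a
reparameterized bottleneck that compresses them before classification. A
hippocampal patch (default 80×100×80 voxels on the MNI152 grid) passes through
a five-block 3-D CNN (Conv3d → BatchNorm3d → ReLU → ceil-mode max-pool),
yielding 128 feature maps of size (3, 4, 3). The flattened features h map to a
latent Gaussian via two dense layers, μ = f_m(h) and σ = exp(f_s(h)/2), and the
bottleneck features are sampled with the reparameterization trick

    Z = ε ⊙ σ + μ,   ε ~ N(0, 1).

Z is concatenated with per-subject morphological metrics (gray-matter,
white-matter, CSF volumes) and classified by an MLP. Training minimises

    l = l_ce + α · l_kl,   l_kl = ½ Σ_j (μ_j² + σ_j² − 1 − log σ_j²),

so the KL term pulls each latent dimension toward N(0, 1): with a
well-chosen α, redundant dimensions collapse onto the prior and only the most
discriminative features keep informative means. Performance is reported as
ACC / SE / SP and rank-statistic AUC over seeded, stratified 80/20
cross-validation with inverse-frequency oversampling.

Real AD cohorts are access-gated, so the package ships a phantom generator
that plants the signal structure the method assumes — a localized
volume-reduced ("atrophic") bilateral signal plus redundant blobs in noise,
and class-shifted morphological vectors — making every stage testable offline.

## Worked example

Simulate a small phantom cohort, train, and evaluate (about two minutes on one
CPU):

```yaml
# example.yaml
simulate:
  shape: [32, 40, 32]
  n_per_class: 40
  signal_radius_nc: 4.0
  seed: 0
model:
  channels: [2, 4, 8, 8, 16]
  latent_dim: 8
train:
  lr_base: 0.003
  batch_size: 8
  epochs: 12
```

```text
$ varcnn simulate --config example.yaml --out cohort
wrote 80 volumes + cohort/cohort.csv

$ varcnn train --config example.yaml --data-dir cohort/images \
               --table cohort/cohort.csv --out run --seed 0
final epoch: acc=0.938 auc=1.000 kl=0.0387

$ varcnn eval --checkpoint run/checkpoint.npz --data-dir cohort/images \
              --table cohort/cohort.csv
{
  "tp": 36, "tn": 37, "fp": 3, "fn": 4,
  "acc": 0.9125, "se": 0.9, "sp": 0.925,
  "auc": 0.988125, "precision": 0.9230769230769231
}
```

The train line reports the held-out 20% split at the final epoch: accuracy
0.938, AUC 1.000 (16 validation phantoms), and a validation KL of 0.039 —
at the default α = 10 the latent distributions sit close to the N(0, 1)
prior. The eval command rescores the full 80-phantom cohort with the saved
checkpoint: 36 of 40 AD phantoms and 37 of 40 NC phantoms are correctly
classified (sensitivity 0.90, specificity 0.925); AUC 0.988 is the
probability a random AD phantom outscores a random NC phantom. Expect
near-perfect numbers here: the planted class signal (atrophy fraction 0.3
plus morphological shift) is strong, and train and eval cohorts overlap.

The receptive-field calculator prints the size recursion for any layer stack;
for the backbone's five-stage downsampling chain each output voxel summarises
a 32×32×32 input region:

```text
$ varcnn rf --pooling-only
layer kernel stride    rf
    1      2      2     2
    2      2      2     4
    3      2      2     8
    4      2      2    16
    5      2      2    32
final receptive field: 32 voxels per axis
```

Other commands: `varcnn grid` produces a mean ± SD AUC matrix over an
(α, latent-dimension) grid, one seeded cross-validation per cell.

Real data enter through the same interface: one registered NIfTI volume per
subject (`<subject_id>.nii.gz`) plus a CSV with `subject_id`, `label`
(0/NC, 1/AD) and metric columns. Intensities are z-scored per volume and
clipped to [−1, 2.5]; the hippocampal crop corner ships in the default config.

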