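# Methods

## Model

The generator is image-conditioned: augmentation starts from a real image,
not from pure noise. An encoder (four conv stages, stride-2 downsampling to
8x8) produces a 100-dimensional latent code, split 50/50 into a *global* and
a *local* stream. Independent Gaussian perturbations (`sigma_global`,
`sigma_local`) are added per stream; the perturbed code is decoded by two
paths whose pre-activation outputs add, and a sigmoid bounds the sum to
[0, 1]:

* the **global reconstruction path** renders from the global stream at 8x8
  and upsamples x8 through fixed binomial-blur stages. Its contribution is
  therefore band-limited to the lowest one-eighth of spatial frequencies by
  construction, which is what makes "global stream = global structure" a
  testable property rather than a hope: perturbing only the global stream
  provably concentrates image change at low frequencies.
* the **local refinement path** decodes the local stream through nearest-
  neighbor upsampling with encoder skip connections at every scale, carrying
  fine detail. Decoder output biases are initialized at the logit of typical
  tissue brightness (-1.4) so early training refines structure rather than a
  global brightness shift.

A projection head (two affine layers with a leaky-ReLU, output dimension 32)
maps latent codes to the embeddings used by the contrastive latent
projection (CLP) loss.

Three critics act in parallel. `D1` is a softmax classifier over the four
tumor classes applied to real and generated images; its penultimate
64-dimensional feature layer uses a *flattened* (not pooled) convolutional
map, because lesion position — not just presence — separates the classes,
and global average pooling destroys exactly that signal. `D2` is a local
patch critic (two stride-2 conv layers plus a 3x3 head): a 16x16 score grid
for 64x64 inputs, each score depending on an 18x18-pixel receptive field.
`D3` scores the DC-centered `log(1 + |F(x)|)` magnitude spectrum; the phase
is discarded by default, so its score is invariant to circular image shifts
(a config-visible choice — the magnitude carries the frequency statistics
the critic is meant to police).

## Objectives

With probability floors of 1e-12 inside every probability logarithm:

* `L_CLP`: temperature-scaled InfoNCE over cosine similarities; for each
  image the anchor and positive are the projections of two independent
  stream perturbations, negatives are the other images' second views in the
  batch. Evaluated exactly in shifted log-sum-exp form, so extreme
  temperatures (tau down to 0.05) neither overflow nor hit the floor.
* `L_cls`: cross-entropy of `D1` on real images (discriminator side) and on
  generated images (generator side, encouraging class-faithful variants).
* `L_D2`, `L_D3`: standard adversarial losses — minus-log on both the real
  and one-minus-fake terms for the critics (the only form bounded below and
  consistent with the minimax objective), and the non-saturating
  minus-log-fake form for the generator.
* Totals are lambda-weighted sums (`lambda_cls = lambda_adv = lambda_freq =
  lambda_clp = 1` by default) with side-appropriate adversarial terms; the
  generator additionally receives an L1 reconstruction anchor to the source
  image with weight 1.0. The CLP term involves only generator parameters, so
  it enters the discriminator-side report as a constant.

Each step runs one joint discriminator update (one optimizer over D1, D2 and
D3) followed by one generator update; Adam, lr 1e-4, beta1 0.5, beta2 0.999,
optional decoupled L2 weight decay (off by default).

## Parameters that matter

| parameter | default | why |
|---|---|---|
| latent dimension | 100 (50 global + 50 local) | total fixed by the protocol; the split is even absent other guidance |
| tau (CLP temperature) | 0.5 | mid-range InfoNCE temperature; exposed in config |
| sigma_global, sigma_local | 0.1 | encoder latents carry ~0.14 per-dimension between-image signal std; perturbations at ~70% of that keep variants semantically tied to their source, which is the stated purpose of the CLP design. Larger values (e.g. 0.5) overwrite image identity and turn "augmentation" into unrelated samples |
| reconstruction weight | 1.0 (L1) | fidelity anchor keeping variants near their source image; L1 preserves edges better than L2 |
| presets | `paper`: batch 64, 50 epochs; `desk`: batch 16, 5 epochs | the desk preset is the CPU-scale protocol used by the tests and the acceptance script |
| image size | 64x64 | power-of-two desk scale; any power of two >= 32 is supported |

## Phantom generator

`PhantomSpec` renders T1-contrast-enhanced-like axial slices: an elliptical
brain (semi-axes 0.42/0.36 of the image) with smooth Gaussian-filtered
texture (amplitude 0.08 around a 0.35 tissue base), a low-frequency cosine
bias field (amplitude 0.06), additive Gaussian noise (sigma 0.02), and a
class-dependent Gaussian-profile lesion: meningioma-analog at 0.78–0.90 of
the elliptical radius (radius 4–6 px), glioma-analog in the interior with a
Perlin-like low-frequency modulation of its boundary (radius 6–11 px),
pituitary-analog central and small (radius 2–3.2 px); lesions add up to 0.55
above tissue, emulating contrast enhancement. All lesion-free tissue stays
below a derivable threshold (base + texture + bias + 4 sigma of noise), so
lesions are detectable by thresholding — this is what the placement tests
exploit.

One integer seed drives everything; each dataset sample uses an independent
counter-derived substream, so sample `i` is identical whether it is drawn in
a dataset of 5 or 5000. A standardized-histogram nearest-centroid classifier
reaches ~0.65 accuracy on the four classes (chance 0.25), which guarantees
the augmentation-utility experiments have signal to move.

What the phantoms do **not** emulate: real anatomy (no atlas), 3-D
structure, multi-modal contrasts, partial-volume effects, scanner artifacts
beyond a smooth bias field, or inter-subject variability. Tests passing on
phantoms demonstrate that the machinery — losses, training dynamics,
augmentation plumbing, metrics — behaves correctly; they are not evidence of
image quality on clinical MRI.

## Evaluation

* **SSIM**: 11x11 Gaussian window (sigma 1.5), C1 = (0.01)^2, C2 = (0.03)^2
  at dynamic range 1, averaged over valid window positions; verified against
  an explicit sliding-window oracle and cross-checked against scikit-image.
* **PSNR**: `10 log10(1/MSE)`, capped at 100 dB for identical images.
* **FID-like**: Frechet distance on sample moments of pluggable features —
  by default the trained `D1` penultimate layer, with a fixed-seed untrained
  CNN as fallback. Without Inception weights these values are *not*
  comparable to published FID numbers; they are relative measures within
  this package. A ridge epsilon regularizes covariances when sets are small.
* **Latent separation**: mean distance between group centroids minus mean
  within-group spread, reported raw (no clipping), groups being the
  perturbed views of each source image. Positive separation means distinct
  images stay distinct while views of one image cluster — the anti-collapse
  property the CLP loss trains for. Grouping by *class* instead is reported
  by the tooling but not asserted: in-batch InfoNCE repels all distinct
  images including same-class ones, so nothing in the objective organizes
  class centroids.
* **Accuracy vs diversity level**: level `k` appends `k` generated variants
  per training image; a fresh `D1`-architecture classifier is trained per
  level with a *fixed budget of 400 uniformly-sampled batches* (batch 16,
  Adam lr 1e-3) rather than epochs. With an epoch budget, higher levels get
  more gradient steps and even duplicate augmentation inflates accuracy;
  with the fixed-step budget, duplicating the training set leaves the batch
  distribution unchanged, so the identity-generator control is exact in
  expectation and any gain must come from the generator.

## Numerical and reproducibility choices

Probability floor 1e-12 in probability logs; CLP in exact log-space; sigmoid
output bounding (differentiable) instead of hard clipping; PSNR cap 100 dB;
PNG quantization is fixed-point (x255, round half-up; read back as /255, so
write-read-write is byte-identical); NIfTI reads rescale per image to [0, 1].
The variance floor documented for the mode-collapse check is 1e-6 mean
per-pixel variance across five seeded variants. All model initializations and
stochastic operations derive from integer seeds via independent
`SeedSequence` substreams; identical config + seed reproduces training
histories to the bit on a fixed platform. Checkpoints are single `.npz`
archives with an embedded JSON config snapshot and a format-version string.

## Problem sizes

The test suite and acceptance script use 256 phantoms (desk preset: batch
16, 5 epochs, 75 optimizer steps) for GAN training, 200/160 train/test
phantoms for the diversity harness, and 3 seeds for every majority-vote
check — sizes chosen so the whole pipeline is comfortable on one CPU. These
are study sizes of this package, orders of magnitude below the full-scale
protocol the `paper` preset encodes (thousands of slices amplified x75, 50
epochs at batch 64); absolute metric values are correspondingly modest
(reconstruction SSIM ~0.3 after 75 optimizer steps), so only the *relative*
properties — improvement over training, augmentation gain over baseline,
separation above zero — are asserted.

## Known limitations

* Desk-scale training produces visibly imperfect reconstructions; the
  `paper` preset is shipped but takes correspondingly longer.
* The encoder is convolutional; a transformer encoder is a possible
  extension, not implemented.
* FID-like values are package-internal, not literature-comparable.
* No 3-D volumes, DICOM, multi-GPU, or mixed precision.
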