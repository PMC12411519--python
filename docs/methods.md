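# Methods

## Pipeline

The package implements an augment-then-classify design for multi-class
grayscale image classification. Five stages run in order, each seeded from
one global seed through fixed per-stage offsets so any stage can be rerun
independently and reproducibly:

1. **Data.** Images live in class-named PNG folders; a CSV manifest
   (`path,class_name,class_id,split`) records labels and split tags. The
   split is stratified per class with largest-remainder rounding (floors of
   the quotas, leftover units to the largest fractional remainders, ties to
   the earlier of train/val/test), so per-class counts match the requested
   fractions to within one sample. The default protocol is 80:10:10; a
   plain 80:20 split is a configuration away.
2. **Autoencoder.** Signed-unit images (resized, scaled to [-1, 1], one
   channel) pass through stride-2 convolution blocks (LeakyReLU 0.2) and a
   dense bottleneck to a latent z; the decoder mirrors with
   nearest-neighbour upsampling + 3x3 convolutions and a tanh output, so
   reconstructions are bounded. MSE loss, Adam at 1e-3, 15 epochs at
   reference scale. Nearest-up + conv was chosen over transposed
   convolution to avoid checkerboard artifacts and keep the adjoint simple.
3. **Conditional GAN.** The trained encoder is copied, its parameters
   flagged non-trainable, and fingerprinted (SHA-256 over names and bytes).
   The discriminator is `sigmoid(head([E(x); e(y)]))`: frozen-encoder
   features concatenated with a 32-dimensional label embedding into a
   2-layer head; the checksum is re-verified on every discriminator call
   and after training, so silent drift of the frozen weights is impossible.
   The encoder consumes the image alone; conditioning enters through the
   embedding path (the label cannot perturb the frozen features). The
   generator embeds the label, concatenates it with N(0, I) noise, projects
   to a 4x4 grid and upsamples to the working resolution with a tanh
   output. Both players minimize BCE with probabilities clamped to
   [1e-7, 1 - 1e-7] inside logarithms; the generator default is the
   non-saturating surrogate -E[log D] (same fixed point as the saturating
   E[log(1-D)], which is available behind a flag, but without its vanishing
   early gradient). Schedule: one discriminator step then one generator
   step per batch, Adam 1e-4 with betas (0.5, 0.999). No label smoothing or
   gradient penalty. Synthetic sampling writes exactly `per_class` images
   per class, labelled by their conditioning class, into the training split
   only — validation and test data never contain generated images.
4. **Classifier.** A hierarchical shifted-window attention backbone:
   4x4 patch embedding, stages of transformer blocks whose self-attention
   is restricted to non-overlapping square windows with learnable relative
   position bias, a cyclic half-window shift on every second block, and
   patch merging (2x2 concat -> linear) halving resolution and doubling
   width between stages; mean-pooled features feed one linear head. The
   shifted blocks use the cyclic shift without the border attention mask —
   a deliberate simplification for the small from-scratch setting; windows
   still exchange information across borders, at the cost of attention
   between wrapped-around pixels. Variants: `scratch-small` (window 4,
   embed 64, depths (2,2), heads (2,4); 64 px default, 32 px in the desk
   profile) and `pretrained-tiny` (window 7, embed 96, depths (2,2,6,2),
   heads (3,6,12,24), 224 px). The tiny variant enforces its patch-grid
   contract but starts from random initialization: no pretrained weights
   ship with the package. Inputs go through the standardized chain (resize,
   replicate grayscale to 3 channels, subtract per-channel mean
   (0.485, 0.456, 0.406), divide by sd (0.229, 0.224, 0.225)). Training:
   cross-entropy, AdamW (lr 3e-5 reference / 5e-4 desk-from-scratch,
   decoupled weight decay 0.01), cosine-annealed to ~0 over the run, one
   scheduler step per epoch; the best-validation-accuracy parameters are
   kept and restored.
5. **Evaluation.** Confusion counting, ROC curve construction and
   stratified fold indexing are delegated to scikit-learn; the percent
   arithmetic is defined here. Precision_c = TP/(TP+FP), recall_c =
   TP/(TP+FN), F1 their harmonic mean, all on the percent scale; a 0/0
   yields 0 with an explicit flag (real runs never hit it). Macro averages
   are unweighted class means; weighted averages use supports. One-vs-rest
   ROC uses each class's probability column with trapezoidal AUC over the
   full threshold sweep (equal to the Mann-Whitney pair statistic, which
   the tests brute-force); the micro average pools all class-membership
   decisions. Cross-validation fixes the 10% test split once and
   re-divides the remaining pool into k stratified folds, so test accuracy
   is comparable across folds; fold summaries report the mean and the
   *population* standard deviation (divisor k). Rounding for display is
   decimal half-up at 1 or 2 decimals; raw values are kept internally and
   tests compare raw values.

## The numerical engine

All three models run on `mriaug.nn`, a purpose-built reverse-mode autodiff
engine on NumPy: tensors record the operations applied to them and
back-propagate exact gradients; convolution is im2col by strided view with
an offset-loop col2im adjoint; Adam/AdamW and cosine annealing are
implemented directly. The engine's analytic gradients are verified against
central finite differences for every composite the models use (convolution
chains, layer norm, windowed attention with shift, embeddings). Float32 is
the working precision; training at these scales is bitwise reproducible
for a fixed seed on a given platform, which the end-to-end rerun test
exercises.

## Phantom generator

Phantoms emulate the *structure* of brain-MRI classification data, not its
physics. Each image is an elliptical brain mask (semi-axes 0.42/0.46 of
the side) whose background intensity is drawn per image from [0.32, 0.38]
(mild acquisition jitter), plus, for tumour classes, one elliptical lesion
with class-specific sampling intervals:

| class      | center box (x, y)           | radius    | eccentricity | intensity |
|------------|-----------------------------|-----------|--------------|-----------|
| notumor    | — (no lesion)               | —         | —            | —         |
| glioma     | [0.28, 0.42] x [0.32, 0.48] | 0.10–0.16 | 0.3–0.6      | 0.75–0.90 |
| meningioma | [0.56, 0.70] x [0.28, 0.44] | 0.07–0.12 | 0.0–0.3      | 0.85–1.00 |
| pituitary  | [0.44, 0.56] x [0.56, 0.68] | 0.05–0.09 | 0.0–0.2      | 0.60–0.75 |

plus Gaussian texture noise (sd 0.02) inside the mask, clipped to [0, 1].
All lengths are unit fractions of the image side; coordinates are
row-major with origin top-left. The classes differ in location, size,
shape and brightness simultaneously, which makes them learnable by a small
model yet non-trivial (a pixel-mean rule beats chance but is far from
perfect). A three-class registry without the healthy class reproduces the
shape of tumour-only datasets. What phantoms do **not** model: anatomy,
acquisition physics, multi-slice geometry, scanner variability, or
inter-class visual ambiguity of real tumours — so passing pipeline tests
demonstrates the machinery (training dynamics, conditioning, freezing,
determinism, metric arithmetic), not clinical performance.

`generate_phantom` is a pure function of (spec, class id, seed);
`sample_phantom_params` exposes the exact sampled geometry so tests can
recompute quantities (e.g. lesion pixel area vs the analytic ellipse area)
independently of the renderer.

## Problem sizes

The `paper` preset carries the reference recipe (15/100/30 epochs, 500
synthetic images per class, 80:10:10, 3 folds, 64 px AE/GAN resolution,
224 px tiny classifier). The `desk` profile is the package's own
CPU-scale choice used by the test suite and the acceptance script: 4
classes x 200 phantoms at 32 px, autoencoder 5 epochs (latent 64, widths
16/32/64), cGAN 30 epochs (noise 64, base width 64), 50 synthetic images
per class, scratch-small classifier at 32 px for 10 epochs at lr 5e-4.
Under this profile the full pipeline reaches >=90% held-out accuracy and
reruns byte-identically.

## Design choices and limitations

- The conditioning path into the discriminator (embed + concatenate before
  the head) keeps the encoder a function of the image alone; an
  alternative would re-train a joint image-label feature path, which would
  defeat the purpose of freezing.
- In the ablation row without the autoencoder, the discriminator uses the
  same encoder architecture trained jointly from random init, so the
  comparison isolates the effect of reconstruction pre-training.
- Argmax ties in prediction break toward the lower class id; class order
  is fixed by the registry so confusion matrices are comparable.
- The GAN has no mode-collapse diagnostics or image-quality scores; the
  tests check conditioning behaviourally (a probe classifier trained on
  real phantoms recognizes generated classes above chance) rather than
  perceptually.
- Pretrained-weight loading for the tiny variant, DICOM/NIfTI input and
  multi-slice volumes are out of scope.
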