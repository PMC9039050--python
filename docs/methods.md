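# Methods

This note documents the models and procedures implemented in
`toothmark`, the choices that were genuinely open, and what the
synthetic experiments do and do not establish.

## Problem

A tooth-marked tongue shows serrated indentations and/or darker
compression patches along its lateral edges; recognising it matters for
tongue diagnosis in traditional Chinese medicine. Clinically one only
obtains *image-level* labels (tooth-marked / not) — drawing boxes around
individual marks is costly and subjective. The package therefore treats
the task as weakly supervised object detection: train a classifier from
image-level labels alone, and make the location of the evidence a
by-product of the architecture.

## Pipeline

1. **Preprocessing** (`toothmark.preprocess`). The tongue region is
   delineated (binary mask or Labelme-style polygon), AND-ed with the
   photograph so everything outside the tongue is exactly zero, and
   resized to 224 x 224 (bilinear, aspect ratio not preserved — the
   network input is a fixed square and the scan that follows only uses
   the nonzero support). Training-time augmentation: random horizontal
   and vertical flips (p = 0.5 each) and a rotation drawn uniformly from
   [0°, 15°], with black fill; the mask is transformed identically and
   re-applied, preserving the exact-zero background. Augmentation happens
   *before* region proposal each epoch, so proposals track the augmented
   geometry.

2. **Spatial region proposal** (`toothmark.srp`). Tooth marks lie on the
   lateral contours, so candidates are anchored there directly: on the
   masked grayscale image, starting at the first foreground row, every
   21st row (⌊2/3 · 32⌋) is visited; the first nonzero pixel scanning
   inward from the left (resp. right) edge, up to half the image width,
   anchors a 32 x 32 box centred on it (clipped, not shifted, at the
   borders). The first and last box on each side are dropped (tongue tip
   and base are uninformative). Typical tongues yield R ≈ 10–16 boxes.

   One convention required care: with an even box size, a single
   horizontal offset of ⌊s/2⌋ for both sides cannot commute with
   horizontal mirroring at pixel resolution. The left side uses
   ⌊s/2⌋ and the right side the mirror-complement s − 1 − ⌊s/2⌋, so a
   horizontally flipped mask produces the exactly mirrored region set
   (for odd s the offsets coincide).

3. **Two-stream scoring network** (`toothmark.model`). A CNN backbone
   with overall stride 32 maps the input to a 7 x 7 x C_f feature map.
   Each candidate box is mapped to its feature-grid cells
   (⌊·/32⌋ / ⌈·/32⌉, so a 32-px box covers 1x1 to 2x2 cells), max-pooled
   by a {1x1, 2x2} spatial pyramid into a fixed 5·C_f vector, and
   embedded by two FC + ReLU layers (default width 4096) shared by both
   heads. Two linear heads produce C x R logit matrices:
   σ_class softmax-normalises over classes within each region
   (columns sum to 1), σ_det over regions within each class (rows sum
   to 1). The image-level score is

       y_c = Σ_r [σ_class ⊙ σ_det]_{c,r} ∈ (0, 1),

   trained with per-class binary cross-entropy against the one-hot
   image label (y is not a simplex, so a softmax cross-entropy over y
   would be the wrong likelihood). At inference the image class is
   argmax_c y_c (ties to the negative class), and for images predicted
   tooth-marked, the regions with σ_det[tooth-mark, r] > 1/R are emitted
   as predicted mark boxes with their scores.

4. **Two-phase training** (`toothmark.training`, `toothmark.estimators`).
   Phase one trains the backbone as a plain image classifier (global
   average pooling + linear softmax head). Phase two builds the
   two-stream detector from one of three initialisations — generic-image
   weights (IW), tongue-classifier weights from random init (TL), or
   tongue-classifier weights that themselves started from generic-image
   weights (IW+TL, the proposed configuration) — and fine-tunes end to
   end with Adam. "Generic-image weights" are produced by pretraining on
   a synthetic two-class shape task (disks vs squares), so the package
   never requires a download; they play the role of
   large-corpus initialisation at desk scale.

## Numerical and design choices

* **NN core.** All layers (strided convolution via im2col,
  batch normalisation, ReLU, max/average pooling, linear, dropout) are
  implemented in numpy (float32) with explicit backpropagation and an
  Adam optimiser; gradients are verified against finite differences in
  the test suite. Two backbones satisfy the stride-32 contract: a full
  34-layer residual network (truncated before pooling; 512 channels),
  and `tiny_test`, a four-layer strided CNN used for all CPU-scale
  experiments.
* **`tiny_test` receptive field.** The tiny backbone's receptive field
  is kept at 37 px — about one candidate box — so a feature cell
  describes its own neighbourhood. With a much larger receptive field
  every cell of a small, easily separable image encodes the image label
  itself, and region scores stop depending on the region.
* **Dropout on the region embeddings** (p = 0.5 after each FC layer, as
  is standard for this family of two-stream detection heads). Without
  it the region softmax σ_det collapses to a near-one-hot distribution
  in the first few epochs, freezing the gradient flow to all other
  regions; the stochasticity keeps σ_det diffuse long enough for the
  classification stream to learn region-level discrimination first.
* **Early stopping** halts when validation *accuracy* has not improved
  for `patience` epochs and restores the best weights; ties in accuracy
  are broken toward lower validation loss, so continued improvement of
  the detection stream is kept after accuracy saturates (common at desk
  scale where held-out accuracy reaches 1.0 quickly). The returned
  weights never come from an epoch with sub-best validation accuracy.
* **Division-by-zero metrics.** Precision/recall/F1 with empty
  denominators are reported as 0 and flagged `undefined`, keeping
  aggregation total. Spread across folds is reported as the standard
  deviation (ddof = 0).
* **Box conventions.** 0-based (x = column, y = row), half-open
  [x, x+w) x [y, y+h) everywhere. Mask rasterization counts any value
  > 0 as foreground.

## Study defaults vs desk-scale protocol

The optimisation defaults mirror the study protocol: Adam, learning
rate 1e-4, weight decay 1e-4, batch size 32, early-stop patience 10,
4-fold cross-validation repeated 5 times, 130:200 class balance.

The reference clinical corpus is not deposited, so all experiments run
on the synthetic benchmark (`toothmark.protocols`): 65 + 100 training
and 13 + 20 held-out tongues (half the clinical cohort, same 13:20
balance), `tiny_test` backbone with 32 feature channels, region
embedding width 256, learning rates 3e-3 (pretrain) / 1e-3 (fine-tune),
batch size 8, and a fixed epoch budget with early stopping disabled
(patience = budget). These are scaled-down study conditions chosen once
for CPU-class hardware: the small model needs a larger step size and a
smaller batch than the full-size network, and at this scale validation
accuracy saturates so quickly that an accuracy-patience stop would end
training long before the detection stream finishes organising.

Protocols that repeat many full trainings use further-reduced budgets
(`toothmark.protocols.ABLATION_PROTOCOL`: 40 + 60 training and 10 + 16
held-out tongues, pretraining 80 epochs, fine-tuning 30). The longer
pretraining budget there is deliberate: the from-scratch initialisation
arm of the ablation must itself train to convergence, otherwise the
comparison measures optimisation budget rather than initialisation
quality.

## Synthetic data: what it does and does not show

`toothmark.synthetic` draws an elliptical "tongue" (semi-axes 26–34% /
34–42% of the image, pink base colour with per-image jitter, additive
Gaussian noise σ = 4 on the foreground only) on an exactly-zero
background. A planted tooth mark is a semicircular notch carved from
the boundary and/or a darker elliptical patch just inside it
(radius 8–20 px, RGB shift (−70, −45, −45)), placed on the lateral arcs
(within 60° of horizontal) — where real tooth marks occur, and clear of
the tip/base regions the proposer trims. Positives carry 1–6 marks and
a tight ground-truth box per mark; negatives are smooth convex
ellipses.

This emulates the two clinical signs (contour serration, compression
discolouration) and the geometry that makes the edge-anchored proposer
sensible. It does not emulate papillae/coating texture, specular
lighting, camera variation, inter-rater label noise, or the ambiguous
"suspicious" cases that make the clinical task hard. Passing the
synthetic experiments therefore establishes that the implementation is
correct and that the weak-supervision mechanism can classify and
localise when the signal is present — not that clinical-grade accuracy
transfers.

Ground-truth boxes exist only synthetically; localization is scored as
the fraction of emitted boxes overlapping a planted mark at IoU ≥ 0.3
(and the recall of planted marks), computed on correctly-predicted
tooth-marked held-out images. Note the geometric ceiling: a 32-px
candidate box and a small mark's tight box can have IoU below 0.3 even
when perfectly centred, so mark-level recall is bounded well below 1 by
construction.

## Known limitations

* Trained at desk scale on synthetic data; no clinical validation here.
* The proposer assumes an exactly-zero background and roughly vertical
  tongue orientation (rows are stepped in image coordinates, not arc
  length).
* Localization is coarse: one box size, no non-maximum suppression, no
  spatial regularisation; the detection stream typically commits to one
  or two boxes per image even when several marks are present.
* The residual-network backbone is implemented and shape-verified but
  impractical to train in this CPU-only numpy stack; transfer from
  published generic-image weights is supported in principle via the
  named-state loader but not exercised.
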