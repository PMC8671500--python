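# Methods

This note documents the models, parameters, numerical choices and known
limitations of the `advcad` pipeline: a safety evaluation of a deep-learning
computer-aided-diagnosis (CAD) classifier for mammography under adversarial
images produced by GAN generators, exercised end to end on synthetic phantom
mammograms.

## The study in one paragraph

A binary classifier ("AI-CAD") is trained to distinguish lesion-bearing
(positive) from lesion-free (negative) 16-bit grayscale images. Two
image-to-image GAN generators are then trained: one removes lesion tissue
from positives (negative-looking fakes), one inserts lesion-like tissue into
negatives (positive-looking fakes). Each fake carries the *flipped* label.
The attack evaluation asks: among real test images the classifier got right,
how often is the label-flipped counterfeit classified as its flipped label
(the *fool rate*)? A separate statistics module scores human-reader response
tables (real / fake / unsure verdicts over reading sessions) into accuracy
breakdowns and session comparisons.

## Phantom cohort

No clinical data is used. The generator fabricates a cohort with the
structure of a screening population:

- **Patients.** Default 100 patients, 28.5% positive (matching a 366/1284
  case mix); positives contribute only the two views (CC, MLO) of the
  affected breast, negatives contribute both breasts (up to 4 images).
  The train/val/test split is at patient level, 80/10/10, stratified by
  class, floor-rounded with the remainder assigned to train.
- **Background.** Multi-scale correlated Gaussian noise (three octaves
  around a 6 px correlation length; mean 22000, SD 3000 counts) inside an
  elliptical breast mask on a zero background. This emulates fibroglandular
  texture: smooth structure the GAN can plausibly modify.
- **Lesion.** An additive Gaussian-profile blob — peak amplitude a uniform
  draw of 16–32% of the 16-bit range, radius 6–12 px (sigma = radius/2) —
  plus 2–10 linear spicules tapering outward, emulating mass-type lesions.
  Rationale for amplitudes: the designed-in learnability property below.
- **Seeding.** One master seed; each image's random stream is derived by a
  counter scheme (seed, patient index, view index), so any single image is
  regenerable in isolation.
- **Learnability property.** The mean intensity inside the lesion disk minus
  the mean over the lesion-free breast support separates classes with
  AUC > 0.95 by construction (checked in tests). A cohort failing this would
  make every downstream result vacuous.

Default working resolution is 128 x 104 ("desk" profile; same 1.23 aspect
ratio as the study's 1728 x 1408). The `low` (1024 x 832) and `high`
(1728 x 1408) profiles are configurable but carry a compute warning: they
are GPU-scale and are not exercised by the test suite.

What the phantoms do **not** model: breast density categories,
calcification-type lesions, view-to-view anatomical correlation within a
patient, scanner noise/artifacts, or any real parenchymal anatomy. Passing
tests therefore demonstrate that the *pipeline logic and optimization*
behave as specified on a learnable cohort — not clinical performance.

## Preprocessing

- **Resizing** is bicubic at a single isotropic factor
  `min(target_h/h, target_w/w)`, anchored top-left, zero-padded to the
  target frame; bit depth (uint16) preserved.
- **Augmentation** (training only): vertical flip (p = 0.5), rotation
  U(-45°, 45°), scaling U(0.5, 2), shearing U(-45°, 45°), composed about the
  image center with bilinear interpolation and zero padding.
- **Normalization**: intensities scaled to [0, 1], then standardized with
  the VGG11/ImageNet per-channel constants (mean 0.485/0.456/0.406,
  SD 0.229/0.224/0.225). Three-channel mode replicates the grayscale plane;
  single-channel mode (the generator's input) uses the first channel's
  constants.

## Classifier

Architecture: a convolutional feature extractor ("Vnet") and a head
("Fnet") with GroupNorm, LeakyReLU (slope 0.2), Dropout (0.2), a 2x2
stride-1 average pool, global max pooling (lesions are small; the firing
element should be magnified, not averaged away), and a fully connected stack
ending in a 2-class softmax.

Two realizations:

- **Full mode** is an architecture table (not an instantiated network):
  the first 20 VGG11 layers plus a head conv stack chosen so the analytic
  receptive field before global pooling is exactly 406 px. The
  `receptive_field` calculator (r += (k-1)·jump; jump *= stride) audits any
  realization.
- **Desk mode** (default, instantiated): a pool-first stack
  (channels 16/32/64/64) whose receptive field of 76 px covers the maximal
  lesion extent (~48 px). Head GroupNorm uses 8 groups of 8 channels — the
  desk analogue of 32 groups over 512 channels.

Loss (per balanced batch of N positives and N negatives, N = 4):

    Loss_cls = FL(p_p) + FL(p_n) + GP(g_p, g_n)
    FL(p)    = -1/N sum_j (1 - p_j)^gamma ln p_j          (gamma = 2)
    GP       = k/(2N) sum_j (||grad_x s(x_j^p)||_2^o + ||grad_x s(x_j^n)||_2^o)

with k = 10, o = 4, and s the scalar pre-softmax positive-class score. The
gradient penalty is an input-smoothness regularizer; its parameter gradient
is a gradient-of-a-gradient, which the autodiff layer supports natively.
Numerical choices: probabilities are clamped at 1e-7 inside FL (logged when
triggered); the norm power is implemented as (squared norm)^(o/2), which is
smooth at zero.

Optimization is Adam (beta1 = 0.5, beta2 = 0.9) in two stages: head-only
first, then head + backbone at separate rates. The full-mode defaults
(lr 1e-4/1e-5, 41 head-only epochs) presuppose an ImageNet-pretrained
backbone whose features should initially be preserved. The desk backbone is
randomly initialized, so the desk schedule uses equal rates of 3e-4, a
2-epoch head-only stage, and 100 epochs; with a pretrained-style tiny
backbone rate the random features would never train. Model selection is by
best validation AUC (no selection rule is otherwise implied by the design).

## Adversarial GANs

The generator is a two-level U-Net (channels 8/16/32; 2x2 stride-2 average
pool downsampling, factor-2 bilinear upsampling, LeakyReLU 0.2) on the
single-channel normalized image, with a sigmoid-normalized [0, 1] output.
The pre-sigmoid output adds the logit of the input plane (clamped to
[1e-4, 1-1e-4]), i.e. the network learns a residual modification on top of
an exact identity passthrough. This makes the identity phase genuinely
reach its 0.002 stopping threshold at desk scale and concentrates training
capacity on the lesion edit itself. The exact channel/depth schedule is
recorded in the checkpoint manifest.

The discriminator shares the classifier's architecture with a single output
neuron and is initialized from the trained classifier; no batch
normalization appears anywhere. Scores are log-sigmoid:
Dis(g) = -ln(1 + exp(-Dnet(Vnet(g)))) <= 0.

The scoring layer is initialized to the classifier's class-difference
direction (raw score = logit of the target class minus the other class;
configurable back to random initialization). This choice matters at desk
scale. With a random scoring layer, the discriminator's real-vs-fake
separation is shallow, and the generator wins with perturbations orders of
magnitude smaller than anything that would move the classifier — the attack
"succeeds" against the discriminator and fails against the classifier.
Two structural facts compound this: the loss term -Dis(x) + |Dis(x)-1|
always pushes the (non-positive) real scores upward with double weight and
no restoring force, so under Adam the raw scores drift into the flat region
of the log-sigmoid where all separation gradients vanish; and the gradient
penalty cannot brake this drift because additive (bias-like) score shifts
have no input gradient. Starting from the classifier's own decision
direction gives the discriminator a deep, semantically meaningful
separation from the first batch: the log-sigmoid is then non-saturating on
the generator's losing side, the adversarial pressure on the generator is
exactly "cross the classifier's (smoothness-regularized) decision
boundary", and the margin stop below fires when the fakes actually cross
it.

Losses (batch means; written for the removal direction, x = real negatives,
y = positives, y_fn = 3-channel pseudo-color of Gnet(y); the insertion
direction swaps x and y):

    Loss_dis  = -Dis(x) + Dis(y_fn) + |Dis(x) - 1| + GP(x)
    GP(x)     = k/2 mean_j ||grad_x Dnet(Vnet(x_j))||_2^o    (k=10, o=4)
    Loss_gen1 = ||y_fn - y||^2 / ||y||^2    (per-sample ratio, batch mean)
    Loss_gen2 = -Dis(y_fn) + Loss_gen1

The |Dis(x)-1| stabilizer anchors real scores; GP is applied to the real
batch only (configurable). Loss_gen1 compares the 3-channel pseudo-color
fake with the identically standardized real plane, so numerator and
denominator are commensurate.

Three-phase schedule (thresholds on epoch means; threshold OR epoch cap,
whichever first, both logged):

| phase | trains            | loss      | stop when         | cap |
|-------|-------------------|-----------|-------------------|-----|
| A     | generator         | Loss_gen1 | mean < 0.002      | 11  |
| B     | final layer of D  | Loss_dis  | margin > 0.2      | 10  |
| C     | D (all), G 1-in-5 | Loss_dis / Loss_gen2 | margin < 0.01 | 200 (desk 20) |

where margin = mean Dis(x) - mean Dis(y_fn). Phase A and B thresholds are
epoch means; the phase-C margin is an epoch-length *sliding* mean over the
per-batch training scores, checked at every batch. The sliding check
matters: once the generator crosses the discriminator's boundary, its
adversarial gradient saturates and the identity term starts to undo the
modification, so a stop that lags the crossing by a whole epoch returns a
generator that has already retreated. Phase-A epochs sweep the full
source-class pool (identity training touches only one class); phases B/C
use balanced batches with the classifier's augmentation and sampling. The
desk schedule raises the learning rates (phase A 3e-4; phase B 1e-3 on the
final layer; phase C generator 1e-3, discriminator head 3e-4) for the same
pretrained-vs-random reason as the classifier, keeps the discriminator
backbone near-frozen (1e-5) so the discriminator stays aligned with the
classifier it must proxy, and caps phase C at 20 epochs for CPU
feasibility.

Generated fakes are mapped from the [0, 1] sigmoid output back to uint16 by
scaling with 65535 and rounding; files carry the flipped label and
realness = fake.

## Attack evaluation

Threshold rule: positive iff probability > 0.5; a probability of exactly
0.5 classifies negative (a side must be chosen; the tie rule is explicit
and configurable). AUC is the rank-based Mann–Whitney statistic with ties
counted half (scikit-learn's implementation; an O(n²) all-pairs oracle
cross-checks it in the tests). The adversarial-set AUC uses the flipped
labels, matching the convention of the original report. Report percentages
round to one decimal; the raw counts are stored alongside so every
percentage recomputes from its own counts.

Education panels display real | fake | signed difference (real - fake); the
difference is windowed symmetrically about zero so equal-magnitude
insertions and removals render with equal contrast, and the lossless signed
difference is exported separately (float32 TIFF).

## Reader statistics

A response is correct iff it names the image's true realness; "unsure" is
never correct and is additionally reported as its own fraction (the
accuracy table lists it as a separate column; a configurable variant
excludes unsure responses from the denominator instead). Subgroup SDs cut
each session's responses, in reading order, into n contiguous equal blocks
(default n = 4, always reported next to the p-value; any remainder is
dropped and logged) and take the ddof-1 SD of block accuracies. Session
comparisons use a two-sample z with each accuracy assigned variance
sd_avg², i.e. z = (acc_b - acc_a)/(sd_avg·sqrt(2)), one-sided; sd_avg is the
average of the sessions' subgroup SDs. With sd_avg = 0 the p-value is
degenerate (0/0.5/1 by sign) and logged. The sqrt(2) pooling and the
subgroup count are explicit package choices where the original description
leaves them open.

The bundled response simulator reproduces the study's session designs
(session 3: 36 real-positive + 179 real-negative + 183 positive-looking +
38 negative-looking = 436 images; session 5: 39/184/180/37 = 440) with
per-reader correctness probabilities. It is a synthetic stand-in to
exercise the scoring code and models no real reader behavior.

## Problem sizes and budgets

The test suite and the acceptance script run the desk profile: 100 patients
(≈344 images) at 128 x 104, the reduced backbone, 60 classifier epochs, and
the desk GAN schedule. On one CPU core this completes in roughly 10
minutes; the numbers it produces are stable in the qualitative sense the
tests assert (validation AUC, fool rates above one half) but fluctuate a
few points across seeds because the test partition holds only ~9 patients.

## Known limitations

- Full-mode (VGG11-scale) networks are described and audited but not
  trained here; the desk profile is the tested configuration.
- The discriminator margin is a noisy epoch statistic at desk scale; phase
  transitions can fire an epoch early or late relative to the underlying
  expectation.
- The insertion direction is intrinsically harder than removal (the
  generator must hallucinate structure rather than smooth it away); its
  fool rate is correspondingly lower and more seed-sensitive — the same
  asymmetry the original study reports.
- Reader statistics treat block accuracies as approximately normal; with
  few blocks the p-values are coarse.
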