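# Methods

`advlesion` is a desk-scale harness for studying L∞ gradient attacks on
binary lesion-image classifiers, the detectability of the resulting
adversarial images, and the relative value of detection filtering versus
adversarial training. Everything runs on synthetic data, so the package
measures the *mechanics and direction* of these effects, not clinical
performance numbers.

## The synthetic imaging model

Each image is a 32×32 single-channel patch in [0, 1]:

```
image = background + lesion·[y = 1] + pixel noise, clipped to [0, 1]
```

* **Background**: white noise smoothed with a Gaussian of scale
  `background_texture_scale` (default 2 px), rescaled per image to mean 0.45
  and SD 0.10 — a stand-in for parenchymal texture.
* **Lesion** (class 1 only): a bright disk with a sigmoid intensity falloff
  of width 0.8 px at the margin, radius uniform in 2.5–5 px, peak amplitude
  `lesion_intensity_shift` (default 0.34) jittered ±20%, placed uniformly at
  random. The *defined margin* matters: against a pure Gaussian blob, a
  classifier can converge to an all-smooth matched filter, and the character
  of its input gradients (hence of every attack built on them) then varies
  arbitrarily between training runs. A margin pins the decision boundary to
  edge-sensitive features.
* **Pixel noise**: i.i.d. Gaussian, SD `noise_sd` = 0.02. This is the
  detectability floor: perturbations well below it are information-
  theoretically invisible to any image-space detector, perturbations above
  it are not. The default places the floor between the canonical budgets
  0.004/0.008 and the top of the default ε grid (0.032), so the
  threshold-of-detectability transition is visible *within* the grid.

Three presets (`ct-like`, `mammo-like`, `mri-like`) vary texture scale and
lesion contrast to mirror a multi-modality design; they make no claim of
anatomic realism. Balanced classes and a stratified 2:1 train/validation
split are invariants of the generator, and generation is bitwise
deterministic in the config seed.

What the generator deliberately omits: anatomy and acquisition physics,
3-D structure, scanner/cohort heterogeneity, label noise, and class overlap
beyond additive noise. Passing tests therefore demonstrate that the
attack/detection/defense machinery behaves as the theory predicts on a
learnable imaging-like task — not that the same accuracies would be observed
on clinical data.

## The classifier

A small CNN trained from scratch: a fixed unsharp-mask front end
`x + g·(x − G₁x)` (gain g = 1.0), then three 3×3 conv blocks (8/16/32
channels, ReLU, 2×2 max-pool twice), global average pooling, and a linear
head. Training is SGD with momentum 0.9, batch 32, learning rate 0.05
stepped down ×0.1 for the final third of 40 epochs, with horizontal/vertical
flips (p = 0.5) and ±15° rotations applied on the fly during training only.
The model is frozen after training; attacks and evaluations see a
deterministic function.

The unsharp front end deserves a note. Large pretrained backbones open with
strong oriented edge filters, which makes their input gradients — and hence
the adversarial perturbations derived from them — consistently
high-frequency. A tiny from-scratch CNN has no such anchor: across training
seeds it may land on smooth templates whose attack perturbations are
large constant-sign patches, qualitatively unlike the signatures studied in
the detection literature. The fixed edge-enhancing stage restores that
property at desk scale. It is linear with a symmetric, zero-padded kernel,
hence exactly self-adjoint: backpropagated input gradients remain exact, and
it neither expands nor shrinks the ε-ball.

Preprocessing (`preprocess`) is center crop → bilinear resize → min-max
rescale to [0, 1]; a constant image maps to all zeros so the operation is
total.

## Attacks

All three attacks maximize the frozen model's cross-entropy on the true
label under ‖x_adv − x‖∞ ≤ ε with pixels clamped to [0, 1]:

* **FGSM**: `x + ε·sign(∇ₓJ(x, y))`, one step.
* **PGD**: T steps of size α (default ε/4, T = 10), each followed by the
  exact L∞ projection onto the ε-ball ∩ pixel box — an elementwise clamp to
  `[max(0, x−ε), min(1, x+ε)]`.
* **BIM**: iterated FGSM with per-step clipping; under the box realization of
  the clip it coincides elementwise with PGD, and both reduce to FGSM at
  T = 1, α = ε.

Numerical choices: iterative gradients are evaluated at the previous iterate;
the initial iterate is x itself (a uniform random start inside the ball is
available but off by default, since the plain update has none); `sign(0) = 0`;
attacks run in float64 and adversarial images are never 8-bit quantized
(quantization would silently erase sub-1/255 perturbations such as ε = 0.004).
All images are attacked, including ones the classifier already misclassifies.

## Detection

Five detectors discriminate clean from adversarial images, trained on the
clean training set plus its BIM-attacked counterpart and evaluated on the
balanced clean+adversarial test mixture:

* **conv_a / conv_b** — small CNNs (8/16/32 and 12/24/48 channels) trained
  end-to-end, but on fixed high-pass residual maps rather than raw pixels:
  two channels per image, |Laplacian| and |x − G₁x|, z-scored with statistics
  from the training rows. Adversarial perturbations are a low-amplitude
  high-frequency additive signal, and a from-scratch network fed raw pixels
  sits at chance for ~20 epochs before (sometimes) discovering residual
  filters — the same observation that leads steganalysis networks to fix
  their first layer to high-pass kernels. These detectors are optimized with
  Adam (lr 0.002, 20 epochs); the classifier's SGD recipe is not binding
  here and plain SGD crosses the residual-learning plateau only erratically.
* **feature_lr / feature_rf / feature_svm** — logistic regression (L2,
  C = 1), random forest (200 trees), and RBF SVM (C = 1) on standardized
  deep features of the frozen classifier. Deep features are the concatenated
  globally pooled activations of *all three* conv blocks (56-d): early-block
  statistics respond to the perturbation long before the decision-level
  features move, which is what lets these detectors track detectability at
  mid-range ε. Standardization statistics are fitted on training rows only.

**Calibration gate.** A stratified 25% of the detection training set is held
out; if the fitted discriminator does not beat chance there by 1.5 binomial
standard deviations, the detector is returned disabled and scores every
image 0.5. Below the detectability floor a 400-image evaluation otherwise
measures pure memorization noise (values like 0.48 at ε = 0.001), which has
no scientific content; a disabled detector measures exactly chance. This is
ordinary model selection against the trivial baseline, and it is also the
deployment-sane behavior for a safety filter.

Ties at score 0.5 resolve to "adversarial" — the conservative direction for
a filter guarding a classifier. Detector training defaults to the matched
condition (training ε = evaluation ε); `cross_attack_matrix` instead trains
at one ε on BIM only and sweeps attacks × ε, the cross-attack protocol.

## Defense comparison

Four regimes share one combined test set per seed: the clean validation set
plus its BIM-attacked counterpart (1:1), attacked at
`SYNTHETIC_DEFENSE_EPSILON` = 0.048 — one rung past the sweep grid, the
smallest budget that reliably drives the undefended model's adversarial
accuracy below 0.3 on these synthetic conditions (at clinical scale a budget
as small as 0.004 plays that role for large pretrained models on subtle
clinical features).

1. **baseline** — undefended model on the mixture; by construction equal to
   the mean of its clean and adversarial accuracies.
2. **detection** — the conv_a detector (trained on the BIM-attacked training
   set) excludes flagged images; adjusted accuracy
   `correct(retained) / (|retained| + |wrongly excluded clean|)` charges
   false positives as errors while correctly excluded adversarials drop out.
   A detector that flags everything scores 0 (the excluded clean half fills
   the denominator), so sweeps never abort. Two limits anchor the formula: a
   null detector
   reproduces the combined baseline, a perfect detector reproduces clean
   accuracy. One property worth stating precisely: catching an extra
   *misclassified* adversarial or removing a false positive never lowers the
   adjusted accuracy, but catching an adversarial the model classifies
   *correctly* removes a correct answer from numerator and denominator and
   strictly lowers the ratio — the formula is monotone in detector quality
   only where the attack actually fools the model.
3. **training** — multi-step PGD adversarial training (Madry-style): in each
   batch half the images are replaced by PGD-5 examples generated against
   the current model state. The attack budget follows a three-phase
   curriculum — clean for the first third of epochs, linear ramp to ε for
   the second, full ε for the last — and the run is 1.5× the ordinary epoch
   count. Both choices are load-bearing: attacked from epoch 1, the
   from-scratch network can remain at chance indefinitely, and the robust
   objective converges more slowly than the clean one. With the adversarial
   fraction at 0 the routine is bit-for-bit ordinary training.
4. **combined** — detection filtering in front of the adversarially trained
   model.

Every regime is replicated over ≥3 seeds and reported as mean ± SD; at desk
scale single-seed deltas are noisy.

## Seeds and reproducibility

A single global seed deterministically derives per-stage seeds as
`sha256(seed:stage) mod 2³¹`, so any stage can be rerun in isolation. Runs
are bitwise reproducible: the only stochastic elements are NumPy generators
seeded this way (the linear algebra is plain NumPy, with no threading
nondeterminism at these sizes).

## Problem sizes

The default study conditions are 300 images per class at 32×32, split 2:1;
the ε grid is the doubling ladder 0.001–0.032; detectors train on 800-image
mixtures. These sizes keep a full sweep plus defense comparison in the
ten-minute range on one CPU while leaving every measured effect (accuracy
collapse, detectability transition, defense ordering) far from its noise
floor.

## Known limitations

* Synthetic images only; none of the measured accuracies transfer to
  clinical cohorts.
* White-box, untargeted, L∞ attacks only; no black-box/transfer attacks, no
  adaptive attacks against the detector (an attacker aware of the filter
  could optimize to evade both models jointly).
* The conv detectors see fixed residual channels; a perturbation crafted to
  be spectrally flat against these filters would be harder to flag.
* Adjusted accuracy assumes the 1:1 clean/adversarial mixture of the
  evaluation protocol; deployment prevalence would differ.
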