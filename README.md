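# advlesion

Adversarial attacks, adversarial-image detection, and defenses for binary
lesion-image classifiers — a complete, reproducible pipeline exercised on
synthetic data.

Deep-learning classifiers that read diagnostic images (is a malignancy
present or not?) can be fooled by *adversarial images*: inputs whose pixels
are shifted by at most a tiny budget ε, invisible to a reader, yet flipping
the model's prediction. For a model used in oncology workflows this is a
patient-safety and fraud surface, and the two standard mitigations are to
**detect** adversarial inputs before the classifier acts, or to **train** the
classifier on adversarial examples so it stops being fooled. This package
implements the full comparison harness — attacks, five detector families,
adversarial training, and the combined defense — for researchers who want to
study the mechanics of these defenses end-to-end without access to clinical
cohorts: a built-in generator emulates the structure of lesion-patch datasets
(single-channel images in [0, 1], balanced binary labels, 2:1 split).

## The core methods

**Attacks** (white-box, untargeted, L∞-bounded; `J` = cross-entropy of the
frozen classifier, ε = max change per pixel):

| method | update |
|---|---|
| FGSM | `x_adv = x + ε·sign(∇ₓ J(x, y))` |
| PGD  | `x_t = Π_ε(x_{t−1} + α·sign(∇ₓ J(x_{t−1}, y)))`, T steps |
| BIM  | `x_t = Clip_{x,ε}{x_{t−1} + α·sign(∇ₓ J(x_{t−1}, y))}`, T steps |

Π and Clip are both realized as the exact projection onto
`[max(0, x−ε), min(1, x+ε)]`, so BIM ≡ PGD here and both reduce to FGSM at
T = 1, α = ε.

**Detection**: two small CNNs on high-pass residual maps (`conv_a`,
`conv_b`) and logistic-regression / random-forest / RBF-SVM detectors on the
classifier's pooled deep features, trained on clean + BIM-attacked training
images and scored by *detection accuracy* — the fraction of a balanced
clean+adversarial test set whose flag is predicted correctly.

**Defense comparison** on a 1:1 clean/adversarial test mixture: baseline
accuracy; detector-filtered *adjusted accuracy*
`correct(retained) / (|retained| + |wrongly excluded clean|)`; PGD
adversarial training (half-adversarial batches against the live model); and
detection + adversarial training combined.

See `docs/methods.md` for the synthetic imaging model, every tunable
parameter, and the numerical choices.

## A worked example

```python
import advlesion as al

cfg = al.default_config("ct-like", n_per_class=300, seed=0)
train, val = al.split_train_validation(al.generate_dataset(cfg), (2, 1), seed=1)
model = al.train_classifier(train, val, al.TrainConfig(seed=0))
print(f"clean: {al.evaluate_accuracy(model, val):.3f}")
for eps in (0.004, 0.016, 0.032):
    adv = al.generate_adversarial_set(model, val, al.AttackConfig(method="bim", epsilon=eps))
    print(f"bim eps={eps}: {al.evaluate_accuracy(model, adv):.3f}")
```

prints (seeds fixed as above):

```
clean: 0.935
bim eps=0.004: 0.885
bim eps=0.016: 0.690
bim eps=0.032: 0.425
```

The classifier separates lesion from non-lesion patches at 93.5% on clean
images, but a BIM perturbation of 0.032 — about eight 8-bit gray levels,
still invisible against the background texture — already costs it half its
margin over chance (0.5). The `examples/` scripts walk through each
capability: data + training, attacks, detection and cross-attack transfer,
the full ε sweep, and the four-regime defense comparison.

A thin CLI wraps the same calls:

```bash
advlesion generate-data --preset ct-like --seed 0 --out scratch/data.npz
advlesion train-classifier --data scratch/data.npz --seed 0 --out scratch/clf.npz
advlesion attack --model scratch/clf.npz --data scratch/data.npz \
    --method bim --epsilon 0.016 --out scratch/adv.npz
advlesion sweep --seed 0 --out scratch/sweep
advlesion defend-compare --seeds 3 --out scratch/defense.csv
```

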