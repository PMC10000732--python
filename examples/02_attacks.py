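"""Craft FGSM/PGD/BIM adversarial images and watch accuracy collapse with eps.

Attacks are white-box: they follow the sign of the frozen classifier's loss
gradient, move each pixel by at most eps (the L-inf budget, in units of the
[0,1] pixel range), and stay inside the pixel bounds. Accuracy on the attacked
validation set falls monotonically as the budget grows.
"""

import advlesion as al

cfg = al.default_config("ct-like", n_per_class=300, seed=0)
train, val = al.split_train_validation(al.generate_dataset(cfg), (2, 1), seed=1)
model = al.train_classifier(train, val, al.TrainConfig(seed=0))
print(f"clean accuracy: {al.evaluate_accuracy(model, val):.3f}")

for method in ("fgsm", "pgd", "bim"):
    row = []
    for eps in (0.004, 0.008, 0.016, 0.032):
        attack = al.AttackConfig(method=method, epsilon=eps)
        adv = al.generate_adversarial_set(model, val, attack)
        row.append(f"eps={eps}: {al.evaluate_accuracy(model, adv):.3f}")
    print(f"{method:>5}: " + "  ".join(row))
print("Every perturbation obeys ||x_adv - x||_inf <= eps; 0.004 is about one "
      "8-bit gray level. The iterative attacks (PGD/BIM) are at least as "
      "damaging as single-step FGSM at the same budget.")
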