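"""White-box L-infinity gradient attacks: FGSM, PGD, and BIM.

All three attacks perturb an input x within an L-inf budget epsilon — the
maximum allowed change to any single pixel — to increase the classifier's
cross-entropy loss on the true label y:

* FGSM takes a single full-budget step along the gradient sign:
  ``x_adv = x + eps * sign(grad_x J(x, y))``.
* PGD iterates smaller signed steps of size alpha, projecting onto the
  eps-ball around x after every step.
* BIM iterates signed steps and clips pixel values into the permitted range
  after every step.

The projection and the clip are both realized as the elementwise clamp onto
``[max(lo, x - eps), min(hi, x + eps)]`` — the exact L-inf projection onto
the intersection of the eps-ball and the pixel-range box — so BIM and PGD
coincide here (and both reduce to FGSM for one full-budget step). Gradients
in the iterative updates are evaluated at the previous iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import LabeledDataset, Provenance
from .nn import DifferentiableModel, ModelFrozenError

__all__ = [
    "AttackConfig",
    "loss_gradient",
    "fgsm",
    "project_linf",
    "pgd",
    "bim",
    "generate_adversarial_set",
    "ATTACK_FNS",
]


@dataclass(frozen=True)
class AttackConfig:
    """L-inf attack parameters.

    ``epsilon`` is the perturbation budget in pixel units of the normalized
    [0, 1] range (0.004 is about one 8-bit gray level). ``alpha`` is the
    per-step size of the iterative attacks; if None it defaults to
    ``epsilon / 4``. ``steps`` is forced to 1 for FGSM. ``random_start``
    draws the PGD initial iterate uniformly inside the eps-ball instead of
    starting at x; it is off by default because the plain update has no
    random-start term.
    """

    method: str = "pgd"  # "fgsm" | "pgd" | "bim"
    epsilon: float = 0.004
    alpha: float | None = None
    steps: int = 10
    pixel_bounds: tuple[float, float] = (0.0, 1.0)
    random_start: bool = False

    def __post_init__(self):
        if self.method not in ("fgsm", "pgd", "bim"):
            raise ValueError(f"unknown attack method {self.method!r}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if self.method == "fgsm" and self.steps != 1:
            object.__setattr__(self, "steps", 1)
        if self.steps <= 0:
            raise ValueError("steps must be positive")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        lo, hi = self.pixel_bounds
        if lo >= hi:
            raise ValueError("pixel_bounds must be an increasing pair")

    @property
    def step_size(self) -> float:
        return self.epsilon / 4.0 if self.alpha is None else self.alpha


def loss_gradient(model: DifferentiableModel, x: np.ndarray, y) -> np.ndarray:
    """Gradient of the cross-entropy loss w.r.t. the input, for a frozen model."""
    if not getattr(model, "frozen", False):
        raise ModelFrozenError("attack target must be frozen")
    g = model.loss_gradient(x, y)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite loss gradient")
    return g


def project_linf(x_t: np.ndarray, x: np.ndarray, config: AttackConfig) -> np.ndarray:
    """L-inf projection of ``x_t`` onto the eps-ball around ``x`` within pixel bounds.

    Elementwise clamp to ``[max(lo, x - eps), min(hi, x + eps)]`` — the
    nearest feasible point under the max norm; idempotent.
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if x_t.shape != x.shape:
        raise ValueError(f"shape mismatch: {x_t.shape} vs {x.shape}")
    lo, hi = config.pixel_bounds
    return np.clip(x_t, np.maximum(lo, x - config.epsilon), np.minimum(hi, x + config.epsilon))


def fgsm(model: DifferentiableModel, x: np.ndarray, y, config: AttackConfig) -> np.ndarray:
    """Single-step attack: ``x + eps * sign(grad)``, clamped to pixel bounds."""
    if config.method != "fgsm":
        raise ValueError("config.method must be 'fgsm'")
    x = np.asarray(x, dtype=np.float64)
    if config.epsilon == 0:
        return x.copy()
    g = loss_gradient(model, x, y)
    step = replace(config, alpha=config.epsilon, steps=1, method="fgsm")
    return project_linf(x + config.epsilon * np.sign(g), x, step)


def _iterate(model, x, y, config: AttackConfig, rng=None) -> np.ndarray:
    """Shared PGD/BIM loop: signed steps of alpha, box projection each step."""
    x = np.asarray(x, dtype=np.float64)
    if config.epsilon == 0:
        return x.copy()
    if config.random_start:
        rng = rng or np.random.default_rng(0)
        x_t = project_linf(x + rng.uniform(-config.epsilon, config.epsilon, x.shape), x, config)
    else:
        x_t = x.copy()
    for _ in range(config.steps):
        g = loss_gradient(model, x_t, y)
        x_t = project_linf(x_t + config.step_size * np.sign(g), x, config)
    return x_t


def pgd(model: DifferentiableModel, x: np.ndarray, y, config: AttackConfig,
        rng: np.random.Generator | None = None) -> np.ndarray:
    """Projected gradient descent: T signed steps, projected after every step."""
    if config.method != "pgd":
        raise ValueError("config.method must be 'pgd'")
    return _iterate(model, x, y, config, rng)


def bim(model: DifferentiableModel, x: np.ndarray, y, config: AttackConfig) -> np.ndarray:
    """Basic iterative method: iterated FGSM with per-step pixel clipping.

    With the clip realized as the exact box clamp this coincides elementwise
    with PGD at identical parameters.
    """
    if config.method != "bim":
        raise ValueError("config.method must be 'bim'")
    return _iterate(model, x, y, config)


ATTACK_FNS = {"fgsm": fgsm, "pgd": pgd, "bim": bim}


def generate_adversarial_set(model: DifferentiableModel, dataset: LabeledDataset,
                             config: AttackConfig, batch_size: int = 128) -> LabeledDataset:
    """Attack every image in a clean dataset with its ground-truth label.

    Untargeted: each image is pushed uphill on the loss of its own label.
    Labels and order are carried over unchanged; provenance is updated to
    record the generating attack and epsilon. All images are attacked,
    including ones the classifier already misclassifies.
    """
    if not dataset.is_clean():
        raise ValueError("refusing to attack an already-adversarial dataset")
    fn = ATTACK_FNS[config.method]
    out = np.empty_like(dataset.images)
    for start in range(0, len(dataset), batch_size):
        sl = slice(start, start + batch_size)
        out[sl] = fn(model, dataset.images[sl], dataset.labels[sl], config)
    prov = [Provenance("adversarial", config.method, config.epsilon) for _ in range(len(dataset))]
    return LabeledDataset(out, dataset.labels.copy(), prov)
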