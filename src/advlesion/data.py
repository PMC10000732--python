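"""Synthetic lesion-image generator and dataset containers.

Real studies of adversarial robustness in oncologic imaging train binary
malignancy classifiers on CT, mammography or MRI patches. Those cohorts
cannot be redistributed, so this module generates images with the same
statistical *structure*: single-channel 2-D patches in [0, 1], one binary
label per image (lesion present / absent), balanced classes, and a 2:1
train/validation split.

A positive image is a smoothed-noise background plus a soft-edged bright
Gaussian blob ("lesion") at a random position; a negative image is background
only. Three presets vary texture scale and lesion contrast to mirror a
multi-modality (CT / mammogram / MRI -like) design without claiming anatomic
realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "Provenance",
    "LabeledDataset",
    "SyntheticConfig",
    "PRESETS",
    "default_config",
    "generate_dataset",
    "split_train_validation",
    "save_png_dataset",
    "load_png_dataset",
    "save_npz_dataset",
    "load_npz_dataset",
]


@dataclass(frozen=True)
class Provenance:
    """Per-image origin record: clean or adversarial, and if so how."""

    source: str = "clean"  # "clean" | "adversarial"
    attack: str = "none"   # "none" | "fgsm" | "pgd" | "bim"
    epsilon: float = 0.0

    def __post_init__(self):
        if self.source not in ("clean", "adversarial"):
            raise ValueError(f"bad source {self.source!r}")
        if self.attack not in ("none", "fgsm", "pgd", "bim"):
            raise ValueError(f"bad attack {self.attack!r}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")


@dataclass
class LabeledDataset:
    """Ordered set of single-channel images with binary malignancy labels.

    ``images`` has shape (n, h, w) with every pixel in [0, 1]; ``labels`` is
    an int array of 0 (no malignancy) / 1 (malignancy); ``provenance`` records
    per image whether it is clean or adversarial and, if adversarial, the
    generating attack and its L-inf budget.
    """

    images: np.ndarray
    labels: np.ndarray
    provenance: list[Provenance] = field(default_factory=list)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.images.ndim != 3:
            raise ValueError("images must have shape (n, h, w)")
        if not self.provenance:
            self.provenance = [Provenance() for _ in range(len(self.labels))]
        if not (len(self.images) == len(self.labels) == len(self.provenance)):
            raise ValueError("images, labels and provenance lengths differ")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def image_size(self) -> int:
        return self.images.shape[1]

    def is_balanced(self, tol: int = 1) -> bool:
        counts = np.bincount(self.labels, minlength=2)
        return abs(int(counts[0]) - int(counts[1])) <= tol

    def is_clean(self) -> bool:
        return all(p.source == "clean" for p in self.provenance)

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(self.images[idx], self.labels[idx],
                              [self.provenance[i] for i in idx])

    def concat(self, other: "LabeledDataset") -> "LabeledDataset":
        return LabeledDataset(np.concatenate([self.images, other.images]),
                              np.concatenate([self.labels, other.labels]),
                              list(self.provenance) + list(other.provenance))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic lesion-image generator.

    ``lesion_intensity_shift`` is the peak added brightness of a lesion in
    pixel units (the [0, 1] range); ``lesion_radius_range`` is the Gaussian
    sigma of the blob in pixels; ``background_texture_scale`` is the Gaussian
    smoothing sigma of the background texture; ``noise_sd`` is i.i.d. pixel
    noise added on top.
    """

    n_per_class: int = 300
    image_size: int = 32
    lesion_intensity_shift: float = 0.34
    lesion_radius_range: tuple[float, float] = (2.5, 5.0)
    background_texture_scale: float = 2.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range must be positive and ordered")
        if 2 * hi > self.image_size:
            raise ValueError("lesion_radius_range does not fit inside the image")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


#: Named presets standing in for a three-modality cohort design. They differ
#: in background texture scale and lesion contrast only.
PRESETS: dict[str, dict] = {
    "ct-like": dict(background_texture_scale=2.0, lesion_intensity_shift=0.34, noise_sd=0.02),
    "mammo-like": dict(background_texture_scale=4.0, lesion_intensity_shift=0.28, noise_sd=0.02),
    "mri-like": dict(background_texture_scale=1.5, lesion_intensity_shift=0.42, noise_sd=0.025),
}


def default_config(preset: str = "ct-like", **overrides) -> SyntheticConfig:
    """Config for a named preset, with optional field overrides."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = SyntheticConfig(**PRESETS[preset])
    return replace(cfg, **overrides) if overrides else cfg


def _backgrounds(rng: np.random.Generator, n: int, size: int, cfg: SyntheticConfig) -> np.ndarray:
    raw = rng.standard_normal((n, size, size))
    smooth = gaussian_filter(raw, sigma=(0, cfg.background_texture_scale, cfg.background_texture_scale))
    smooth -= smooth.mean(axis=(1, 2), keepdims=True)
    sd = smooth.std(axis=(1, 2), keepdims=True)
    smooth /= np.where(sd > 0, sd, 1.0)
    return 0.45 + 0.10 * smooth


#: Width (pixels) of the sigmoid intensity falloff at the lesion margin.
#: Masses present as bright disks with a defined but not pixel-sharp margin;
#: a sub-pixel-soft edge also keeps the decision boundary anchored to
#: edge-sensitive features rather than to a single smooth template.
LESION_EDGE_WIDTH = 0.8


def _add_lesion(img: np.ndarray, rng: np.random.Generator, cfg: SyntheticConfig) -> None:
    size = img.shape[0]
    r = rng.uniform(*cfg.lesion_radius_range)
    margin = r
    cy, cx = rng.uniform(margin, size - margin, size=2)
    amp = cfg.lesion_intensity_shift * rng.uniform(0.8, 1.2)
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    img += amp / (1.0 + np.exp((dist - r) / LESION_EDGE_WIDTH))


def generate_dataset(config: SyntheticConfig) -> LabeledDataset:
    """Generate a balanced, shuffled clean dataset of 2*n_per_class images.

    Class 1 images contain one randomly placed soft-edged bright blob over a
    textured background; class 0 images are background only. All pixels are
    clipped into [0, 1]. Bitwise deterministic given the config (incl. seed).
    """
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_class
    images = _backgrounds(rng, n, config.image_size, config)
    labels = np.repeat([0, 1], config.n_per_class)
    for i in np.nonzero(labels == 1)[0]:
        _add_lesion(images[i], rng, config)
    if config.noise_sd > 0:
        images += rng.normal(0.0, config.noise_sd, images.shape)
    np.clip(images, 0.0, 1.0, out=images)
    order = rng.permutation(n)
    return LabeledDataset(images[order], labels[order])


def split_train_validation(dataset: LabeledDataset, ratio: tuple[int, int] = (2, 1),
                           seed: int = 0) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/validation split at the given integer ratio.

    Each class is shuffled independently under ``seed`` and divided so both
    halves stay balanced; sizes are within 1 of the exact ratio per class.
    The two parts partition the input (no overlap).
    """
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    r_train, r_val = ratio
    if r_train <= 0 or r_val <= 0:
        raise ValueError("ratio entries must be positive")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in (0, 1):
        idx = np.nonzero(dataset.labels == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        n_train = int(round(len(idx) * r_train / (r_train + r_val)))
        train_idx.append(idx[:n_train])
        val_idx.append(idx[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    val_idx = np.sort(np.concatenate(val_idx))
    return dataset.subset(train_idx), dataset.subset(val_idx)


# ---------------------------------------------------------------------------
# on-disk formats


def _manifest(dataset: LabeledDataset, filenames: Sequence[str] | None = None) -> pd.DataFrame:
    rows = {
        "label": dataset.labels,
        "source": [p.source for p in dataset.provenance],
        "attack": [p.attack for p in dataset.provenance],
        "epsilon": [p.epsilon for p in dataset.provenance],
    }
    if filenames is not None:
        rows = {"filename": list(filenames), **rows}
    return pd.DataFrame(rows)


def save_png_dataset(dataset: LabeledDataset, directory) -> Path:
    """Write 8-bit grayscale PNGs plus a manifest CSV; returns the manifest path.

    PNG quantizes pixels to 1/255 steps; adversarial perturbations smaller
    than that are not preserved. Use the NPZ format for lossless storage.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = [f"img_{i:05d}.png" for i in range(len(dataset))]
    for name, img in zip(names, dataset.images):
        iio.imwrite(directory / name, np.round(img * 255).astype(np.uint8))
    manifest = directory / "manifest.csv"
    _manifest(dataset, names).to_csv(manifest, index=False)
    return manifest


def load_png_dataset(directory) -> LabeledDataset:
    directory = Path(directory)
    df = pd.read_csv(directory / "manifest.csv")
    images = np.stack([iio.imread(directory / f).astype(np.float64) / 255.0
                       for f in df["filename"]])
    prov = [Provenance(r.source, r.attack, float(r.epsilon)) for r in df.itertuples()]
    return LabeledDataset(images, df["label"].to_numpy(), prov)


def save_npz_dataset(dataset: LabeledDataset, path) -> Path:
    """Lossless NPZ bundle (float images, int labels) + JSON provenance sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, images=dataset.images, labels=dataset.labels)
    sidecar = path.with_suffix(".provenance.json")
    sidecar.write_text(json.dumps(
        [{"source": p.source, "attack": p.attack, "epsilon": p.epsilon}
         for p in dataset.provenance]))
    return path


def load_npz_dataset(path) -> LabeledDataset:
    path = Path(path)
    with np.load(path) as bundle:
        images, labels = bundle["images"], bundle["labels"]
    sidecar = path.with_suffix(".provenance.json")
    prov = [Provenance(**rec) for rec in json.loads(sidecar.read_text())]
    return LabeledDataset(images, labels, prov)
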