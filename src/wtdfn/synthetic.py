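"""Synthetic two-class single-cell image generator.

Emulates the contrast between lymphoblasts and normal lymphocytes as seen
in stained blood-smear crops: both classes are a roundish cell (ellipse of
cytoplasm) with a darker nucleus, and the *discriminative* signal is
confined to the nucleus — lymphoblast-like images ("blast", label 0) get a
larger nucleus-to-cell ratio, coarse chromatin speckle, and occasional
vacuole spots, while "normal" (label 1) nuclei are smaller and smooth.
Nuisance variation (orientation, position, size, per-channel color shift,
background noise) is heavy and class-independent, which gives the low
interclass / high intraclass structure that makes the task fine-grained.

Everything is driven by an explicit ``numpy`` generator, so images,
manifests and splits are reproducible byte-for-byte from a seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

from .exceptions import ConfigError

CLASS_NAMES = ("blast", "normal")

_BACKGROUND = np.array([0.88, 0.87, 0.90])
_CYTOPLASM = np.array([0.72, 0.66, 0.84])
_NUCLEUS = np.array([0.42, 0.28, 0.58])
_VACUOLE = np.array([0.86, 0.83, 0.92])


@dataclass
class SyntheticSpec:
    """Generator parameters; intervals are fractions of the relevant scale."""

    image_size: int = 64
    cell_radius_range: tuple = (0.28, 0.42)          # fraction of image size
    aspect_range: tuple = (0.75, 1.0)                # ellipse minor/major ratio
    nucleus_ratio: dict = field(default_factory=lambda: {
        "blast": (0.70, 0.90), "normal": (0.40, 0.60)})  # of cell radius
    chromatin_noise_sd: dict = field(default_factory=lambda: {
        "blast": 0.18, "normal": 0.04})              # inside nucleus only
    vacuole_prob: dict = field(default_factory=lambda: {"blast": 0.5, "normal": 0.0})
    background_noise_sd: float = 0.03
    rotation_jitter_deg: float = 180.0
    center_jitter_frac: float = 0.10                 # of image size
    nucleus_offset_frac: float = 0.05                # of image size
    color_jitter: float = 0.08                       # per-channel shift

    def validate(self) -> None:
        for name, (lo, hi) in dict(cell_radius=self.cell_radius_range,
                                   aspect=self.aspect_range,
                                   **{f"nucleus_{k}": v for k, v in self.nucleus_ratio.items()}
                                   ).items():
            if not (0.0 < lo <= hi <= 1.0):
                raise ConfigError(f"{name} interval must lie within (0, 1]: ({lo}, {hi})")
        for k, p in self.vacuole_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"vacuole_prob[{k}] must be a probability")


def _uniform(rng, lo, hi):
    return float(lo + (hi - lo) * rng.random())


def generate_cell_image(label: int, rng: np.random.Generator,
                        spec: SyntheticSpec | None = None):
    """Draw one cell image; returns (H x W x 3 float image in [0,1], metadata)."""
    spec = spec or SyntheticSpec()
    spec.validate()
    cls = CLASS_NAMES[label]
    size = spec.image_size

    angle = np.deg2rad(_uniform(rng, -spec.rotation_jitter_deg, spec.rotation_jitter_deg))
    cj = spec.center_jitter_frac * size
    cy = size / 2 + _uniform(rng, -cj, cj)
    cx = size / 2 + _uniform(rng, -cj, cj)
    r = _uniform(rng, *spec.cell_radius_range) * size
    aspect = _uniform(rng, *spec.aspect_range)
    ratio = _uniform(rng, *spec.nucleus_ratio[cls])
    shift = rng.uniform(-spec.color_jitter, spec.color_jitter, size=3)

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - cy, xx - cx
    u = np.cos(angle) * dx + np.sin(angle) * dy
    v = -np.sin(angle) * dx + np.cos(angle) * dy
    cell = (u / r) ** 2 + (v / (r * aspect)) ** 2 <= 1.0

    nj = spec.nucleus_offset_frac * size
    ny = cy + _uniform(rng, -nj, nj)
    nx = cx + _uniform(rng, -nj, nj)
    nr = ratio * r * aspect
    nucleus = (yy - ny) ** 2 + (xx - nx) ** 2 <= nr ** 2
    nucleus &= cell

    img = np.empty((size, size, 3))
    img[...] = _BACKGROUND + shift
    img[cell] = _CYTOPLASM + shift
    img[nucleus] = _NUCLEUS + shift

    if spec.background_noise_sd > 0:
        img += rng.normal(0.0, spec.background_noise_sd, size=(size, size, 1))

    chromatin_sd = spec.chromatin_noise_sd[cls]
    if chromatin_sd > 0:
        speckle = rng.normal(0.0, chromatin_sd, size=(size, size))
        img[nucleus] += speckle[nucleus, None]

    n_vac = 0
    if rng.random() < spec.vacuole_prob[cls] and nr > 3.0:
        n_vac = int(rng.integers(1, 4))
        for _ in range(n_vac):
            vr = _uniform(rng, 0.10, 0.22) * nr
            rho = _uniform(rng, 0.0, max(nr - vr, 0.0))
            phi = _uniform(rng, 0.0, 2 * np.pi)
            vy, vx = ny + rho * np.sin(phi), nx + rho * np.cos(phi)
            vac = (yy - vy) ** 2 + (xx - vx) ** 2 <= vr ** 2
            img[vac & nucleus] = _VACUOLE + shift

    img = np.clip(img, 0.0, 1.0)
    meta = {
        "label": label, "class_name": cls,
        "cell_center": (round(cy, 4), round(cx, 4)), "cell_radius": round(r, 4),
        "aspect": round(aspect, 4), "angle_deg": round(float(np.rad2deg(angle)), 4),
        "nucleus_center": (round(ny, 4), round(nx, 4)), "nucleus_radius": round(nr, 4),
        "nucleus_ratio": round(ratio, 4), "n_vacuoles": n_vac,
        "color_shift": [round(float(s), 4) for s in shift],
    }
    return img, meta


def nucleus_mask(meta: dict, size: int) -> np.ndarray:
    """Boolean nucleus-region mask reconstructed from image metadata."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    ny, nx = meta["nucleus_center"]
    return (yy - ny) ** 2 + (xx - nx) ** 2 <= meta["nucleus_radius"] ** 2


def _split_for_index(i: int, n: int) -> str:
    n_train = int(round(n * 0.6))
    n_val = int(round(n * 0.2))
    if i < n_train:
        return "train"
    if i < n_train + n_val:
        return "val"
    return "test"


def generate_arrays(n_per_class: int, seed: int, spec: SyntheticSpec | None = None):
    """In-memory dataset: (images, labels, metas, splits), stratified 60/20/20."""
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    spec = spec or SyntheticSpec()
    images, labels, metas, splits = [], [], [], []
    for label, cls in enumerate(CLASS_NAMES):
        for i in range(n_per_class):
            rng = np.random.default_rng([seed, label, i])
            img, meta = generate_cell_image(label, rng, spec)
            meta["index"] = i
            images.append(img)
            labels.append(label)
            metas.append(meta)
            splits.append(_split_for_index(i, n_per_class))
    return np.stack(images), np.array(labels), metas, splits


def generate_dataset(n_per_class: int, seed: int, spec: SyntheticSpec | None = None,
                     out_dir: str | Path = "synthetic_cells"):
    """Write a directory-per-class PNG dataset plus a CSV manifest.

    The manifest has columns path,label,split,seed,params with a stratified
    60/20/20 train/val/test split; params is a JSON record of every sampled
    geometry/noise parameter. Returns the manifest rows.
    """
    spec = spec or SyntheticSpec()
    out = Path(out_dir)
    images, labels, metas, splits = generate_arrays(n_per_class, seed, spec)
    rows = []
    for img, label, meta, split in zip(images, labels, metas, splits):
        cls = CLASS_NAMES[label]
        (out / cls).mkdir(parents=True, exist_ok=True)
        rel = f"{cls}/{cls}_{meta['index']:05d}.png"
        arr = np.round(img * 255.0).astype(np.uint8)
        PILImage.fromarray(arr).save(out / rel)
        rows.append({
            "path": rel, "label": int(label), "split": split, "seed": int(seed),
            "params": json.dumps(meta, sort_keys=True),
        })
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "label", "split", "seed", "params"])
        writer.writeheader()
        writer.writerows(rows)
    return rows
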