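"""Image-folder dataset loading.

Consumes directory-per-class single-cell image folders (PNG/JPEG/BMP).
Class order is lexicographic on directory names and item order is
lexicographic within each class, so two loads of the same tree enumerate
identically. Images decode to H x W x 3 float arrays in [0, 1]; grayscale
inputs are replicated to three channels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

from .exceptions import ConfigError

_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp"}


@dataclass
class Dataset:
    items: list                      # (path, label index) pairs
    class_names: list
    splits: list = field(default_factory=list)   # optional per-item split tags
    resolution: int | None = None

    def __len__(self):
        return len(self.items)

    def load_image(self, i: int) -> np.ndarray:
        path, _ = self.items[i]
        try:
            with PILImage.open(path) as im:
                im = im.convert("RGB")
                if self.resolution and im.size != (self.resolution, self.resolution):
                    im = im.resize((self.resolution, self.resolution), PILImage.BILINEAR)
                arr = np.asarray(im, dtype=float) / 255.0
        except OSError as exc:
            raise OSError(f"cannot decode image file {path}: {exc}") from exc
        return arr

    def arrays(self, split: str | None = None):
        """Materialize (images, labels) — optionally only one split."""
        idx = range(len(self.items))
        if split is not None:
            idx = [i for i in idx if self.splits and self.splits[i] == split]
        images = np.stack([self.load_image(i) for i in idx])
        labels = np.array([self.items[i][1] for i in idx])
        return images, labels

    @property
    def labels(self) -> np.ndarray:
        return np.array([label for _, label in self.items])


def load_image_folder(root, resolution: int | None = None) -> Dataset:
    """Load a directory-per-class image tree in deterministic order."""
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ConfigError(f"no class subdirectories under {root}")
    items, class_names = [], []
    split_by_path = _read_manifest_splits(root)
    splits = []
    for label, class_dir in enumerate(class_dirs):
        files = sorted(p for p in class_dir.iterdir()
                       if p.suffix.lower() in _EXTENSIONS)
        if not files:
            raise ConfigError(f"class directory {class_dir} contains no images")
        class_names.append(class_dir.name)
        for path in files:
            items.append((str(path), label))
            splits.append(split_by_path.get(f"{class_dir.name}/{path.name}", ""))
    return Dataset(items=items, class_names=class_names, splits=splits,
                   resolution=resolution)


def _read_manifest_splits(root: Path) -> dict:
    manifest = root / "manifest.csv"
    if not manifest.exists():
        return {}
    with open(manifest, newline="") as fh:
        return {row["path"]: row["split"] for row in csv.DictReader(fh)
                if "path" in row and "split" in row}
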