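"""Attention-guided crop and erase augmentation.

Given a normalized attention map on the feature grid, the map is
bilinearly upsampled to image resolution and thresholded at 0.5. The crop
stream takes the smallest bounding rectangle of the above-threshold
region and zooms it back to the input size ("see details"); the erase
stream multiplies the image by the complementary mask, blacking out the
attended part so training must discover secondary cues ("see more").

Both masks come from the same map and the same threshold, so they are
exact pixelwise complements. All coordinates are 0-based and boxes are
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError, InvalidInputError


@dataclass(frozen=True)
class Box:
    """Half-open pixel rectangle [top, bottom) x [left, right)."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self):
        if not (0 <= self.top < self.bottom and 0 <= self.left < self.right):
            raise InvalidInputError(f"degenerate box {self}")


def _bilinear_coords(n_out: int, n_in: int) -> np.ndarray:
    # align-corners: endpoints of the output grid map to endpoints of the input
    if n_out == 1 or n_in == 1:
        return np.zeros(n_out)
    return np.arange(n_out) * (n_in - 1) / (n_out - 1)


def resize_bilinear(values: np.ndarray, H: int, W: int) -> np.ndarray:
    """Align-corners bilinear resize of a 2-D array or H x W x C image."""
    values = np.asarray(values, dtype=float)
    rows = _bilinear_coords(H, values.shape[0])
    cols = _bilinear_coords(W, values.shape[1])
    grid = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    if values.ndim == 2:
        out = ndimage.map_coordinates(values, coords, order=1, mode="nearest")
        return out.reshape(H, W)
    out = np.stack(
        [
            ndimage.map_coordinates(values[..., ch], coords, order=1, mode="nearest").reshape(H, W)
            for ch in range(values.shape[2])
        ],
        axis=-1,
    )
    return out


def upsample_map(Fk_star: np.ndarray, H: int, W: int) -> np.ndarray:
    """Bilinearly upsample a normalized h x w map to H x W, clipped to [0, 1]."""
    if H < 1 or W < 1:
        raise InvalidInputError("target size must be positive")
    return np.clip(resize_bilinear(np.asarray(Fk_star, dtype=float), H, W), 0.0, 1.0)


def _check_threshold(threshold: float) -> None:
    if not (0.0 < threshold < 1.0):
        raise ConfigError(f"threshold must lie in (0, 1); got {threshold}")


def crop_mask(attn: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask: 1 where the map is >= threshold, else 0."""
    _check_threshold(threshold)
    return (np.asarray(attn, dtype=float) >= threshold).astype(np.uint8)


def erase_mask(attn: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask: 0 where the map is >= threshold, else 1 (complement of crop)."""
    _check_threshold(threshold)
    return (np.asarray(attn, dtype=float) < threshold).astype(np.uint8)


def bounding_box(mask: np.ndarray) -> Box:
    """Smallest half-open rectangle covering all 1s; full image if none."""
    mask = np.asarray(mask)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return Box(0, 0, mask.shape[0], mask.shape[1])
    return Box(int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)


def attention_crop(image: np.ndarray, Fk_star: np.ndarray, threshold: float = 0.5
                   ) -> np.ndarray:
    """Zoom the attended region back to the input size.

    Pipeline: upsample map -> threshold -> minimal bounding box -> extract
    the sub-image -> bilinear resize to the original H x W.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape[:2]
    attn = upsample_map(Fk_star, H, W)
    box = bounding_box(crop_mask(attn, threshold))
    sub = image[box.top : box.bottom, box.left : box.right]
    if sub.shape[:2] == (H, W):
        return image.copy()
    return np.clip(resize_bilinear(sub, H, W), 0.0, 1.0)


def attention_erase(image: np.ndarray, Fk_star: np.ndarray, threshold: float = 0.5
                    ) -> np.ndarray:
    """Black out the attended region: image * erase_mask, per channel."""
    image = np.asarray(image, dtype=float)
    H, W = image.shape[:2]
    mask = erase_mask(upsample_map(Fk_star, H, W), threshold)
    return image * mask[:, :, None]
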