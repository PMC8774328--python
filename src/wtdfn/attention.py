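"""Attention core: part-attention maps, bilinear attention pooling, and
selection/normalization of the map that guides augmentation.

Feature maps X (C x h x w) come from the last convolutional stage of the
backbone. A learnable 1x1 convolution with bias, followed by ReLU, turns
them into M nonnegative part-attention maps F (M x h x w). Bilinear
attention pooling (BAP) forms a part-feature matrix P with
P[k, c] = mean_ij F_k(i, j) * X_c(i, j); the flattened matrix is
signed-square-rooted and L2-normalized before classification. One map,
chosen at random during training or by maximum spatial energy at test
time, is min-max normalized to [0, 1] and handed to the crop/erase
augmentation.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigError, InvalidInputError


def extract_feature_maps(image: np.ndarray, model) -> np.ndarray:
    """Backbone activations for a single H x W x 3 image, as C x h x w."""
    X, _ = model.extract_features(image)
    return X[0]


def generate_attention_maps(X: np.ndarray, weight: np.ndarray, bias: np.ndarray | None = None
                            ) -> np.ndarray:
    """Apply a 1x1 convolution (weights M x C) plus ReLU to C x h x w features.

    This is the functional form of the model's attention head; the model
    stores ``weight``/``bias`` as trainable parameters.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise InvalidInputError("expected feature maps of shape (C, h, w)")
    weight = np.asarray(weight, dtype=float).reshape(-1, X.shape[0])
    if weight.shape[0] < 1:
        raise ConfigError("need at least one attention map (M >= 1)")
    maps = np.einsum("kc,chw->khw", weight, X)
    if bias is not None:
        maps = maps + np.asarray(bias, dtype=float)[:, None, None]
    return np.maximum(maps, 0.0)


def bilinear_attention_pool(X: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Part-feature matrix P (M x C): spatial mean of F_k * X_c.

    Raw pooled values; the signed-sqrt / L2 normalization applied before
    the classifier lives in the model forward, not here.
    """
    X = np.asarray(X, dtype=float)
    F = np.asarray(F, dtype=float)
    if X.ndim != 3 or F.ndim != 3:
        raise InvalidInputError("X and F must be 3-D (channels/maps first)")
    if X.shape[1:] != F.shape[1:]:
        raise InvalidInputError(
            f"spatial size mismatch: X {X.shape[1:]} vs F {F.shape[1:]}"
        )
    h, w = X.shape[1:]
    return np.einsum("khw,chw->kc", F, X) / (h * w)


def normalize_attention_map(Fk: np.ndarray) -> np.ndarray:
    """Min-max rescale a single map to [0, 1]; constant maps become zeros."""
    Fk = np.asarray(Fk, dtype=float)
    if not np.all(np.isfinite(Fk)):
        raise InvalidInputError("attention map contains non-finite values")
    lo = Fk.min()
    hi = Fk.max()
    if hi == lo:
        return np.zeros_like(Fk)
    return (Fk - lo) / (hi - lo)


def select_augmentation_map(F: np.ndarray, rng: np.random.Generator | None = None,
                            mode: str = "random"):
    """Choose the map that guides augmentation.

    ``random``: k uniform over the M maps (training default).
    ``max_energy``: k with the largest spatial sum, ties to the smallest
    index (deterministic test-time default).

    Returns ``(k, normalized_map)`` with k a 0-based index.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 3 or F.shape[0] < 1:
        raise InvalidInputError("expected attention maps of shape (M, h, w)")
    if mode == "random":
        if rng is None:
            raise ConfigError("random selection requires a seeded generator")
        k = int(rng.integers(F.shape[0]))
    elif mode == "max_energy":
        k = int(np.argmax(F.sum(axis=(1, 2))))  # argmax takes the first of ties
    else:
        raise ConfigError(f"unknown selection mode {mode!r}")
    return k, normalize_attention_map(F[k])
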