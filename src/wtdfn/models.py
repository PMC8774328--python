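"""Model assembly: shared-backbone ternary-stream classifier.

The model is backbone -> attention head (1x1 conv, ReLU) -> bilinear
attention pooling -> linear classifier. The same parameter set serves all
three streams (raw / crop / erase); only the input image differs. A
baseline variant (``use_attention=False``) replaces the attention branch
with global average pooling and a single linear head, which is the
single-stream reference configuration.

Parameter accounting: with backbone channel width C, M attention maps and
c classes, the attention branch adds (C*M + M) + (M*C*c + c) parameters on
top of the backbone's convolutional trunk, versus (C*c + c) for the
baseline head.
"""

from __future__ import annotations

import numpy as np
import yaml

from . import nn
from .exceptions import ConfigError, InvalidInputError

_BAP_EPS = 1e-12
_SQRT_EPS = 1e-8


# ---------------------------------------------------------------------------
# Backbone registry


def _toy_cnn(rng):
    """Three conv blocks, C=32; sized for 64x64 desk-scale experiments."""
    return (
        nn.Sequential(
            nn.Conv2d(3, 16, 3, padding=1, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
            nn.Conv2d(16, 32, 3, padding=1, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
            nn.Conv2d(32, 32, 3, padding=1, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
        ),
        32,
    )


def _resnet(block, layers, rng, groups=1, base_width=64, se=False):
    planes = [64, 128, 256, 512]
    strides = [1, 2, 2, 2]
    stem = [
        nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng),
        nn.BatchNorm2d(64),
        nn.ReLU(),
        nn.MaxPool2d(3, stride=2, padding=1),
    ]
    blocks = []
    cin = 64
    for p, s, n_blocks in zip(planes, strides, layers):
        for i in range(n_blocks):
            if block is nn.BasicBlock:
                b = nn.BasicBlock(cin, p, stride=s if i == 0 else 1, rng=rng)
            else:
                b = nn.Bottleneck(cin, p, stride=s if i == 0 else 1, groups=groups,
                                  base_width=base_width, se=se, rng=rng)
            blocks.append(b)
            cin = p * block.expansion
    return nn.Sequential(*stem, *blocks), planes[-1] * block.expansion


_MBV2_CFG = [
    # expand, cout, repeats, stride
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
]


def _mobilenet_v2(rng):
    layers = [nn.Conv2d(3, 32, 3, stride=2, padding=1, bias=False, rng=rng),
              nn.BatchNorm2d(32), nn.ReLU6()]
    cin = 32
    for t, c, n, s in _MBV2_CFG:
        for i in range(n):
            layers.append(nn.InvertedResidual(cin, c, stride=s if i == 0 else 1,
                                              expand=t, rng=rng))
            cin = c
    layers += [nn.Conv2d(cin, 1280, 1, bias=False, rng=rng), nn.BatchNorm2d(1280), nn.ReLU6()]
    return nn.Sequential(*layers), 1280


BACKBONES = {
    "toy_cnn": _toy_cnn,
    "resnet18": lambda rng: _resnet(nn.BasicBlock, [2, 2, 2, 2], rng),
    "resnet34": lambda rng: _resnet(nn.BasicBlock, [3, 4, 6, 3], rng),
    "resnet50": lambda rng: _resnet(nn.Bottleneck, [3, 4, 6, 3], rng),
    "se_resnext26": lambda rng: _resnet(nn.Bottleneck, [2, 2, 2, 2], rng,
                                        groups=32, base_width=4, se=True),
    "se_resnext50": lambda rng: _resnet(nn.Bottleneck, [3, 4, 6, 3], rng,
                                        groups=32, base_width=4, se=True),
    "mobilenet_v2": _mobilenet_v2,
}


class WTDFNModel(nn.Module):
    """Shared backbone + attention head + BAP + linear classifier."""

    def __init__(self, backbone_name: str, M: int, c: int, seed: int = 0,
                 input_resolution: int = 300, use_attention: bool = True,
                 class_names=None):
        if backbone_name not in BACKBONES:
            raise ConfigError(
                f"unknown backbone {backbone_name!r}; available: {sorted(BACKBONES)}"
            )
        if M < 1:
            raise ConfigError("M must be >= 1")
        if c < 2:
            raise ConfigError("need at least two classes")
        rng = np.random.default_rng(seed)
        self.backbone, self.C = BACKBONES[backbone_name](rng)
        self.backbone_name, self.M, self.c = backbone_name, M, c
        self.input_resolution = input_resolution
        self.use_attention = use_attention
        self.class_names = list(class_names) if class_names else None
        if use_attention:
            self.attention_head = nn.Conv2d(self.C, M, 1, bias=True, rng=rng)
            self.classifier = nn.Linear(M * self.C, c, rng=rng)
        else:
            self.attention_head = None
            self.classifier = nn.Linear(self.C, c, rng=rng)

    # -- forward -----------------------------------------------------------

    @staticmethod
    def _to_nchw(images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=nn.DTYPE)
        if images.ndim == 3:
            images = images[None]
        if images.ndim != 4 or images.shape[-1] != 3:
            raise InvalidInputError("expected images of shape (N, H, W, 3) or (H, W, 3)")
        if images.shape[1] < 1 or images.shape[2] < 1:
            raise InvalidInputError("image spatial size must be positive")
        if not np.all(np.isfinite(images)):
            raise InvalidInputError("image contains non-finite values")
        return np.ascontiguousarray(images.transpose(0, 3, 1, 2))

    def extract_features(self, images: np.ndarray, train: bool = False):
        """Backbone activations X of shape (N, C, h, w) plus the cache."""
        x = self._to_nchw(images)
        return self.backbone.forward(x, train=train)

    def forward_batch(self, images: np.ndarray, train: bool = False):
        """Return (scores, attention_maps, feature_maps, cache) for a batch."""
        X, bb_cache = self.extract_features(images, train=train)
        n, C, h, w = X.shape
        if not self.use_attention:
            z = X.mean(axis=(2, 3))
            scores, lin_cache = self.classifier.forward(z, train=train)
            return scores, None, X, ("plain", bb_cache, lin_cache, X.shape)
        raw_maps, att_cache = self.attention_head.forward(X, train=train)
        relu_mask = raw_maps > 0
        A = np.maximum(raw_maps, 0)
        # bilinear attention pooling: P[n,k,c] = mean_ij A[n,k,ij] * X[n,c,ij]
        P = np.einsum("nkhw,nchw->nkc", A, X, optimize=True) / (h * w)
        S = np.sign(P) * np.sqrt(np.abs(P))
        flat = S.reshape(n, -1)
        norms = np.linalg.norm(flat, axis=1, keepdims=True) + _BAP_EPS
        feats = (flat / norms).astype(nn.DTYPE)
        scores, lin_cache = self.classifier.forward(feats, train=train)
        cache = ("bap", bb_cache, att_cache, relu_mask, A, X, P, S, flat, norms, lin_cache)
        return scores, A, X, cache

    def forward(self, x, train: bool = False):
        scores, A, X, cache = self.forward_batch(x, train=train)
        return scores, (A, X, cache)

    def forward_image(self, image: np.ndarray):
        """Spec-shaped single-image forward: (scores[c], AttentionMaps, FeatureMaps)."""
        scores, A, X, _ = self.forward_batch(image)
        att = A[0] if A is not None else None
        return scores[0], att, X[0]

    # -- backward ----------------------------------------------------------

    def backward_batch(self, dscores: np.ndarray, cache) -> None:
        kind = cache[0]
        if kind == "plain":
            _, bb_cache, lin_cache, xshape = cache
            dz = self.classifier.backward(dscores, lin_cache)
            n, C, h, w = xshape
            dX = np.broadcast_to(dz[:, :, None, None] / (h * w), xshape).astype(nn.DTYPE)
            self.backbone.backward(dX, bb_cache)
            return
        _, bb_cache, att_cache, relu_mask, A, X, P, S, flat, norms, lin_cache = cache
        n, C, h, w = X.shape
        dfeats = self.classifier.backward(dscores, lin_cache)
        # L2 normalization backward: y = s / (||s|| + eps)
        y = flat / norms
        dflat = dfeats / norms - y * np.sum(dfeats * y, axis=1, keepdims=True) / norms
        dS = dflat.reshape(S.shape)
        dP = dS * 0.5 / np.sqrt(np.abs(P) + _SQRT_EPS)
        dA = np.einsum("nkc,nchw->nkhw", dP, X, optimize=True) / (h * w)
        dX = np.einsum("nkc,nkhw->nchw", dP, A, optimize=True) / (h * w)
        draw = (dA * relu_mask).astype(nn.DTYPE)
        dX = dX + self.attention_head.backward(draw, att_cache)
        self.backbone.backward(dX.astype(nn.DTYPE), bb_cache)


def build_wtdfn(backbone_name: str, M: int = 32, c: int = 2, pretrained: bool = False,
                seed: int = 0, input_resolution: int = 300, use_attention: bool = True,
                class_names=None) -> WTDFNModel:
    """Build a ternary-stream model from the backbone registry.

    ``pretrained`` is accepted for interface compatibility; no pretrained
    weights ship with this package, so requesting them is a config error.
    """
    if pretrained:
        raise ConfigError("no pretrained weights are distributed with this package")
    return WTDFNModel(backbone_name, M, c, seed=seed, input_resolution=input_resolution,
                      use_attention=use_attention, class_names=class_names)


def count_parameters(model: nn.Module, trainable_only: bool = True) -> int:
    """Exact trainable parameter count (batchnorm running stats excluded)."""
    return model.num_parameters(trainable_only=trainable_only)


def params_in_millions(model: nn.Module) -> float:
    """Parameter count formatted the way comparison tables print it (xx.xxM)."""
    return round(count_parameters(model) / 1e6, 2)


# ---------------------------------------------------------------------------
# Checkpoint I/O


def _walk_modules(module, prefix=""):
    yield prefix.rstrip("."), module
    for name, value in module.__dict__.items():
        if isinstance(value, nn.Module):
            yield from _walk_modules(value, f"{prefix}{name}.")
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                if isinstance(item, nn.Module):
                    yield from _walk_modules(item, f"{prefix}{name}.{i}.")


def save_checkpoint(model: WTDFNModel, path: str) -> None:
    """Weights as an .npz archive plus a YAML sidecar with the build config."""
    arrays = {name: p.data for name, p in model.named_parameters()}
    for name, mod in _walk_modules(model):
        if isinstance(mod, nn.BatchNorm2d):
            arrays[f"{name}.running_mean"] = mod.running_mean
            arrays[f"{name}.running_var"] = mod.running_var
    np.savez(path, **arrays)
    meta = {
        "backbone_name": model.backbone_name,
        "M": int(model.M),
        "c": int(model.c),
        "input_resolution": int(model.input_resolution),
        "use_attention": bool(model.use_attention),
        "class_names": model.class_names,
    }
    with open(str(path) + ".meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_checkpoint(path: str) -> WTDFNModel:
    with open(str(path) + ".meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    model = WTDFNModel(
        meta["backbone_name"], meta["M"], meta["c"],
        input_resolution=meta["input_resolution"],
        use_attention=meta["use_attention"], class_names=meta["class_names"],
    )
    npz_path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
    import os

    if not os.path.exists(npz_path):
        npz_path = str(path)
    with np.load(npz_path) as data:
        for name, p in model.named_parameters():
            p.data = np.ascontiguousarray(data[name], dtype=nn.DTYPE)
        for name, mod in _walk_modules(model):
            if isinstance(mod, nn.BatchNorm2d):
                mod.running_mean = data[f"{name}.running_mean"].astype(nn.DTYPE)
                mod.running_var = data[f"{name}.running_var"].astype(nn.DTYPE)
    return model
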