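"""Two-phase ternary-stream training.

Each optimization step runs both phases: Phase-I forwards the raw
(preprocessed) images and collects attention maps; a map is then drawn at
random per image, thresholded into crop and erase wrappings (no gradient
flows through mask construction), and Phase-II forwards both wrappings
through the same weights. The loss is the unweighted mean of the three
streams' cross-entropies. The learning-rate schedule is a linear warm-up
over ``warmup_epochs`` followed by stepped multiplicative decay
(``decay_factor`` every ``decay_every`` epochs), and training stops early
when the validation weighted F1 stops improving.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage

from . import attention, augment, inference, metrics
from .exceptions import ConfigError, InvalidInputError
from .nn import OPTIMIZERS, softmax, DTYPE


@dataclass
class TrainConfig:
    epochs: int = 120
    batch_size: int = 7
    base_lr: float = 0.01
    weight_decay: float = 1e-4
    warmup_epochs: int = 2
    decay_factor: float = 0.95
    decay_every: int = 2
    input_resolution: int = 300
    M: int = 32
    early_stop_patience: int = 15
    seed: int = 0
    optimizer: str = "adam"
    threshold: float = 0.5
    ternary: bool = True          # False: raw stream only (baseline ablation)
    preprocess: bool = True       # flips / affine / grayscale / color jitter

    def validate(self) -> None:
        counts = dict(epochs=self.epochs, batch_size=self.batch_size,
                      warmup_epochs=self.warmup_epochs, decay_every=self.decay_every,
                      input_resolution=self.input_resolution, M=self.M,
                      early_stop_patience=self.early_stop_patience)
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1; got {value}")
        if self.base_lr <= 0:
            raise ConfigError("base_lr must be positive")
        if not (0 < self.decay_factor <= 1):
            raise ConfigError("decay_factor must lie in (0, 1]")
        if self.optimizer not in OPTIMIZERS:
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


@dataclass
class TrainHistory:
    """One record per completed epoch."""

    records: list = field(default_factory=list)

    columns = ("epoch", "lr", "train_loss", "train_err", "val_err", "val_wf1s")

    def append(self, **kwargs):
        self.records.append({k: kwargs[k] for k in self.columns})

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=self.columns)
            writer.writeheader()
            for rec in self.records:
                writer.writerow(rec)

    def column(self, name):
        return [rec[name] for rec in self.records]


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Linear warm-up, then base_lr * decay_factor ** floor((e - warmup) / every)."""
    if epoch < config.warmup_epochs:
        return config.base_lr * (epoch + 1) / config.warmup_epochs
    steps = (epoch - config.warmup_epochs) // config.decay_every
    return config.base_lr * config.decay_factor ** steps


def compute_loss(p_raw, p_crop, p_erase, labels) -> float:
    """Mean of the three streams' cross-entropies (equal weights)."""
    labels = np.asarray(labels, dtype=int)
    total = 0.0
    for probs in (p_raw, p_crop, p_erase):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != labels.shape[0]:
            raise InvalidInputError("probability batch does not match labels")
        if labels.min() < 0 or labels.max() >= probs.shape[1]:
            raise InvalidInputError("label outside 0..c-1")
        picked = probs[np.arange(len(labels)), labels]
        total += float(np.mean(-np.log(np.maximum(picked, 1e-12))))
    return total / 3.0


# ---------------------------------------------------------------------------
# Raw-stream preprocessing (flips, affine, grayscale, color jitter)


def preprocess_image(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = img
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    # small affine: rotation, isotropic scale, translation
    angle = np.deg2rad(rng.uniform(-15, 15))
    scale = rng.uniform(0.9, 1.1)
    h, w = out.shape[:2]
    shift = rng.uniform(-0.05, 0.05, size=2) * (h, w)
    cos, sin = np.cos(angle) / scale, np.sin(angle) / scale
    mat = np.array([[cos, -sin], [sin, cos]])
    center = np.array([(h - 1) / 2, (w - 1) / 2])
    offset = center - mat @ center + shift
    out = np.stack(
        [ndimage.affine_transform(out[..., ch], mat, offset=offset, order=1, mode="nearest")
         for ch in range(out.shape[2])], axis=-1)
    if rng.random() < 0.1:
        out = np.repeat(out.mean(axis=2, keepdims=True), 3, axis=2)
    gain = rng.uniform(0.9, 1.1, size=3)
    bias = rng.uniform(-0.05, 0.05, size=3)
    return np.clip(out * gain + bias, 0.0, 1.0)


def _build_streams(model, images, A, rng, threshold):
    crops = np.empty_like(images)
    erases = np.empty_like(images)
    for i, img in enumerate(images):
        _, fk_star = attention.select_augmentation_map(A[i], rng=rng, mode="random")
        crops[i] = augment.attention_crop(img, fk_star, threshold)
        erases[i] = augment.attention_erase(img, fk_star, threshold)
    return crops, erases


def ternary_forward(model, images, labels=None, rng=None, threshold: float = 0.5):
    """Forward the raw/crop/erase streams; returns (p_raw, p_crop, p_erase, A).

    Phase-I: raw images produce predictions and attention maps. A map index
    is drawn per image from ``rng``; the resulting crop/erase wrappings are
    data (no gradient through mask construction). Phase-II forwards both
    through the same model.
    """
    del labels  # labels only matter for the loss, kept for interface symmetry
    if len(np.asarray(images)) == 0:
        raise InvalidInputError("empty batch")
    rng = rng or np.random.default_rng(0)
    images = np.asarray(images, dtype=DTYPE)
    scores_raw, A, _, _ = model.forward_batch(images)
    crops, erases = _build_streams(model, images, A, rng, threshold)
    scores_crop, _, _, _ = model.forward_batch(crops)
    scores_erase, _, _, _ = model.forward_batch(erases)
    return softmax(scores_raw), softmax(scores_crop), softmax(scores_erase), A


def _train_step(model, optimizer, images, labels, rng, config):
    """One optimization step; returns (loss, raw-stream error count)."""
    n = len(images)
    c = model.c
    onehot = np.zeros((n, c), dtype=DTYPE)
    onehot[np.arange(n), labels] = 1.0

    scores_raw, A, _, cache_raw = model.forward_batch(images, train=True)
    p_raw = softmax(scores_raw)
    model.zero_grad()
    if config.ternary and model.use_attention:
        crops, erases = _build_streams(model, images, A, rng, config.threshold)
        scores_crop, _, _, cache_crop = model.forward_batch(crops, train=True)
        scores_erase, _, _, cache_erase = model.forward_batch(erases, train=True)
        p_crop, p_erase = softmax(scores_crop), softmax(scores_erase)
        loss = compute_loss(p_raw, p_crop, p_erase, labels)
        for probs, cache in ((p_raw, cache_raw), (p_crop, cache_crop),
                             (p_erase, cache_erase)):
            model.backward_batch(((probs - onehot) / (3.0 * n)).astype(DTYPE), cache)
    else:
        picked = p_raw[np.arange(n), labels]
        loss = float(np.mean(-np.log(np.maximum(picked, 1e-12))))
        model.backward_batch(((p_raw - onehot) / n).astype(DTYPE), cache_raw)
    optimizer.step()
    errors = int(np.sum(np.argmax(p_raw, axis=1) != labels))
    return loss, errors


def evaluate_model(model, images, labels, threshold: float = 0.5):
    """Deterministic (max-energy) voted evaluation: (error rate, WF1S, preds)."""
    if model.use_attention:
        preds = inference.predict(model, images, mode="max_energy", threshold=threshold)
        y_pred = inference.voted_labels(preds)
    else:
        scores, _, _, _ = model.forward_batch(np.asarray(images, dtype=DTYPE))
        y_pred = np.argmax(scores, axis=1)
        preds = None
    labels = np.asarray(labels, dtype=int)
    err = float(np.mean(y_pred != labels))
    wf1s = metrics.weighted_f1(labels, y_pred, model.c)
    return err, wf1s, preds


def train(model, train_set, val_set, config: TrainConfig):
    """Run the training loop; returns (best-validation model, TrainHistory).

    ``train_set`` / ``val_set`` are ``(images, labels)`` with images as an
    (n, H, W, 3) float array in [0, 1].
    """
    config.validate()
    train_images, train_labels = (np.asarray(train_set[0], dtype=DTYPE),
                                  np.asarray(train_set[1], dtype=int))
    val_images, val_labels = (np.asarray(val_set[0], dtype=DTYPE),
                              np.asarray(val_set[1], dtype=int))
    if len(train_images) == 0 or len(val_images) == 0:
        raise ConfigError("datasets must be nonempty")
    if train_labels.max() >= model.c or val_labels.max() >= model.c:
        raise InvalidInputError("label outside the model's class range")

    shuffle_rng = np.random.default_rng([config.seed, 0])
    k_rng = np.random.default_rng([config.seed, 1])
    pre_rng = np.random.default_rng([config.seed, 2])

    optimizer = OPTIMIZERS[config.optimizer](
        model.parameters(), lr=config.base_lr, weight_decay=config.weight_decay)
    history = TrainHistory()
    best_wf1s, best_state, since_best = -1.0, None, 0

    for epoch in range(config.epochs):
        optimizer.lr = lr_at_epoch(config, epoch)
        order = shuffle_rng.permutation(len(train_images))
        total_loss, total_err, n_batches = 0.0, 0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = train_images[idx]
            if config.preprocess:
                batch = np.stack([preprocess_image(img, pre_rng) for img in batch])
                batch = batch.astype(DTYPE)
            loss, errors = _train_step(model, optimizer, batch, train_labels[idx],
                                       k_rng, config)
            total_loss += loss
            total_err += errors
            n_batches += 1
        val_err, val_wf1s, _ = evaluate_model(model, val_images, val_labels,
                                              config.threshold)
        history.append(epoch=epoch, lr=optimizer.lr,
                       train_loss=total_loss / n_batches,
                       train_err=total_err / len(order),
                       val_err=val_err, val_wf1s=val_wf1s)
        if val_wf1s > best_wf1s:
            best_wf1s = val_wf1s
            best_state = [p.data.copy() for p in model.parameters()]
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break
    if best_state is not None:
        for p, data in zip(model.parameters(), best_state):
            p.data = data
    return model, history
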