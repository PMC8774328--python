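"""Coarse-to-fine prediction with plurality voting.

At test time each image is classified three times by the same network:
once raw, once after attention-guided cropping, once after attention
erasing. The final label is the plurality of the three argmax labels.
With two classes a three-voter tie is impossible; with c >= 3 a full
three-way disagreement is resolved by the argmax of the mean of the three
probability vectors.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass

import numpy as np

from . import attention, augment
from .exceptions import InvalidInputError
from .nn import softmax


@dataclass
class TernaryPrediction:
    """Probabilities and labels for the raw/crop/erase streams of one image."""

    p_raw: np.ndarray
    p_crop: np.ndarray
    p_erase: np.ndarray
    voted_label: int
    vote_detail: tuple  # the three per-stream argmax labels


def vote(p_raw, p_crop, p_erase) -> int:
    """Plurality of the three stream labels; three-way ties by mean argmax."""
    vectors = [np.asarray(p, dtype=float) for p in (p_raw, p_crop, p_erase)]
    c = vectors[0].shape[-1]
    if any(v.ndim != 1 or v.shape[0] != c for v in vectors):
        raise InvalidInputError("the three probability vectors must share one length")
    labels = [int(np.argmax(v)) for v in vectors]
    winner, count = Counter(labels).most_common(1)[0]
    if count >= 2:
        return winner
    return int(np.argmax(np.mean(vectors, axis=0)))


def predict(model, images: np.ndarray, mode: str = "max_energy",
            rng: np.random.Generator | None = None, threshold: float = 0.5,
            batch_size: int = 64) -> list[TernaryPrediction]:
    """Run the three streams on a batch of H x W x 3 images and vote.

    ``mode`` picks the attention map guiding crop/erase: ``max_energy``
    (deterministic default) or ``random`` (requires ``rng``).
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[None]
    out: list[TernaryPrediction] = []
    for start in range(0, len(images), batch_size):
        chunk = images[start : start + batch_size]
        scores_raw, A, _, _ = model.forward_batch(chunk)
        crops = np.empty_like(chunk)
        erases = np.empty_like(chunk)
        for i, img in enumerate(chunk):
            _, fk_star = attention.select_augmentation_map(A[i], rng=rng, mode=mode)
            crops[i] = augment.attention_crop(img, fk_star, threshold)
            erases[i] = augment.attention_erase(img, fk_star, threshold)
        scores_crop, _, _, _ = model.forward_batch(crops)
        scores_erase, _, _, _ = model.forward_batch(erases)
        p_raw = softmax(scores_raw)
        p_crop = softmax(scores_crop)
        p_erase = softmax(scores_erase)
        for i in range(len(chunk)):
            detail = (int(np.argmax(p_raw[i])), int(np.argmax(p_crop[i])),
                      int(np.argmax(p_erase[i])))
            out.append(TernaryPrediction(
                p_raw=p_raw[i], p_crop=p_crop[i], p_erase=p_erase[i],
                voted_label=vote(p_raw[i], p_crop[i], p_erase[i]),
                vote_detail=detail,
            ))
    return out


def voted_labels(predictions: list[TernaryPrediction]) -> np.ndarray:
    return np.array([p.voted_label for p in predictions])


def stream_labels(predictions: list[TernaryPrediction]):
    """Per-stream argmax labels as three arrays (raw, crop, erase)."""
    detail = np.array([p.vote_detail for p in predictions])
    return detail[:, 0], detail[:, 1], detail[:, 2]


def mean_positive_scores(predictions: list[TernaryPrediction]) -> np.ndarray:
    """Mean of the three streams' class-1 probabilities (binary AUC input)."""
    return np.array(
        [(p.p_raw[1] + p.p_crop[1] + p.p_erase[1]) / 3.0 for p in predictions]
    )


def write_predictions_csv(path, predictions: list[TernaryPrediction],
                          image_paths: list[str]) -> None:
    c = len(predictions[0].p_raw) if predictions else 0
    header = (["image_path", "label_raw", "label_crop", "label_erase", "label_voted"]
              + [f"p_raw_{j}" for j in range(c)]
              + [f"p_crop_{j}" for j in range(c)]
              + [f"p_erase_{j}" for j in range(c)])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for img_path, pred in zip(image_paths, predictions):
            row = [img_path, pred.vote_detail[0], pred.vote_detail[1],
                   pred.vote_detail[2], pred.voted_label]
            row += [f"{v:.6f}" for v in pred.p_raw]
            row += [f"{v:.6f}" for v in pred.p_crop]
            row += [f"{v:.6f}" for v in pred.p_erase]
            writer.writerow(row)
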