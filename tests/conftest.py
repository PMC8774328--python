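"""Shared fixtures.

The scaled-down end-to-end experiment (synthetic dataset, toy backbone,
ternary training) is expensive, so it runs once per session and several
tests assert different properties of the same trained model.
"""

import numpy as np
import pytest

from wtdfn import inference, models, synthetic, training


E2E_SEED = 1
E2E_N_PER_CLASS = 300
E2E_SIZE = 64
E2E_M = 4
E2E_EPOCHS = 30


@pytest.fixture(scope="session")
def synthetic_dataset():
    """300 images per class at 64 px with the default generator settings."""
    images, labels, metas, splits = synthetic.generate_arrays(
        E2E_N_PER_CLASS, seed=E2E_SEED)
    return {
        "images": images.astype(np.float32),
        "labels": labels,
        "metas": metas,
        "splits": np.array(splits),
    }


@pytest.fixture(scope="session")
def trained_toy(synthetic_dataset):
    """Ternary-trained toy model plus its test-split predictions."""
    ds = synthetic_dataset
    tr = ds["splits"] == "train"
    va = ds["splits"] == "val"
    te = ds["splits"] == "test"
    model = models.build_wtdfn("toy_cnn", M=E2E_M, c=2, seed=E2E_SEED,
                               input_resolution=E2E_SIZE,
                               class_names=list(synthetic.CLASS_NAMES))
    config = training.TrainConfig(epochs=E2E_EPOCHS, batch_size=32, base_lr=0.003,
                                  M=E2E_M, seed=E2E_SEED, input_resolution=E2E_SIZE)
    model, history = training.train(
        model, (ds["images"][tr], ds["labels"][tr]),
        (ds["images"][va], ds["labels"][va]), config)
    predictions = inference.predict(model, ds["images"][te])
    return {
        "model": model,
        "history": history,
        "config": config,
        "predictions": predictions,
        "test_labels": ds["labels"][te],
        "test_indices": np.flatnonzero(te),
        "dataset": ds,
    }
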