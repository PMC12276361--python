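import numpy as np
import pytest

from chromodyn import RenderConfig, SimulationConfig, TrainConfig
from chromodyn.synthetic import make_classification_dataset
from chromodyn.classifier.model import render_dataset, train_classifier


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


# ---------------------------------------------------------------------------
# Trained scaled-down CNN, shared by the validation-accuracy check and the
# model-behaviour tests (rotation invariance, baseline agreement). Training
# happens once per session; sizes follow the desk-scale protocol: 300 tracks
# per class, 23 rotations, 128-px canvas, lr 0.0005 / batch 16, with the
# optimizer-step cap chosen for a single CPU core.
# ---------------------------------------------------------------------------

TRAINED_SCALE = {"n_per_class": 300, "image_size": 128, "max_steps": 400}


@pytest.fixture(scope="session")
def trained_cnn():
    root = np.random.SeedSequence(1)
    s_data, s_train = root.spawn(2)
    sim_cfg = SimulationConfig(seed=int(s_data.generate_state(1)[0] % 2**31))
    collection = make_classification_dataset(
        sim_cfg, TRAINED_SCALE["n_per_class"], seed=s_data)
    render_cfg = RenderConfig(canvas=TRAINED_SCALE["image_size"])
    train_cfg = TrainConfig(
        image_size=TRAINED_SCALE["image_size"],
        epochs=1,
        max_steps=TRAINED_SCALE["max_steps"],
        seed=int(s_train.generate_state(1)[0] % 2**31),
    )
    images, labels, _ = render_dataset(collection, render_cfg,
                                       train_cfg.n_rotations)
    model, history = train_classifier(images, labels, train_cfg)
    return {
        "model": model,
        "history": history,
        "render_cfg": render_cfg,
        "train_cfg": train_cfg,
        "sim_cfg": sim_cfg,
        "collection": collection,
    }
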