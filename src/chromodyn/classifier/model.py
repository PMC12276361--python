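"""The trajectory-classification CNN: architecture, training and inference.

Architecture (input canvas x canvas x 3):

    C1 8x8-32, C2 5x5-64, C3 2x2-128, C4 2x2-256, C5 2x2-512,

each convolution followed by 2x2 max pooling, batch normalization and
ReLU; then adaptive max pooling to 3x3, flatten (4,608 features) and a
dense 3-way softmax head. At 512 x 512 input the network holds exactly
762,275 trainable parameters (746,464 convolutional + 1,984 batch-norm
affine + 13,827 head); the count is input-size independent thanks to the
adaptive pooling, which is what makes reduced-resolution desk-scale
training equivalent in shape.

Training follows the published recipe: coordinate-level rotation
augmentation, shuffling, an 80/20 train/validation split applied after
augmentation, Adam at learning rate 0.0005 with batch size 16 and
cross-entropy loss, keeping the snapshot with the best validation
accuracy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from ..config import RenderConfig, TrainConfig
from ..tracks import Trajectory, CLASS_NAMES
from . import nn
from .render import augment_rotations, render, standardize

logger = logging.getLogger(__name__)

CONV_SPECS = ((8, 32), (5, 64), (2, 128), (2, 256), (2, 512))


@dataclass
class TrajectoryLabel:
    label: str
    probabilities: np.ndarray | None

    def __post_init__(self) -> None:
        if self.probabilities is not None:
            self.probabilities = np.asarray(self.probabilities, dtype=float)
            if np.any(self.probabilities < 0) or \
               abs(self.probabilities.sum() - 1.0) > 1e-6:
                raise ValueError("probabilities must be non-negative and sum to 1")


def build_model(cfg: TrainConfig | None = None,
                image_size: int | None = None) -> nn.Sequential:
    """Build the five-conv-layer classifier for the given input size."""
    cfg = cfg or TrainConfig()
    size = image_size or cfg.image_size
    if size % 32 != 0 or size < 32:
        raise ValueError("image_size must be a positive multiple of 32")
    rng = np.random.default_rng(cfg.seed)
    layers: list = []
    in_ch = 3
    for li, (k, filters) in enumerate(CONV_SPECS):
        layers.append(nn.Conv2D(in_ch, filters, k, rng, first_layer=(li == 0)))
        layers.append(nn.MaxPool2())
        layers.append(nn.BatchNorm2D(filters))
        layers.append(nn.ReLU())
        in_ch = filters
    layers.append(nn.AdaptiveMaxPool(3))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(3 * 3 * 512, 3, rng))
    return nn.Sequential(layers)


def count_parameters(model: nn.Sequential) -> int:
    return model.n_parameters()


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------

def render_dataset(collection, render_cfg: RenderConfig,
                   n_rotations: int = 23, include_original: bool = False):
    """Render a labeled collection into a uint8 image stack with labels.

    Each trajectory is standardized and replaced by its ``n_rotations``
    coordinate-level rotations (k·2π/24, k = 1..n); with
    ``include_original`` the unrotated orientation is added too. Returns
    ``(images, labels, track_index)`` where images is
    (n, canvas, canvas, 3) uint8 and labels are integer class indices.
    """
    images, labels, origin = [], [], []
    name_to_idx = {n: i for i, n in enumerate(CLASS_NAMES)}
    for tidx, (traj, lab) in enumerate(zip(collection.tracks, collection.labels)):
        std = standardize(traj)
        variants = ([std] if include_original else []) + \
            augment_rotations(std, n_rotations)
        for var in variants:
            img = render(var, render_cfg)
            images.append((img * 255.0 + 0.5).astype(np.uint8))
            labels.append(name_to_idx[lab])
            origin.append(tidx)
    return (np.stack(images), np.asarray(labels, dtype=np.int64),
            np.asarray(origin, dtype=np.int64))


def _to_input(batch_u8: np.ndarray) -> np.ndarray:
    """uint8 NHWC images -> float32 NHWC in [0, 1]."""
    return batch_u8.astype(np.float32) / 255.0


# ---------------------------------------------------------------------------
# Training / inference
# ---------------------------------------------------------------------------

def evaluate(model: nn.Sequential, images_u8: np.ndarray, labels: np.ndarray,
             batch_size: int = 64) -> float:
    """Classification accuracy in eval mode (running batch-norm stats)."""
    correct = 0
    for start in range(0, len(labels), batch_size):
        xb = _to_input(images_u8[start:start + batch_size])
        logits = model.forward(xb, train=False)
        correct += int(np.sum(np.argmax(logits, axis=1) ==
                              labels[start:start + batch_size]))
    return correct / len(labels)


def train_classifier(images_u8: np.ndarray, labels: np.ndarray,
                     cfg: TrainConfig, eval_every: int | None = None):
    """Train the CNN on rendered images; returns (model, history).

    The dataset is shuffled with the config seed and split
    ``cfg.split`` / ``1 - cfg.split`` into training and validation *after*
    augmentation. Optimization uses Adam at ``cfg.learning_rate`` with
    ``cfg.batch_size`` and cross-entropy loss for ``cfg.epochs`` epochs
    (optionally capped at ``cfg.max_steps`` optimizer steps). The returned
    model carries the best-validation-accuracy snapshot; ``history`` holds
    the loss curve and validation accuracies. Deterministic given the seed.
    """
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    rng = np.random.default_rng(cfg.seed)
    n = len(labels)
    order = rng.permutation(n)
    n_train = int(round(cfg.split * n))
    train_idx, val_idx = order[:n_train], order[n_train:]
    if len(val_idx) == 0:
        raise ValueError("validation split is empty")
    size = images_u8.shape[1]
    model = build_model(cfg, image_size=size)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    history = {"loss": [], "val_accuracy": [], "val_steps": []}
    best = {"acc": -1.0, "state": None}

    def _evaluate_and_snapshot(step: int) -> None:
        acc = evaluate(model, images_u8[val_idx], labels[val_idx],
                       cfg.eval_batch_size)
        history["val_accuracy"].append(acc)
        history["val_steps"].append(step)
        if acc > best["acc"]:
            best["acc"] = acc
            best["state"] = model.state_dict()
        logger.info("step %d: validation accuracy %.4f", step, acc)

    step = 0
    done = False
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(train_idx))
        for start in range(0, len(perm), cfg.batch_size):
            idx = train_idx[perm[start:start + cfg.batch_size]]
            if len(idx) < 2:
                continue  # batch-norm needs at least 2 samples
            xb = _to_input(images_u8[idx])
            logits = model.forward(xb, train=True)
            loss, grad, _ = nn.cross_entropy(logits, labels[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at step {step}")
            model.backward(grad)
            opt.step()
            history["loss"].append(loss)
            step += 1
            if eval_every and step % eval_every == 0:
                _evaluate_and_snapshot(step)
            if cfg.max_steps is not None and step >= cfg.max_steps:
                done = True
                break
        if not done:
            _evaluate_and_snapshot(step)
        if done:
            break
    if done or not history["val_steps"] or history["val_steps"][-1] != step:
        _evaluate_and_snapshot(step)
    model.load_state(best["state"])
    history["best_val_accuracy"] = best["acc"]
    return model, history


def classify(model: nn.Sequential, traj: Trajectory,
             render_cfg: RenderConfig) -> TrajectoryLabel:
    """Standardize, render and forward one trajectory.

    A blank rendering (single-point track) yields the label
    ``"unclassifiable"`` with no probabilities; callers exclude those
    downstream.
    """
    img = render(standardize(traj), render_cfg)
    if not np.any(img):
        logger.info("classify: track %s rendered blank", traj.track_id)
        return TrajectoryLabel("unclassifiable", None)
    logits = model.forward(img.astype(np.float32)[None], train=False)
    probs = nn.softmax(logits)[0]
    return TrajectoryLabel(CLASS_NAMES[int(np.argmax(probs))], probs)


def classify_batch(model: nn.Sequential, trajs, render_cfg: RenderConfig,
                   batch_size: int = 64) -> list:
    """Vectorized ``classify`` over many trajectories."""
    results: list = [None] * len(trajs)
    todo, imgs = [], []
    for i, traj in enumerate(trajs):
        img = render(standardize(traj), render_cfg)
        if not np.any(img):
            results[i] = TrajectoryLabel("unclassifiable", None)
        else:
            todo.append(i)
            imgs.append(img)
    for start in range(0, len(todo), batch_size):
        chunk = todo[start:start + batch_size]
        x = np.stack([imgs[start + k] for k in range(len(chunk))])
        logits = model.forward(x, train=False)
        probs = nn.softmax(logits)
        for row, i in enumerate(chunk):
            results[i] = TrajectoryLabel(
                CLASS_NAMES[int(np.argmax(probs[row]))], probs[row])
    return results


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: nn.Sequential, render_cfg: RenderConfig,
               train_cfg: TrainConfig, path) -> None:
    """Serialize weights plus a manifest embedding the render config, so
    inference can never mismatch the training rasterization."""
    manifest = {
        "format_version": 1,
        "render": {"canvas": render_cfg.canvas,
                   "d_thresholds": list(render_cfg.d_thresholds),
                   "spatial_window": render_cfg.spatial_window,
                   "samples_per_px": render_cfg.samples_per_px,
                   "line_width": render_cfg.line_width},
        "train": {"image_size": train_cfg.image_size,
                  "learning_rate": train_cfg.learning_rate,
                  "batch_size": train_cfg.batch_size,
                  "seed": train_cfg.seed},
    }
    arrays = {}
    for li, entry in enumerate(model.state_dict()):
        for pi, arr in enumerate(entry):
            arrays[f"l{li:02d}_p{pi}"] = arr
    np.savez(path, manifest=json.dumps(manifest), **arrays)


def load_model(path):
    """Returns (model, RenderConfig, manifest dict)."""
    data = np.load(path, allow_pickle=False)
    manifest = json.loads(str(data["manifest"]))
    rcfg = RenderConfig(
        canvas=manifest["render"]["canvas"],
        d_thresholds=tuple(manifest["render"]["d_thresholds"]),
        spatial_window=manifest["render"]["spatial_window"],
        samples_per_px=manifest["render"]["samples_per_px"],
        line_width=manifest["render"].get("line_width", 1.0),
    )
    tcfg = TrainConfig(image_size=manifest["train"]["image_size"],
                       seed=manifest["train"]["seed"])
    model = build_model(tcfg, image_size=tcfg.image_size)
    state = []
    li = 0
    for layer in model.layers:
        entry = [p["w"] for p in layer.params]
        if isinstance(layer, nn.BatchNorm2D):
            entry = entry + [layer.running_mean, layer.running_var]
        state.append([data[f"l{li:02d}_p{pi}"] for pi in range(len(entry))])
        li += 1
    model.load_state(state)
    return model, rcfg, manifest
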