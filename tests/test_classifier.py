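"""Rendering, the numpy NN layers, and the segment-threshold baseline."""

import numpy as np
import pytest

from chromodyn import RenderConfig, SimulationConfig, TrainConfig, Trajectory
from chromodyn.classifier import (
    augment_rotations,
    baseline_classify_segments,
    build_model,
    channel_for_diffusion,
    count_parameters,
    instantaneous_diffusion,
    map_segment_states,
    render,
    segment_states,
    standardize,
)
from chromodyn.classifier import nn
from chromodyn.classifier.model import TrajectoryLabel, save_model, load_model
from chromodyn.synthetic import simulate_population


def _traj(x, y, dt=0.01):
    return Trajectory("t", np.arange(len(x)), x, y, dt)


# ---------------------------------------------------------------------------
# Instantaneous diffusion and color partition
# ---------------------------------------------------------------------------

def test_instantaneous_diffusion_examples():
    assert instantaneous_diffusion(0.2, 0.0, 0.01) == pytest.approx(1.0)
    assert instantaneous_diffusion(0.0, 0.0, 0.01) == 0.0
    assert instantaneous_diffusion(0.3, 0.4, 0.01) == pytest.approx(6.25)
    with pytest.raises(ValueError):
        instantaneous_diffusion(0.1, 0.1, 0.0)


def test_color_partition_boundaries():
    """Boundary values belong to the lower-named channel: red <= 0.5 < green <= 1."""
    assert channel_for_diffusion(0.2) == 0
    assert channel_for_diffusion(0.5) == 0
    assert channel_for_diffusion(0.75) == 1
    assert channel_for_diffusion(1.0) == 1
    assert channel_for_diffusion(6.25) == 2
    d = np.array([0.0, 0.5, 0.500001, 1.0, 1.000001])
    assert channel_for_diffusion(d).tolist() == [0, 0, 1, 1, 2]


# ---------------------------------------------------------------------------
# Standardization and rotation augmentation
# ---------------------------------------------------------------------------

def test_standardize_translates_to_origin_and_is_idempotent():
    traj = _traj([2.0, 2.5, 3.0], [1.0, 0.5, 1.5])
    std = standardize(traj)
    assert (std.x[0], std.y[0]) == (0.0, 0.0)
    assert np.allclose(np.diff(std.x), np.diff(traj.x))
    again = standardize(std)
    assert np.array_equal(again.x, std.x) and np.array_equal(again.y, std.y)


def test_rotation_full_orbit_returns_to_input():
    traj = standardize(_traj([0.0, 0.3, 0.1], [0.0, -0.2, 0.4]))
    rots = augment_rotations(traj, 24)  # 24th rotation = full circle
    assert np.allclose(rots[-1].x, traj.x, atol=1e-12)
    assert np.allclose(rots[-1].y, traj.y, atol=1e-12)


def test_rotations_preserve_step_lengths_and_colors():
    rng = np.random.default_rng(0)
    traj = standardize(_traj(rng.standard_normal(10) * 0.1,
                             rng.standard_normal(10) * 0.1))
    base = instantaneous_diffusion(np.diff(traj.x), np.diff(traj.y), 0.01)
    for rot in augment_rotations(traj, 23):
        d = instantaneous_diffusion(np.diff(rot.x), np.diff(rot.y), 0.01)
        assert d == pytest.approx(base, rel=1e-12)


def test_augmentation_count_per_trajectory():
    traj = standardize(_traj([0.0, 0.1], [0.0, 0.0]))
    assert len(augment_rotations(traj, 23)) == 23


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

CFG64 = RenderConfig(canvas=64)


def test_render_single_point_is_blank():
    img = render(standardize(_traj([0.0], [0.0])), CFG64)
    assert not np.any(img)


def test_render_slow_step_only_red_channel():
    # D = 0.25 um^2/s -> red
    img = render(standardize(_traj([0.0, 0.1], [0.0, 0.0])), CFG64)
    assert np.any(img[:, :, 0])
    assert not np.any(img[:, :, 1]) and not np.any(img[:, :, 2])


def test_render_mixed_track_two_monochromatic_segments():
    # steps with D 0.25 (red) then 6.25 (blue)
    img = render(standardize(_traj([0.0, 0.1, 0.6], [0.0, 0.0, 0.0])), CFG64)
    assert np.any(img[:, :, 0]) and np.any(img[:, :, 2])
    assert not np.any(img[:, :, 1])


def test_render_line_width_thickens_strokes():
    traj = standardize(_traj([0.0, 0.0], [0.0, 1.0]))
    thin = render(traj, RenderConfig(canvas=64, line_width=1.0))
    thick = render(traj, RenderConfig(canvas=64, line_width=3.0))
    # a 3-px stroke covers ~4 bilinear columns vs ~2 for a 1-px stroke
    assert (thick[:, :, 2] > 0).sum() >= 1.9 * (thin[:, :, 2] > 0).sum()
    # stroke width never changes the segment's channel
    assert not np.any(thick[:, :, 0]) and not np.any(thick[:, :, 1])


def test_render_intensities_bounded():
    rng = np.random.default_rng(1)
    traj = standardize(_traj(np.cumsum(rng.standard_normal(30)) * 0.02,
                             np.cumsum(rng.standard_normal(30)) * 0.02))
    img = render(traj, CFG64)
    assert img.min() >= 0.0 and img.max() <= 1.0


def test_render_rot90_equivariance():
    """Rendering a 90-degree-rotated trajectory equals rotating the image."""
    rng = np.random.default_rng(2)
    traj = standardize(_traj(np.cumsum(rng.standard_normal(12)) * 0.03,
                             np.cumsum(rng.standard_normal(12)) * 0.03))
    rot = augment_rotations(traj, 23)[5]  # k=6 -> 90 degrees
    img_rot = render(rot, CFG64)
    # rotating (x, y) by +90deg maps columns/rows of the canvas: compare
    # against numpy's rot90 of the direct rendering (axes: y=row, x=col)
    img = render(traj, CFG64)
    expected = np.rot90(img, k=-1, axes=(0, 1))
    assert np.allclose(img_rot, expected, atol=1e-5)


# ---------------------------------------------------------------------------
# NN building blocks
# ---------------------------------------------------------------------------

def test_parameter_count_breakdown():
    model = build_model(TrainConfig(image_size=128), image_size=128)
    conv = sum(l.w.size + l.b.size for l in model.layers
               if isinstance(l, nn.Conv2D))
    bn = sum(l.gamma.size + l.beta.size for l in model.layers
             if isinstance(l, nn.BatchNorm2D))
    dense = sum(l.w.size + l.b.size for l in model.layers
                if isinstance(l, nn.Dense))
    assert conv == 746_464
    assert bn == 1_984
    assert dense == 13_827
    assert count_parameters(model) == 762_275


def test_forward_softmax_and_channel_semantics():
    model = build_model(TrainConfig(image_size=64, seed=3), image_size=64)
    rng = np.random.default_rng(4)
    x = rng.random((2, 64, 64, 3), dtype=np.float32)
    probs = nn.softmax(model.forward(x, train=False))
    assert probs.sum(axis=1) == pytest.approx([1.0, 1.0])
    permuted = model.forward(x[..., ::-1].copy(), train=False)
    assert not np.allclose(model.forward(x, train=False), permuted)


def test_model_build_rejects_bad_size():
    with pytest.raises(ValueError):
        build_model(image_size=48)


def test_gradients_match_numerical():
    """Analytic gradients of every layer type agree with finite differences."""
    rng = np.random.default_rng(5)
    layers = [nn.Conv2D(3, 4, 3, rng), nn.MaxPool2(), nn.BatchNorm2D(4),
              nn.ReLU(), nn.Conv2D(4, 6, 2, rng), nn.MaxPool2(),
              nn.BatchNorm2D(6), nn.ReLU(), nn.AdaptiveMaxPool(3),
              nn.Flatten(), nn.Dense(54, 3, rng)]
    model = nn.Sequential(layers)
    x = rng.standard_normal((4, 8, 8, 3)).astype(np.float32)
    y = np.array([0, 1, 2, 1])

    def loss():
        l, g, _ = nn.cross_entropy(model.forward(x.copy(), train=True), y)
        return l, g

    _, grad = loss()
    model.backward(grad)
    stored = [(p["w"], p["grad"].copy()) for p in model.params]
    eps = 1e-3
    for w, analytic in stored:
        flat = w.ravel()
        for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            old = flat[i]
            flat[i] = old + eps
            lp, _ = loss()
            flat[i] = old - eps
            lm, _ = loss()
            flat[i] = old
            numeric = (lp - lm) / (2 * eps)
            assert analytic.ravel()[i] == pytest.approx(
                numeric, abs=2e-2 * max(1.0, abs(numeric)))


def test_training_is_deterministic_given_seed():
    from chromodyn.classifier.model import train_classifier

    rng = np.random.default_rng(6)
    images = (rng.random((40, 32, 32, 3)) * 255).astype(np.uint8)
    labels = np.repeat([0, 1], 20)
    cfg = TrainConfig(image_size=32, epochs=1, max_steps=4, seed=9)
    m1, h1 = train_classifier(images, labels, cfg)
    m2, h2 = train_classifier(images, labels, cfg)
    assert h1["loss"] == h2["loss"]
    for p1, p2 in zip(m1.params, m2.params):
        assert np.array_equal(p1["w"], p2["w"])


def test_training_rejects_single_class():
    from chromodyn.classifier.model import train_classifier

    images = np.zeros((10, 32, 32, 3), dtype=np.uint8)
    labels = np.zeros(10, dtype=np.int64)
    with pytest.raises(ValueError):
        train_classifier(images, labels, TrainConfig(image_size=32, seed=0))


def test_model_serialization_roundtrip(tmp_path):
    rcfg = RenderConfig(canvas=32)
    tcfg = TrainConfig(image_size=32, seed=1)
    model = build_model(tcfg, image_size=32)
    path = tmp_path / "model.npz"
    save_model(model, rcfg, tcfg, path)
    loaded, loaded_rcfg, manifest = load_model(path)
    assert loaded_rcfg.canvas == 32
    x = np.random.default_rng(2).random((1, 32, 32, 3), dtype=np.float32)
    assert np.allclose(model.forward(x, train=False),
                       loaded.forward(x, train=False))


# ---------------------------------------------------------------------------
# Baseline classifier
# ---------------------------------------------------------------------------

def test_mapping_rule_strict_examples():
    assert map_segment_states([0, 0, 0]) == "immobile"
    assert map_segment_states([1, 1]) == "mobile"
    assert map_segment_states([0, 1, 0]) == "hybrid"
    with pytest.raises(ValueError):
        map_segment_states([])


def test_baseline_hand_examples():
    # all segments D < 0.5 -> immobile
    slow = _traj([0.0, 0.05, 0.10], [0.0, 0.0, 0.0])
    assert baseline_classify_segments(slow, tolerance=0.0).label == "immobile"
    # D sequence (0.25, 6.25, 0.25) -> hybrid under the strict rule
    mixed = _traj([0.0, 0.1, 0.6, 0.7], [0.0, 0.0, 0.0, 0.0])
    states = segment_states(mixed)
    assert states.tolist() == [0, 1, 0]
    assert map_segment_states(states, tolerance=0.0) == "hybrid"


def test_baseline_probabilities_are_one_hot():
    lab = baseline_classify_segments(_traj([0.0, 0.05], [0.0, 0.0]))
    assert lab.probabilities.sum() == 1.0
    assert lab.label == "immobile"


def test_baseline_accuracy_on_generator_defaults():
    """Threshold baseline recovers >= 95% of ground-truth labels."""
    cfg = SimulationConfig(n_tracks=1500, seed=77)
    coll = simulate_population(cfg)
    correct = total = 0
    for traj, truth in zip(coll.tracks, coll.labels):
        if traj.n_points < 5:
            continue
        total += 1
        correct += baseline_classify_segments(traj).label == truth
    assert correct / total >= 0.95


def test_trajectory_label_validation():
    with pytest.raises(ValueError):
        TrajectoryLabel("immobile", [0.5, 0.2, 0.2])
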