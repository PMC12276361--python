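"""Line segmentation, moments-ellipse thickness and recruitment curves."""

import numpy as np
import pytest

from chromodyn import (
    ImageSimConfig,
    NucleusImageSeries,
    recruitment_curve,
    segment_line,
    simulate_line_images,
    thickness_from_mask,
    thickness_series,
)
from chromodyn.imaging import UnsegmentableFrame


def _brute_force_minor_axis(mask, pixel_size, subsamples=16):
    """Oracle: dense sub-pixel sampling of the mask's second moments."""
    rows, cols = np.nonzero(mask)
    offs = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    rr = np.repeat(rows, subsamples ** 2) + np.tile(
        np.repeat(offs, subsamples), len(rows))
    cc = np.repeat(cols, subsamples ** 2) + np.tile(
        np.tile(offs, subsamples), len(cols))
    r = rr - rr.mean()
    c = cc - cc.mean()
    cov = np.array([[np.mean(r * r), np.mean(r * c)],
                    [np.mean(r * c), np.mean(c * c)]])
    return 4.0 * np.sqrt(np.linalg.eigvalsh(cov)[0]) * pixel_size


def test_two_level_image_segments_exactly():
    frame = np.full((64, 64), 100.0)
    frame[:, 30:34] = 1000.0
    mask = segment_line(frame)
    assert np.array_equal(mask, frame == 1000.0)


def test_pure_noise_image_rejected():
    rng = np.random.default_rng(0)
    frame = rng.normal(100.0, 5.0, size=(64, 64))
    with pytest.raises(UnsegmentableFrame):
        segment_line(frame)
    with pytest.raises(UnsegmentableFrame):
        segment_line(np.full((32, 32), 7.0))


def test_noisy_band_jaccard_overlap():
    """SNR ~10 synthetic band: mask overlaps truth with Jaccard >= 0.9."""
    rng = np.random.default_rng(1)
    truth = np.zeros((96, 96), dtype=bool)
    truth[:, 40:52] = True
    frame = np.where(truth, 1000.0, 100.0) + rng.normal(0, 90.0, (96, 96))
    mask = segment_line(frame)
    jacc = np.logical_and(mask, truth).sum() / np.logical_or(mask, truth).sum()
    assert jacc >= 0.9


def test_rectangle_minor_axis_closed_form():
    """Solid 4-px-tall band -> minor axis 2*4/sqrt(3) px within 2%."""
    mask = np.zeros((64, 64), dtype=bool)
    mask[30:34, 4:60] = True
    ps = 0.16
    got = thickness_from_mask(mask, ps)
    assert got == pytest.approx(2.0 * 4.0 / np.sqrt(3.0) * ps, rel=0.02)
    assert got == pytest.approx(_brute_force_minor_axis(mask, ps), rel=1e-3)


def test_minor_axis_rotation_invariance():
    h, length = 10.0, 50.0
    theta = np.deg2rad(30.0)
    yy, xx = np.mgrid[0:128, 0:128]
    u = (xx - 64) * np.cos(theta) + (yy - 64) * np.sin(theta)
    v = -(xx - 64) * np.sin(theta) + (yy - 64) * np.cos(theta)
    rotated = (np.abs(u) <= length / 2) & (np.abs(v) <= h / 2)
    axis_aligned = np.zeros((128, 128), dtype=bool)
    axis_aligned[59:69, 39:89] = True
    a = thickness_from_mask(rotated, 1.0)
    b = thickness_from_mask(axis_aligned, 1.0)
    assert a == pytest.approx(b, rel=0.03)


def test_disk_minor_axis_equals_diameter():
    yy, xx = np.mgrid[0:64, 0:64]
    disk = (xx - 32.0) ** 2 + (yy - 32.0) ** 2 <= 12.0 ** 2
    # continuous disk of radius R: second moment R^2/4 -> minor axis 2R
    assert thickness_from_mask(disk, 1.0) == pytest.approx(24.0, rel=0.02)


def test_tiny_mask_flagged():
    mask = np.zeros((16, 16), dtype=bool)
    mask[3, 3:6] = True
    with pytest.raises(ValueError):
        thickness_from_mask(mask, 0.16)


def test_constant_width_series_normalizes_to_one():
    cfg = ImageSimConfig(line_width_profile=(1.0, 1.0, 1.0), psf_sigma=0.1,
                         poisson_noise=False, read_noise_sigma=0.0, seed=2)
    series = simulate_line_images(cfg)
    ts = thickness_series(series)
    assert ts.normalized[ts.reference_frame] == 1.0
    assert np.allclose(ts.normalized, 1.0, atol=1e-6)


def test_programmed_width_change_recovered():
    """Width x1.4 at a mid-series frame is reported within 5% at high SNR."""
    widths = (2.0, 2.0, 2.8, 2.0)
    cfg = ImageSimConfig(line_width_profile=widths, pixel_size=0.08,
                         psf_sigma=0.08, intensity_fg=5000.0, seed=3)
    ts = thickness_series(simulate_line_images(cfg))
    assert ts.normalized[2] == pytest.approx(1.4, abs=0.05)
    assert ts.normalized[1] == pytest.approx(1.0, abs=0.05)


def test_line_wider_than_image_rejected():
    with pytest.raises(ValueError):
        ImageSimConfig(image_shape=(32, 32), pixel_size=0.16,
                       line_width_profile=(10.0,))


def _series(frames):
    return NucleusImageSeries(np.asarray(frames, dtype=float), 0.16,
                              np.arange(len(frames), dtype=float),
                              irradiation_frame=1)


def test_recruitment_null_curve_is_flat():
    frame = np.full((32, 32), 50.0)
    nuc_region = np.zeros((32, 32), bool)
    nuc_region[2:30, 2:30] = True
    frame[nuc_region] = 200.0
    series = _series([frame, frame, frame])
    roi = np.zeros((32, 32), bool)
    roi[10:20, 10:20] = True
    nucleus = np.zeros((32, 32), bool)
    nucleus[2:30, 2:30] = True
    background = ~nucleus
    curve = recruitment_curve(series, roi, nucleus, background, [0])
    assert np.allclose(curve.ratio, 1.0)


def test_recruitment_cancels_photobleaching():
    """2x ROI enrichment plus 50% global bleaching still reads as 2x."""
    base = np.full((32, 32), 50.0)
    nucleus = np.zeros((32, 32), bool)
    nucleus[4:28, 4:28] = True
    roi = np.zeros((32, 32), bool)
    roi[12:20, 12:20] = True
    background = ~nucleus
    pre = base.copy()
    pre[nucleus] = 250.0
    post = base.copy()
    # recruitment conserves total nuclear signal: the ROI doubles its
    # background-subtracted intensity while the rest of the nucleus dims,
    # keeping the whole-nucleus mean (the bleaching reference) at 250
    n_nuc, n_roi = nucleus.sum(), roi.sum()
    post[nucleus] = (250.0 * n_nuc - (50.0 + 2.0 * 200.0) * n_roi) / (n_nuc - n_roi)
    post[roi] = 50.0 + 2.0 * 200.0      # 2x enrichment above background
    post_bleached = 0.5 * post          # global photobleaching of the frame
    series = NucleusImageSeries(np.stack([pre, post_bleached]), 0.16,
                                np.array([0.0, 1.0]), irradiation_frame=1)
    curve = recruitment_curve(series, roi, nucleus, background, [0])
    assert curve.ratio[1] == pytest.approx(2.0, rel=1e-6)


def test_recruitment_scale_invariance():
    rng = np.random.default_rng(4)
    frame = rng.uniform(100, 400, size=(32, 32))
    nucleus = np.zeros((32, 32), bool)
    nucleus[4:28, 4:28] = True
    roi = np.zeros((32, 32), bool)
    roi[10:16, 10:16] = True
    background = ~nucleus
    s1 = _series([frame, frame * 3.7])
    curve = recruitment_curve(s1, roi, nucleus, background, [0])
    assert curve.ratio[1] == pytest.approx(1.0, rel=1e-9)


def test_recruitment_requires_disjoint_masks():
    frame = np.full((16, 16), 10.0)
    m = np.ones((16, 16), bool)
    with pytest.raises(ValueError):
        recruitment_curve(_series([frame]), m, m, m, [0])
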