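"""Trajectory preprocessing and rasterization to diffusion-colored images.

A trajectory is standardized (translated so its first point sits at the
origin), optionally augmented by coordinate-level rotations, and drawn on a
square canvas: every pair of consecutive positions becomes an anti-aliased
straight segment placed at sub-pixel precision in exactly one of three
color channels, selected by the instantaneous diffusion coefficient of the
step, D = (dx² + dy²) / (4 Δt):

    red    0 < D <= 0.5 μm²/s
    green  0.5 < D <= 1 μm²/s
    blue   1 μm²/s < D

Rotations are applied to coordinates, not pixels, so they preserve step
lengths (and hence segment colors) exactly and introduce no resampling
distortion.
"""

from __future__ import annotations

import logging

import numpy as np

from ..config import RenderConfig
from ..tracks import Trajectory

logger = logging.getLogger(__name__)


def instantaneous_diffusion(dx, dy, dt: float):
    """Single-step 2-D diffusion estimate (dx² + dy²) / (4 Δt), in μm²/s."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    out = (dx * dx + dy * dy) / (4.0 * dt)
    return float(out) if out.ndim == 0 else out


def channel_for_diffusion(d, thresholds=(0.5, 1.0)):
    """Channel index for a step: 0 red, 1 green, 2 blue (boundaries belong
    to the lower-named channel)."""
    d = np.asarray(d, dtype=float)
    out = np.where(d <= thresholds[0], 0, np.where(d <= thresholds[1], 1, 2))
    return int(out) if out.ndim == 0 else out


def standardize(traj: Trajectory) -> Trajectory:
    """Translate so the first localization is the origin (idempotent)."""
    if traj.n_points < 1:
        raise ValueError("empty trajectory")
    return Trajectory(traj.track_id, traj.frames.copy(),
                      traj.x - traj.x[0], traj.y - traj.y[0],
                      traj.frame_interval)


def rotate(traj: Trajectory, angle: float) -> Trajectory:
    c, s = np.cos(angle), np.sin(angle)
    return Trajectory(traj.track_id, traj.frames.copy(),
                      c * traj.x - s * traj.y, s * traj.x + c * traj.y,
                      traj.frame_interval)


def augment_rotations(traj: Trajectory, n_rotations: int = 23) -> list:
    """``n_rotations`` copies rotated about the origin by k·(2π/24), k = 1..n.

    23 rotations complete a uniform 24-fold orbit together with the
    identity orientation; pairwise distances are preserved exactly.
    """
    step = 2.0 * np.pi / 24.0
    return [rotate(traj, k * step) for k in range(1, n_rotations + 1)]


def _sample_segment(x0, y0, x1, y1, samples_per_px: float):
    """Dense sample points along one segment in canvas-pixel coordinates."""
    length = float(np.hypot(x1 - x0, y1 - y0))
    n_samples = max(2, int(np.ceil(length * samples_per_px)) + 1)
    t = np.linspace(0.0, 1.0, n_samples)
    return x0 + (x1 - x0) * t, y0 + (y1 - y0) * t


def render(traj: Trajectory, cfg: RenderConfig) -> np.ndarray:
    """Rasterize a standardized trajectory to a (canvas, canvas, 3) image.

    The physical window ``cfg.spatial_window`` (μm) is centred on the
    origin and mapped across the canvas; each segment is splatted with
    bilinear (sub-pixel) anti-aliasing into its diffusion-selected channel.
    Out-of-window portions are clipped with a logged warning.

    Accumulated intensity is normalized by the image maximum rather than
    hard-clipped, so pixels revisited by many segments stay brighter than
    single-pass lines: at reduced canvas sizes a dwelling phase collapses
    into a few pixels, and this density contrast is what still
    distinguishes a dwell from an isolated slow step. Intensities lie in
    [0, 1]; a single-point trajectory yields an all-zero image.
    """
    n_px = cfg.canvas
    img = np.zeros((n_px, n_px, 3), dtype=np.float32)
    if traj.n_points < 2:
        logger.warning("render: single-point trajectory %s -> blank image",
                       traj.track_id)
        return img
    scale = (n_px - 1) / cfg.spatial_window
    cx = (n_px - 1) / 2.0
    px = cx + traj.x * scale
    py = cx + traj.y * scale
    d = instantaneous_diffusion(np.diff(traj.x), np.diff(traj.y),
                                traj.frame_interval)
    channels = channel_for_diffusion(d, cfg.d_thresholds)
    per_channel_x = [[], [], []]
    per_channel_y = [[], [], []]
    # strokes wider than 1 px are drawn as parallel sample lines offset
    # perpendicular to the segment
    n_strands = max(1, int(round(cfg.line_width)))
    offsets = np.linspace(-(cfg.line_width - 1) / 2.0,
                          (cfg.line_width - 1) / 2.0, n_strands)
    for k in range(traj.n_points - 1):
        dx, dy = px[k + 1] - px[k], py[k + 1] - py[k]
        norm = np.hypot(dx, dy)
        ux, uy = ((-dy / norm, dx / norm) if norm > 0 else (0.0, 0.0))
        for off in offsets:
            xs, ys = _sample_segment(px[k] + off * ux, py[k] + off * uy,
                                     px[k + 1] + off * ux, py[k + 1] + off * uy,
                                     cfg.samples_per_px)
            per_channel_x[channels[k]].append(xs)
            per_channel_y[channels[k]].append(ys)
    clipped = 0
    w = 1.0 / cfg.samples_per_px
    for ch in range(3):
        if not per_channel_x[ch]:
            continue
        xs = np.concatenate(per_channel_x[ch])
        ys = np.concatenate(per_channel_y[ch])
        inside = (xs >= 0) & (xs <= n_px - 1) & (ys >= 0) & (ys <= n_px - 1)
        clipped += int(np.count_nonzero(~inside))
        xs, ys = xs[inside], ys[inside]
        if len(xs) == 0:
            continue
        j0 = np.floor(xs).astype(np.intp)
        i0 = np.floor(ys).astype(np.intp)
        fx = xs - j0
        fy = ys - i0
        j1 = np.minimum(j0 + 1, n_px - 1)
        i1 = np.minimum(i0 + 1, n_px - 1)
        plane = img[:, :, ch]
        np.add.at(plane, (i0, j0), ((1 - fx) * (1 - fy) * w).astype(np.float32))
        np.add.at(plane, (i0, j1), (fx * (1 - fy) * w).astype(np.float32))
        np.add.at(plane, (i1, j0), ((1 - fx) * fy * w).astype(np.float32))
        np.add.at(plane, (i1, j1), (fx * fy * w).astype(np.float32))
    if clipped:
        logger.debug("render: %d samples of track %s outside the canvas",
                     clipped, traj.track_id)
    peak = float(img.max())
    if peak > 1.0:
        img /= peak
    return img
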