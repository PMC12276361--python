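"""Segment-threshold baseline classifier and the segment-to-track mapping rule.

Per-segment diffusive states (immobile/mobile) are obtained by thresholding
the instantaneous diffusion coefficient of each step — a two-state
reduction of the three color ranges in which the green and blue ranges
collapse to "mobile". Track labels then follow the mapping rule used to
compare per-segment HMM classifications with whole-track ones: a track is
immobile if (essentially) all its segments are immobile, mobile if all are
mobile, and hybrid when its segments switch between classes.

With raw thresholded states the strict all-segments rule is fragile: step
lengths have exponential-like tails, so a genuinely mobile track of ~17
frames has a sizable chance of containing one sub-threshold segment and
would be mislabeled hybrid. ``tolerance`` therefore allows a small minority
fraction of discordant segments before a track stops counting as pure
(default 0.2); ``tolerance = 0`` reproduces the strict published rule and
is appropriate for pre-smoothed (HMM) segment states.
"""

from __future__ import annotations

import numpy as np

from ..tracks import Trajectory
from .model import TrajectoryLabel
from .render import instantaneous_diffusion


def segment_states(traj: Trajectory, threshold: float = 0.5) -> np.ndarray:
    """Per-step states from thresholded instantaneous D: 0 immobile, 1 mobile.

    Only consecutive-frame steps are scored; gap-spanning steps are skipped.
    """
    if traj.n_points < 2:
        raise ValueError("need at least 2 points")
    consecutive = np.diff(traj.frames) == 1
    d = instantaneous_diffusion(np.diff(traj.x)[consecutive],
                                np.diff(traj.y)[consecutive],
                                traj.frame_interval)
    return (np.atleast_1d(d) > threshold).astype(np.int8)


def map_segment_states(states, tolerance: float = 0.0) -> str:
    """Track label from a per-segment state sequence.

    immobile if the mobile fraction is <= tolerance, mobile if the immobile
    fraction is <= tolerance, hybrid otherwise.
    """
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("empty state sequence")
    if not 0.0 <= tolerance < 0.5:
        raise ValueError("tolerance must be in [0, 0.5)")
    frac_mobile = float(np.mean(states))
    if frac_mobile <= tolerance:
        return "immobile"
    if frac_mobile >= 1.0 - tolerance:
        return "mobile"
    return "hybrid"


def baseline_classify_segments(traj: Trajectory, d_threshold: float = 0.5,
                               tolerance: float = 0.2) -> TrajectoryLabel:
    """Threshold-based track classification (no training required)."""
    label = map_segment_states(segment_states(traj, d_threshold), tolerance)
    probs = np.zeros(3)
    probs[("immobile", "hybrid", "mobile").index(label)] = 1.0
    return TrajectoryLabel(label, probs)
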