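"""Configuration objects for simulation, rendering, training and the pipeline.

Defaults encode the acquisition geometry and the calibrated population
structure of the live-cell experiments the simulator emulates: 100 Hz
frames, 160 nm pixels, an immobile subdiffusive majority (fBm,
alpha = 0.59, A = 0.0378 μm²/s^0.59 so the tangent-denoised effective D
equals 0.0078 μm²/s), a fast Brownian minority (D = 3.661 μm²/s), a switching
hybrid class, class fractions 84/7/9 % (immobile/hybrid/mobile) and
geometric track-length attrition with mean 17 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

from .tracks import RectROI


def tangent_effective_diffusion(A: float, alpha: float,
                                t0: float = 0.1, t1: float = 1.0) -> float:
    """Mean of d/dt (A t^alpha) / 4 over [t0, t1] — the denoised effective D.

    Closed form: (1/(t1-t0)) * ∫ A·alpha·t^(alpha-1)/4 dt = A (t1^a - t0^a) / (4 (t1 - t0)).
    """
    if alpha == 0:
        return 0.0
    return A * (t1 ** alpha - t0 ** alpha) / (4.0 * (t1 - t0))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic single-particle-tracking experiment."""

    frame_interval: float = 0.01          # s (100 Hz)
    pixel_size: float = 0.160             # μm
    class_fractions: tuple = (0.84, 0.07, 0.09)   # (immobile, hybrid, mobile)
    immobile_alpha: float = 0.59          # MSD exponent of the slow population
    immobile_A: float = 0.0378            # μm²/s^alpha; tangent D == 0.0078 μm²/s
    mobile_D: float = 3.661               # μm²/s, Brownian fast population
    hybrid_switch_rates: tuple = (0.05, 0.10)     # per-frame (imm->mob, mob->imm)
    noise_sigma: float = 0.025            # μm localization error per coordinate
    track_survival_p: float = 15.0 / 16.0 # per-frame survival; mean length 17
    n_tracks: int = 2400
    field_size: tuple = (12.0, 10.0)      # μm extent over which tracks start
    damage_effect: float = 1.0            # step-amplitude factor inside the ROI
    roi: RectROI | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.class_fractions, dtype=float)
        if fr.size != 3 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("class_fractions must be 3 non-negative values summing to 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 < self.track_survival_p <= 1.0:
            raise ValueError("track_survival_p must be in (0, 1]")
        if not 0.0 < self.immobile_alpha <= 2.0:
            raise ValueError("immobile_alpha must be in (0, 2]")
        d_imm = self.immobile_effective_D
        if d_imm > 0 and self.mobile_D < 10.0 * d_imm:
            raise ValueError(
                "mobile_D must exceed the immobile effective D by >= 10x "
                f"(got {self.mobile_D} vs {d_imm:.4g})"
            )

    @property
    def immobile_effective_D(self) -> float:
        """Tangent-denoised effective D of the immobile class (μm²/s)."""
        return tangent_effective_diffusion(self.immobile_A, self.immobile_alpha)

    @property
    def mean_track_length(self) -> float:
        p = self.track_survival_p
        return 2.0 + p / (1.0 - p) if p < 1 else float("inf")


@dataclass
class ImageSimConfig:
    """Synthetic photoactivated-line image series (stand-in fixture for
    H2B-PAGFP micro-irradiation movies; no real optics model intended)."""

    image_shape: tuple = (128, 128)       # px (rows, cols)
    pixel_size: float = 0.160             # μm
    line_width_profile: tuple = (1.0,)    # μm per timepoint
    psf_sigma: float = 0.2                # μm
    intensity_fg: float = 1000.0
    intensity_bg: float = 100.0
    poisson_noise: bool = True
    read_noise_sigma: float = 5.0         # additive Gaussian, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        widths = np.asarray(self.line_width_profile, dtype=float)
        if np.any(widths <= 0):
            raise ValueError("line_width_profile must be positive")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        extent = self.image_shape[1] * self.pixel_size
        if np.any(widths >= extent):
            raise ValueError("line wider than the image")


@dataclass
class RenderConfig:
    """Rasterization of trajectories to diffusion-colored RGB images.

    Each inter-frame segment is drawn in exactly one channel selected by
    its instantaneous diffusion coefficient: red for D <= d_thresholds[0],
    green for d_thresholds[0] < D <= d_thresholds[1], blue above.
    """

    canvas: int = 512                     # square canvas, px
    d_thresholds: tuple = (0.5, 1.0)      # μm²/s
    spatial_window: float = 5.0           # μm mapped across the canvas
    samples_per_px: float = 3.0           # sub-pixel splatting density
    line_width: float = 1.0               # stroke width in canvas px

    def __post_init__(self) -> None:
        lo, hi = self.d_thresholds
        if not 0 < lo < hi:
            raise ValueError("d_thresholds must be strictly increasing and positive")
        if self.canvas < 4:
            raise ValueError("canvas too small")
        if self.line_width < 1.0:
            raise ValueError("line_width must be >= 1 px")


@dataclass
class TrainConfig:
    """CNN training hyper-parameters (published values as defaults)."""

    learning_rate: float = 0.0005
    batch_size: int = 16
    n_rotations: int = 23
    split: float = 0.8                    # train fraction, applied after augmentation
    epochs: int = 1
    max_steps: int | None = None          # optional cap on optimizer steps
    image_size: int = 512                 # reducible for desk-scale runs
    eval_batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split < 1.0:
            raise ValueError("split must be in (0, 1)")
        if self.n_rotations < 0:
            raise ValueError("n_rotations must be >= 0")
        if self.image_size % 32 != 0:
            raise ValueError("image_size must be divisible by 32 (five pooling stages)")


@dataclass
class AnalysisConfig:
    """Downstream analysis knobs shared by the pipeline."""

    min_track_points: int = 5
    n_resamples: int = 10_000
    trim_fraction: float = 0.2
    bootstrap_ci: float = 0.95
    msd_max_lag: int = 20
    fit_range: tuple = (0.0, 5.0)         # s, short-time (subdiffusive) window
    min_pairs_per_lag: int = 5
    jump_class: str = "immobile"


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    classifier: str = "baseline"          # "baseline" | "cnn" | "truth"
    timepoints: tuple = ("before", "1min", "5min", "10min")
    # measured mean-jump ratio targets per timepoint (damage response profile)
    jump_ratio_profile: Mapping[str, float] = field(
        default_factory=lambda: {"before": 1.0, "1min": 1.5, "5min": 1.01, "10min": 0.93}
    )
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["simulation"].get("roi") is not None:
            d["simulation"]["roi"] = asdict(self.simulation.roi)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.get("simulation", {})
        roi = sim.get("roi")
        if roi is not None:
            sim["roi"] = RectROI(**roi)
        kw = {}
        if sim:
            kw["simulation"] = SimulationConfig(**sim)
        if "analysis" in raw:
            kw["analysis"] = AnalysisConfig(**raw["analysis"])
        if "render" in raw:
            kw["render"] = RenderConfig(**raw["render"])
        if "train" in raw:
            kw["train"] = TrainConfig(**raw["train"])
        for key in ("classifier", "seed"):
            if key in raw:
                kw[key] = raw[key]
        if "timepoints" in raw:
            kw["timepoints"] = tuple(raw["timepoints"])
        if "jump_ratio_profile" in raw:
            kw["jump_ratio_profile"] = dict(raw["jump_ratio_profile"])
        return cls(**kw)
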