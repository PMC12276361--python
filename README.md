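# chromodyn

Multiscale chromatin-dynamics analysis for live-cell imaging: classify
single-nucleosome trajectories, quantify anomalous diffusion, compare
mobility between experimental conditions with robust bootstrap statistics,
and measure chromatin compaction from photoactivated-line image series.
A fully ground-truthed synthetic-data generator emulates the underlying
single-particle-tracking (SPT) experiment so that every stage of the
pipeline can be validated without any microscope data.

The package is aimed at researchers analyzing sptPALM-style histone
tracking experiments (e.g. H2B-Halo/PA-JF549 imaged at 100 Hz) and at
anyone who needs a tested reference implementation of the analysis chain:
track tables in, per-condition mobility statistics out.

## What it computes

**Trajectory classification.** Tracks are rasterized into RGB images in
which each inter-frame segment is colored by its instantaneous diffusion
coefficient D = (dx² + dy²)/(4Δt) (red ≤ 0.5 < green ≤ 1 < blue, μm²/s)
and classified into three diffusive populations — *immobile*
(chromatin-incorporated), *mobile* (freely diffusing) and *hybrid*
(switching) — either by a five-conv-layer CNN (8×8–32, 5×5–64, 2×2–128,
2×2–256, 2×2–512, each followed by max-pooling, batch-norm and ReLU;
762,275 trainable parameters) trained on rotation-augmented rendered
trajectories, or by a fast per-segment threshold baseline using the
segment→track mapping rule (immobile if essentially all segments are
slow, mobile if essentially all are fast, hybrid otherwise).

**MSD analysis.** Time-averaged MSD with all overlapping displacement
pairs,

    MSD(nΔt) = 1/(N−n) Σᵢ [(x_{i+n}−x_i)² + (y_{i+n}−y_i)²],

time-ensemble averages across tracks, weighted fits of the anomalous
diffusion model MSD(t) = A·t^α + σ², and two effective diffusion
coefficients: D = p/4 from the slope of the first four MSD points, and a
noise-robust variant averaging the tangent of the fitted power law over
0.1–1.0 s.

**Jump-distance statistics.** Per-track mean jump distance over one frame
interval (a model-free mobility metric), bootstrap distributions of the
averaged mean jump distance (10,000 resamples, percentile CIs), Gaussian
KDEs with Scott's-rule bandwidth, and two-sided Yuen–Welch tests (trimmed
means, Winsorized variances) between conditions, with the damage-response
ratio and its bootstrap CI.

**Compaction imaging.** k-means segmentation of a photoactivated
chromatin line, thickness as the minor axis of the moments-equivalent
ellipse, normalization to the first post-irradiation frame, and
bleaching-corrected recruitment curves from caller-supplied masks.

**Synthetic experiments.** The generator produces labeled track
populations calibrated to the biology: an immobile subdiffusive majority
(fractional Brownian motion, α = 0.59, effective D = 0.0078 μm²/s,
84 %), a fast Brownian minority (D = 3.661 μm²/s, 9 %), a switching
hybrid class (7 %), geometric track-length attrition (mean 17 frames at
100 Hz), localization noise, and a micro-irradiation protocol in which
the mean jump distance inside a 3-μm region of interest transiently rises
(by 50 % at the 1-minute timepoint) and recovers.

## Worked example

Simulate a micro-irradiation experiment and recover the programmed
mobility surge:

```python
from chromodyn import PipelineConfig, SimulationConfig
from chromodyn.pipeline import run_synthetic_experiment

cfg = PipelineConfig(
    simulation=SimulationConfig(n_tracks=2400, seed=101),
    classifier="baseline",
    timepoints=("before", "1min"),
    jump_ratio_profile={"before": 1.0, "1min": 1.5},
    seed=101,
)
report = run_synthetic_experiment(cfg)
row = report["comparisons"]["1min"]
print(round(row["inside"]["ratio"], 3), row["inside"]["significance"])
print(round(row["outside"]["ratio"], 3), row["outside"]["significance"])
```

prints (seed 101)

```
1.408 significant
1.002 not significant
```

i.e. the mobility surge inside the irradiated region is detected and
significant at the p < 0.001 reporting band, while the region away from
the damage shows no change (p > 0.05). The recovered ratio (1.41) sits
below the programmed 1.5 because threshold classification preferentially
drops the fastest damaged tracks from the immobile pool — an attenuation
property of strong effects discussed in `docs/methods.md`; with
ground-truth labels (`classifier="truth"`) the programmed ratio is
recovered within the bootstrap CI. The full report also carries per-class
proportions, bootstrap CIs, KDE tables and the MSD fit of the immobile
population.

The same chain runs on real track tables (CSV dialect
`track_id,frame,x_um,y_um`, TrackMate exports also accepted) through
`chromodyn.pipeline.run_analysis` or the `chromodyn` command-line tool
(`chromodyn simulate|train|classify|msd|jumps-compare|analyze`).

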