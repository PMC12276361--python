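# Methods

This note documents the models, the calibration of the synthetic-data
generator, the numerical choices, and the known limitations of the
package. It is the place where design decisions that were genuinely open
are recorded, in the package's own terms.

## Motion models

**Immobile (chromatin-incorporated) population.** Modeled as 2-D
fractional Brownian motion (fBm) with MSD(t) = A·t^α. fBm is the standard
phenomenological stand-in for polymer-driven subdiffusion of chromatin
loci (a Rouse chain predicts α ≈ 0.5); no explicit polymer simulation is
attempted. Increments are exact: fractional Gaussian noise is synthesized
by Davies–Harte circulant embedding (FFT-diagonalized covariance), with a
Cholesky fallback for the rare parameter/length combinations where the
embedding is not non-negative. Exactness matters because the generator
doubles as the oracle for the MSD estimators.

**Mobile (freely diffusing) population.** Brownian motion with diffusion
coefficient D; equivalently fBm with α = 1, A = 4D.

**Hybrid population.** A two-state Markov chain over frames switches each
step between the immobile and the mobile increment process. The two
increment streams are pre-generated for the whole track and selected
per-step by the state, so the immobile phase retains its fBm correlation
structure across (short) mobile interruptions — an approximation chosen
for simplicity; dwell-local re-initialization would differ only through
the long-memory kernel. State sequences are conditioned on containing at
least one switch: the hybrid class is defined by observed switching
behaviour (the segment→track mapping rule labels a track hybrid only if
its segments actually switch), so an unswitched realization is by
definition not a hybrid track. Hybrid tracks therefore have a minimum
length of 3 points.

**Localization noise.** I.i.d. Gaussian noise of standard deviation σ per
coordinate is added to true positions — the standard SPT static-error
model. It contributes 2σ² per axis to each apparent displacement and a
constant 4σ² offset to the 2-D MSD.

## Generator calibration (the defaults)

The defaults encode the experimental conditions the simulator emulates —
single-nucleosome imaging at 100 Hz with 160 nm pixels:

| parameter | default | rationale |
|---|---|---|
| frame_interval | 0.01 s | 100 Hz acquisition |
| pixel_size | 0.160 μm | camera geometry |
| class_fractions | (0.84, 0.07, 0.09) | immobile/hybrid/mobile population shares |
| immobile_alpha | 0.59 | subdiffusive exponent of bound chromatin |
| immobile_A | 0.0378 μm²/s^0.59 | chosen so the tangent-denoised effective D equals 0.0078 μm²/s (see below) |
| mobile_D | 3.661 μm²/s | fast, unincorporated histones |
| hybrid_switch_rates | (0.05, 0.10) per frame | ≈200 ms bound / ≈100 ms free dwells, representative of transient chromatin binding and of phase structure discernible within a ~17-frame track |
| noise_sigma | 0.025 μm | typical localization precision at this SNR; places the undamaged immobile mean 10-ms jump at ≈0.063 μm |
| track_survival_p | 15/16 | geometric attrition; mean track length 2 + p/(1−p) = 17 frames. Track loss is dominated by out-of-focus motion, not photobleaching, hence a memoryless per-frame survival model |

The tangent-denoised effective D of a fitted power law over a window
[t0, t1] is the time-average of d/dt(A t^α)/4, which integrates to
A (t1^α − t0^α) / (4 (t1 − t0)); with [0.1, 1.0] s and the defaults this
equals 0.0078 μm²/s. (Note the α in the integrand cancels on
integration — a naive "slope × α" form double-counts it.)

**Damage response.** Micro-irradiation is modeled as a multiplicative
factor on immobile-*state* step amplitudes for tracks whose true centroid
lies inside the rectangular damage ROI: all steps of immobile-class
tracks, and the bound-phase steps of hybrid tracks (damage acts on
chromatin-bound motion; freely diffusing segments are unaffected).
Because the measured jump distance carries a localization-noise floor,
a target ratio R on the *measured* mean jump requires a larger true
amplitude factor g, obtained in closed form from
g²s² + 2σ² = R²(s² + 2σ²) with s² the per-axis true step variance. The
default per-timepoint profile targets measured ratios
(1.0, 1.5, 1.01, 0.93) at (before, 1 min, 5 min, 10 min): a strong
transient surge at 1 minute, recovery by 5 minutes, and a dip below
baseline at later times.

## Trajectory rendering and classification

Segments between consecutive localizations are drawn as anti-aliased
straight lines (dense sub-pixel sampling with bilinear splatting) on a
square canvas, each in the single channel selected by its instantaneous
diffusion coefficient D = (dx²+dy²)/(4Δt): red ≤ 0.5 < green ≤ 1 < blue
(μm²/s), boundaries belonging to the lower channel. Rotation augmentation
acts on coordinates (k·2π/24, k = 1..23), never on pixels, so step
lengths, and hence segment colors, are preserved exactly.

Two rendering choices required judgement:

* **Spatial window, 5 μm across the canvas.** The window must map the
  class-separating displacement range onto the canvas: a 17-frame track
  at D = 3.661 μm²/s spans ~1.6–4 μm, and hybrid tracks that start in the
  free phase travel ~1 μm before binding. A 2-μm window clips most of the
  mobile class — including, fatally, the bound-phase blob of such
  hybrids, making them indistinguishable from mobile tracks.
* **Density-preserving intensity.** Accumulated intensity is normalized
  by the image maximum rather than clipped at 1. At 512 px a dwelling
  phase is a resolvable tangle of lines; at the 128-px desk scale it
  collapses into a few pixels, and after hard clipping its value would
  equal a single passing line. Max normalization keeps the revisit
  density — the cue that distinguishes a bound dwell from an isolated
  slow step — while preserving the [0, 1] range and per-segment
  monochromaticity.

The CNN follows the published architecture: five convolutions
(8×8–32, 5×5–64, 2×2–128, 2×2–256, 2×2–512), each followed by 2×2 max
pooling, batch normalization and ReLU; adaptive max pooling to 3×3;
flatten (4,608); dense 3-way softmax. The head reproduces the published
762 K trainable-parameter count exactly (746,464 conv + 1,984 batch-norm
+ 13,827 head = 762,275), and adaptive pooling makes the count
independent of the input size, so reduced-resolution training exercises
the same parameterization. Training uses cross-entropy, Adam at learning
rate 0.0005 with batch size 16 (the optimizer family is an assumption —
the published recipe names only the learning rate and batch size), an
80/20 train/validation split applied after augmentation, and the
best-validation snapshot. The implementation is plain numpy/BLAS
(im2col and an exact FFT convolution engine for the large kernels),
single-threaded, bit-deterministic given the seed.

The **baseline classifier** thresholds each segment's instantaneous D at
0.5 μm²/s (collapsing green/blue to "mobile") and maps segment states to
a track label: immobile if the mobile fraction is ≤ tolerance, mobile if
the immobile fraction is ≤ tolerance, hybrid otherwise. Tolerance 0
reproduces the strict published mapping rule and suits pre-smoothed (HMM)
segment states; the default tolerance 0.2 is needed for raw thresholded
states because step lengths have exponential tails — a genuinely mobile
17-frame track contains a sub-threshold segment with probability ~0.9,
so the strict rule would label most mobile tracks hybrid.

**Classifier-induced attenuation of strong effects.** Scaling immobile
steps moves their instantaneous D toward the 0.5 μm²/s threshold: at the
amplitude needed for a measured 1.5× jump ratio, ~17 % of damaged-track
segments cross it, the threshold classifier reclassifies the fastest
damaged tracks as hybrid, and the recovered ratio drops to ~1.41. This
is a selection bias of appearance-based classification under condition
shift, not of the jump statistics (with ground-truth labels the
programmed ratio is recovered with calibrated CI coverage). At
physiological effect sizes (~1.25× measured jump) fewer than 8 % of
segments cross and the bias is negligible.

## MSD analysis

The time-averaged MSD uses all N − n overlapping pairs at lag n; ensemble
curves weight tracks equally per lag. The anomalous model
MSD(t) = A t^α + σ² is fitted by weighted least squares (weights = pair
counts; lags with fewer than 5 pairs excluded) after a log–log
initialization; σ² is a free non-negative offset by default (the printed
model form, rather than the 4σ² static-error convention, is
implemented; the offset can be released to negative values). D = p/4
uses the least-squares slope of the first four MSD points and is inflated
by localization error via the σ² offset — the documented reason for the
tangent-denoised variant. Directed-motion regimes (α up to 2) are fitted
with the same model; short/long-lag windows are config parameters
(default split at 5 s).

## Jump-distance statistics

Mean jump distances are computed over consecutive-frame pairs only;
gap-spanning displacements are skipped, never divided down. Bootstrap
(default 10,000 resamples at the original sample size) yields percentile
CIs — the CI method is config-reported since a normal-approximation
variant would also be defensible. KDEs use Gaussian kernels with Scott's
bandwidth (std · n^(−1/5)), equal weights. Condition comparisons use the
two-sided Yuen–Welch test on 20 %-trimmed means (the conventional trim,
config-exposed and reported); trim 0 reduces exactly to Welch's t-test.
Only the immobile class enters jump statistics by default, mirroring the
focus on chromatin-incorporated histones. Significance reporting follows
the assay's two bands — significant at p < 0.001, not significant at
p > 0.05 — with the raw p-value always included.

## Compaction imaging

Line segmentation clusters pixel intensities with k-means (k = 2 by
default; foreground = highest-mean cluster; largest connected component
retained). Frames whose foreground/background separation falls below 3.5
within-cluster standard deviations are flagged unsegmentable: splitting a
single Gaussian population at its mean yields ~2.65, while any resolvable
two-level line sits above 4. Thickness is the minor axis of the ellipse
with the mask's second central moments, computed with the unit-square
pixel-extent correction (+1/12 per axis) so a solid axis-aligned
rectangle of height h gives exactly 2h/√3; the series is normalized to
the first post-irradiation frame by default ("time zero" normalization is
available). Recruitment curves use caller-supplied ROI/nucleus/background
masks: (ROI − background)/(nucleus − background), normalized to the
pre-damage mean; the nuclear ratio cancels global photobleaching exactly.
Masks are inputs by design — nucleus segmentation is manual in this
assay.

## Desk-scale problem sizes

Tests and the reproduction script run every stage at sizes chosen for a
single CPU core: classifier experiments use 300 tracks per class,
23 rotations (20,700 augmented images), a 128-px canvas, and a capped
number of Adam steps (400 in the test fixture, 500 in
`scripts/acceptance.py`; the loss is still decreasing at the cap, so the
reported validation accuracy is a lower bound on what the recipe reaches
when trained to convergence); fBm calibration checks use 300 replicate tracks
per parameter-grid point; bootstrap coverage uses 500 replicate
experiments of n = 100; the end-to-end damage experiment uses 1,600–2,400
tracks per timepoint and 20 replicates for CI-coverage assessment. The
full-scale published protocol (3,120 annotated 512-px images, 71,760
augmented, training to convergence) is emulated in shape, not in compute.

## What passing tests do and do not show

The generator realizes the *statistical structure* the analyses assume:
power-law MSDs, well-separated diffusive classes, geometric attrition,
Gaussian localization error, a multiplicative and ROI-confined damage
response. Real SPT data additionally contain linking errors, blinking,
drift, anisotropic and heterogeneous motion, nuclear-boundary effects and
class-imbalanced, condition-dependent track lengths — none of which are
simulated. Passing tests therefore demonstrate correctness of the
estimators and the pipeline plumbing under the stated model, and
parameter-recovery behaviour under that model; they do not certify
performance on any particular real dataset. The classifier in particular
is validated on synthetic renderings; applying it to other proteins or
imaging conditions requires retraining and fresh validation.

## Known limitations

* No photophysics (blinking/bleaching kinetics beyond attrition), no 3-D
  motion, no camera-noise calibration, no polymer simulation.
* The hybrid sub-model (Brownian free phase, per-frame Markov switching,
  switch rates) is a fixture: plausible, but not fitted to data.
* vbSPT itself is not reimplemented; only the published segment→track
  mapping rule is provided.
* Threshold-based classification attenuates strong condition effects
  (see above); effect-size estimates from classified pools should be
  read with that bias in mind.
* CNN training on a single CPU core is compute-limited; the desk-scale
  protocol trains for a capped number of steps rather than to full
  convergence.
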