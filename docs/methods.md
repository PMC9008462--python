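# Methods

This note documents the models behind `axodyn`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the known
limitations. Every empirical claim here is computed by the test suite or
by `scripts/acceptance.py`; nothing is quoted from an external dataset.

## The motion model

Axonal cargo is simulated in an arc-length coordinate along a polyline
axon path oriented distal → soma.

**Active transport (AT).** A renewal process of alternating *active*
(run) and *paused* phases. Within an active phase the cargo moves
soma-ward at a constant speed drawn per phase from a truncated normal
(mean/SD configurable; the region presets use the measured per-phase net
speeds, e.g. 1.531 ± 0.486 µm/s distal, 1.544 ± 0.446 µm/s proximal).
During pauses the position is frozen up to isotropic jitter
(SD 0.05 µm by default — "confined to the track" at the localization-
noise scale). The long-run net speed of such a process is
s_a·T_a/(T_a+T_p); for the distal kinetics (T_a = 7.218 s,
T_p = 5.285 s) this gives ≈ 0.88 µm/s, which the trajectory-level suite
reproduces.

**Phase durations** are drawn from gamma distributions moment-matched to
the requested (mean, SD) *after shifting by a 0.5-s duration floor*:
`duration = floor + Gamma(k, θ)` with the gamma matched to
(mean − floor, SD), and the alternating sequence is burned in for four
mean cycles before the observation window opens, so a track begins in
either phase with the equilibrium time-weighted probability — the
natural model for cargo picked up mid-transport (always starting in a
run would inflate the active time fraction of finite windows by a few
percent). Rationale for the floor: the region-stratified phase statistics
this generator reproduces are statistics of *observed* phases — no
video-rate segmentation can resolve a 0.1-s pause, so such phases cannot
appear in measured tables — and an unshifted gamma with SD > mean (the
distal pauses are 5.285 ± 9.420 s) would put a large probability mass at
durations far below any detector's resolution, making "recover the
generative mean" ill-posed by construction. The floor makes the
generative distribution the observable one. The emitted mean and SD still
equal the requested values.

**Back-and-forth (B&F)** is 1-D Brownian motion (default
D = 0.1 µm²/s) reflected inside a confinement domain (default 5 µm, the
middle of the observed 3–7 µm range). **Stationary (S)** is isotropic
jitter only. **Pairs** share the leader's phase sequence and run speeds;
the follower trails by an Ornstein–Uhlenbeck tether (rest 0.5 µm,
SD 0.15 µm, relaxation 1 s) hard-bounded below 2 µm, matching the
observation that co-transported cargo never separates that far.

**Blinking** is a two-state Markov chain per frame (default
p_off = 0.05, p_on = 0.5 → geometric dark dwells, mean 2 frames).

## The camera model

Frames are rendered as pixel-integrated 2-D Gaussians (error-function
integration, σ_PSF = 1.3 px) over a uniform background, then passed
through: Poisson shot noise → EM excess noise (variance inflation
F = 2, the ideal EM-register value; applied as an equivalent Gaussian
term, folded with read noise into a single draw) → division by gain
(0.13 photons/ADU) → offset (100 ADU) → read noise (0.65 ADU RMS) →
16-bit quantization. Defaults: 127-nm pixels, 1/17-s frames, 512×512
ROI. Photon budget 400 photons/frame over 5 photons/px background gives
≈ 12 nm CRLB, ≈ 17 nm actual error including EM noise — around the
20-nm localization noise the trajectory-level suites assume. No
photon-budget figure is reported for the original movies; these values
are this package's documented choice, selected to make detection easy
(SNR ≈ 15) but localization noise non-negligible.

Fixed-cell stacks use 195-nm pixels, 250-nm z-steps and a Gaussian axial
envelope (σ_z = 0.4 µm), so each dot occupies a contiguous subset of
slices.

Pixel-size note: the source describes live imaging at 127 nm/px but
elsewhere mentions an effective pixel of 245 nm; the package simply
parameterizes pixel size and uses 127 nm for live movies and 195 nm for
fixed stacks.

## Calibration

Photon-transfer calibration: offset and read noise from a dark stack;
gain from the slope of pooled per-pixel temporal variance vs mean
(variance is F·µ/g² + σ_r², so the slope is F/g). Whether the reported
gain absorbs the EM excess factor is exposed as `em_excess_noise`
(default 2; set 1 to fold F into the gain). Flat-field references are
normalized to unit mean before division so corrected images keep their
intensity scale. Negative post-offset values are clipped to zero by
default because the Poisson likelihood requires non-negative data; the
clip is a flag (`clip_negative`) since it biases low-background sums.

## Detection and localization

DoG bandpass (σ = 1.0/2.0 px), strict 8-neighbour maxima with
deterministic plateau tie-breaking, threshold defaulting to 5 robust SDs
(1.4826·MAD) of the response — estimated once per movie, since the
background is temporally stationary. Fits maximize the Poisson
likelihood of (x, y, photons, background) for a pixel-integrated
Gaussian by damped Fisher scoring (expected-information Newton steps
with backtracking; convergence |Δposition| < 1e-4 px, max 50
iterations; L-BFGS-B fallback). Precision is the CRLB at the optimum;
fit quality is the Poisson deviance, and the default gate (500) is set
loose because EM excess noise roughly doubles the deviance expected of
an ideal Poisson detector while single-pixel artifacts exceed the gate by
orders of magnitude. Duplicates within 2 px merge keeping the brighter
fit. RMSE tracks the CRLB within 15% at 200–2000 photons (test suite).

Fixed-stack counting: maximum projection over z, DoG + maxima with a
7-robust-SD threshold (projection of 20 slices samples the upper tail of
the per-slice noise, so the floor sits higher than for single frames),
local background gate, duplicate suppression. Counting error on
synthetic fields at 20–120 dots per 78×78 µm stays well under 5%.

## Linking

Standard LAP augmentation per frame pair: link cost = squared
displacement (forbidden beyond 0.5 µm/frame), death/birth costs
−log(p_off + p_miss) and −log(p_on + p_miss) with p_miss = 0.05 for
detection failures. Gap closing joins ends to starts across ≤ 12 dark
frames within a distance growing as 0.5·√g + 2·g·Δt µm (diffusive plus
transport term). The 12-frame default covers the 99.98th percentile of
dark dwells under the default blink model; 8 frames — a plausible first
choice — leaves ≈ 0.2 expected track splits per minute of tracking,
which measurably caps trajectory completeness. Tracks shorter than 10
localizations are dropped (the window-7 velocity and the phase
statistics need support); this automated filter replaces the interactive
trajectory curation used in the original analysis.

## Trajectory statistics and diffusion

The six per-track statistics follow the definitions in the README table;
mean curvilinear speed excludes increments spanning more than the
gap-closing window so bridged dark periods do not dilute it (a flag).
Whether a diffusion constant is most meaningful per whole trajectory or
per sub-trajectory is left open by the source; the pipeline computes it
at both levels — one MLE per track in the statistics table, and one per
phase (where the phase has ≥ 11 localizations) in the phases table — and
labels both. The diffusion MLE treats per-axis increments as independent Gaussians
with variance 2DΔt_i + σ_i² + σ_{i+1}²; the −σ² covariance between
consecutive increments is neglected by default (the exact banded-
covariance likelihood is available via `covariance="tridiagonal"`), and
motion blur is not modelled. Bias stays below 5% for
D ∈ {0.01, 0.1, 1} µm²/s at N = 1000 with 20-nm errors (test suite),
and the estimator remains unbiased under strongly heterogeneous
precisions where the naive MSD/4Δt estimator fails. Confidence
intervals come from the profile likelihood (Δ2·nll = 3.84).

## Segmentation

Motion classes: S if d_max < 0.5 µm; else AT if d_net ≥ 5 µm with
sustained window speed above v_on; else B&F if d_max ∈ [2, 10] µm,
r_lin < 0.2 and ≥ 3 velocity sign reversals along the principal axis;
else unclassified. No numeric thresholds exist in the source; these are
this package's documented choices.

Active/pause segmentation of AT tracks runs on the window-7 speed:

1. **Hysteresis**: enter active at v_on = 0.6 µm/s, leave at
   v_off = 0.4 µm/s. The asymmetry suppresses chatter around a single
   threshold.
2. **Adaptive threshold-crossing refinement**: each switch moves to the
   crossing of the midpoint between the adjacent blocks' median speeds
   (a fixed midpoint is biased by the per-phase run speed).
3. **Changepoint refinement**: each boundary is re-placed by local
   segmented regression — linear position on the run side, constant
   position on the pause side, scanned within ±8 frames. Both models are
   fit on flanking data at least 3 frames from the boundary and held
   fixed while scanning the cut: refitting per candidate cut would let
   the more flexible line model absorb ambiguous plateau points at
   almost no residual cost and systematically trim short pauses. This
   step removes the residual few-frame bias that any smoothed-speed
   threshold crossing carries, because the changepoint, unlike the
   crossing, is symmetric in the underlying positions.
4. **Minimum durations**: phases measured shorter than 0.35 s merge
   into their neighbours. A floor-length (0.5 s) phase of either label
   spans 8 frames = 7 intervals = 0.41 s of measured duration, so the
   0.35-s cut leaves one frame of boundary-jitter margin; a higher cut
   silently erases genuine floor phases — erased pauses bias the pause
   mean upward directly, and erased runs fuse their two flanking pauses,
   which biases it even more. Spurious noise phases are instead
   suppressed by the hysteresis width and the fixed-model changepoint,
   which shrinks them below the cut. Blink gaps are linearly
   interpolated onto the full frame grid first (gaps inside short pauses
   otherwise delete exactly the low-speed samples that reveal them).

All thresholds were calibrated once against the generator's truth
channel (both axonal presets, multiple seeds) to satisfy the design
requirement that recovered phase kinetics match generative values within
10%; with them, matched recovered/true pause boundaries agree to ±1
frame and matched durations to ≈ 2%.

A phase is *interior* when bounded by opposite-label phases on both
sides; only interior phases enter duration statistics, since a phase cut
by the start or end of observation has an unknown true extent. Interior
selection in a finite movie is length-biased against long phases (a
pause must fit inside the window with runs on both sides); at 120-s
tracks this deflates the mean observed pause by ≈ 3–5% (proximal) while
missed sub-resolution pauses inflate it comparably, which is why
recovery is compared at 120-s scale.

## Regional analysis

Regions are half-open arc intervals along the device (default: 100 µm
axonal compartment, 450 µm microchannel, 1000 µm proximal axon, 50 µm
soma), so each localization has exactly one label; a trajectory belongs
to the region holding the majority of its localizations. Transport
distance is measured along the path from the ligand addition point
(Euclidean vs along-path is unstated in the source; along-path is the
physically meaningful choice for axonal transport). Histograms use
left-closed 200-µm bins with SEM across replicates. Pairs are detected
as co-temporal tracks with mean inter-distance < 2 µm over ≥ 5 s of
overlap — the source reports the < 2 µm observation but defines no
detector, so the criterion is operationalized here. Group comparisons
are Welch t tests and one-way ANOVA with Bonferroni-adjusted pairwise
post-hocs (a Dunnett-style option is out of scope; the flag exists to
switch corrections).

## What the synthetic data do not emulate

Axon curvature beyond a configurable polyline (defaults are straight,
making statistics analytically checkable); axon outgrowth or branching;
z-extended emitters in live movies (single focal plane, as acquired);
partial-frame blinking (visibility is binary per frame); QD spectral or
intensity heterogeneity; autofluorescence structure and vignetting in
live movies; endosome fusion/splitting (the linker deliberately has no
merge/split moves). Passing tests therefore demonstrate correctness of
the estimators under the stated noise and motion models, not robustness
to every feature of real recordings.

## Problem sizes

The test suite runs reduced problem sizes (e.g. 8 rendered movies, 200
CRLB draws per photon budget); `scripts/acceptance.py` runs the
study-scale versions (53 trajectories per region, 20 fixed-cell fields,
30 rendered 120-s movies) in about 15 minutes on one CPU. Every random
draw descends from the single `--seed` via `numpy.random.SeedSequence`.
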