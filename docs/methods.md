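# Methods

This note documents the models, algorithms and numerical choices behind
hyphatrack: what the simulator assumes, how each analysis stage is
defined, which knobs matter, and what the synthetic benchmarks do and do
not demonstrate about real data.

## Growth and chromosome model (simulator)

One hypha is a one-dimensional tube elongating at its tip. All
positions are arclengths from the tip (µm, 0 at the tip); the frame
interval defaults to 10 min.

**Tip extension.** Each hypha draws a rate
`v_h ~ N(extension_rate_mean, extension_rate_sd²)` once and extends by
`max(0, v_h + ε_t)` per frame, `ε_t ~ N(0, extension_noise_sd²)`.
Defaults 0.7 / 0.15 / 0.15 µm per interval. These are assumptions — the
source system is only characterized as extending at roughly a micrometre
per ten minutes, with no published rate statistics — and they are chosen
so that per-frame focus displacements stay below the tracking gate (see
*Linking*).

**Anchored origin.** The tip-proximal origin follows a discrete
mean-reverting (AR(1)) process,

    d ← d + κ·(anchor_offset − d) + η,   η ~ N(0, σ_η²),

with `σ_η = anchor_sd·sqrt(1 − (1−κ)²)` so that the stationary
distribution has exactly mean `anchor_offset` and s.d. `anchor_sd`
independently of the relaxation strength κ. AR(1) is the simplest
process with a prescribed stationary mean and spread; nothing in the
observations constrains the correlation time. κ defaults to 0.3, which
puts the per-frame step s.d. near 0.3 µm for the wild-type anchor
(1.4 ± 0.4 µm) — comfortably below the linking gate. Positions are
clipped to `[0.1 µm, L(t)]`: a focus sits behind the tip dome, never at
arclength exactly 0.

**Trailing origins.** Origin *j* (tip order at birth, j ≥ 2) receives a
fraction `c_j = coupling_base**j` of every tip advance:
`d_j ← d_j + (1−c_j)·ΔL + η`, `η ~ N(0, trailing_noise_sd²)` (default
0.15 µm). Geometric decay in the index is the simplest form consistent
with a movement/extension correlation that falls off with oriC index;
the data constrain only the qualitative decay. With zero noise the
regression slope of focus movement on tip extension equals `c_j`
exactly, which the tests exploit.

**Replication and duplication.** A schedule entry
`(oriC index, start frame, duration)` makes a replisome focus appear at
the chosen origin at `start` and the origin split `duration` frames
later. Until the split the replisome co-moves with the replicating
origin; from the split frame on it is stationary in the material frame
of the hypha (its tip distance grows by ΔL each frame). The
tip-proximal daughter simply continues the parent's process; the
tip-distal daughter is born on the replisome (with a minimum initial
offset of 0.5 µm from the parent, the scale at which two
diffraction-limited foci first become resolvable) and co-moves with it.
This reproduces the observed phenomenology: the anchored daughter keeps
its tip distance, the other falls behind with the replisome, and their
separation grows at roughly the extension rate.

**Branches.** A schedule entry `(frame, stem position, populate_delay,
stall)` spawns a sub-hypha at 45° from the stem with its own extension
rate. After `populate_delay` frames a new branch-local focus enters and
becomes anchored to the branch tip. Stalling branches grow for
`stall_growth_frames` (default 3) frames and then hold length forever.
Branch-entering foci are modeled as new objects rather than migrating
stem objects; the conservation property (origin count +1 per split,
never decreasing) therefore applies to stem origins.

**Scenarios.** `wild_type` anchors at 1.4 ± 0.4 µm. `delta_parA` /
`delta_parB` displace the anchor to 2.3 / 2.5 µm with *nominal* AR s.d.
1.05 / 1.6 µm. The nominal values exceed the intended spreads (≈1.0 /
≈1.4 µm) because truncation at the tip clips the lower tail of a wide
anchor distribution; the chosen values realize tip-distance variance
ratios of ≈6.3 and ≈12 relative to wild type, which is the contrast the
scenarios exist to emulate. Mutant scenarios also populate branches
later (delays 5–6 frames vs 3).

**Determinism.** Every hypha uses a generator seeded with
`(master seed, hypha_id)`; rendering uses `(seed, hypha_id, channel)`.
Identical configuration and seed give bit-identical trajectories,
images and output tables.

## Rendering

Frames are 16-bit grayscale images. The stem lies along the x-axis
(base fixed, tip advancing); branches run at 45°. The tube is drawn at
`hypha_width` px with a weak autofluorescence, each focus as an
isotropic Gaussian of s.d. `psf_sigma` (default 0.15 µm) centred at its
exact sub-pixel arclength position, over a uniform background (default
100 counts) with optional Poisson noise and Gaussian read noise
(default s.d. 6). Pixel size defaults to 0.065 µm/px. Centerlines are
emitted tip-end first at 1 px spacing with the first point exactly at
the tip, so arclength 0 in every profile is the true tip.

The renderer does not model photobleaching, focus blinking, axial
defocus, tube-brightness variation along the hypha, or overlapping
crossing hyphae. Benchmarks passing on these images therefore show the
pipeline is correct at realistic SNR and geometry, not that it is robust
to every artifact of real micrographs.

## Profile extraction

For each arclength sample (grid step = one pixel by default) the
intensity is the mean of bilinearly interpolated image values over the
`2·half_width+1` px segment perpendicular to the centerline
(`half_width` default 2 px). Nearest-neighbour interpolation is
available for oracle tests. Background is subtracted as the 10th
percentile of the profile (robust and parameter-light; an off-hypha
`external_region` mode exists), then clipped at zero. Normalization
rescales a profile so its maximum is 100 %. Ensemble summaries use
statsmodels' lowess over pooled (arclength, intensity) points with a
bootstrap-over-profiles 95 % band and report the curve maximum.

## Focus detection

The profile is smoothed by a Markov-chain (stationary-vector) smoother:
adjacent bins are states of a birth/death chain whose transition
weights compare intensities up to `window` (default 3) bins away via
`exp((I_far − I_near)/sqrt(I_far + I_near))` with +1 regularization;
the stationary vector is computed by the product-of-ratios recurrence
in log space (overflow-safe) and rescaled to the input maximum. A
constant profile is a fixed point; an isolated spike stays unimodal at
its position; smoothing reduces variance in flat regions and moves an
isolated peak's argmax by at most one grid step — all covered by tests.

Candidate foci are local maxima of the smoothed profile (the profile is
zero-padded by one sample per end so a focus at the tip itself is
callable). Each candidate is snapped to the nearest raw local maximum,
thresholded on its raw amplitude — by default a fraction of the
hypha-wide maximum of the channel (0.5 in snapshot mode, matching the
half-of-brightest-signal convention; 0.3 in time-lapse mode so
sub-dominant daughter foci survive), and additionally above a robust
noise floor of 6 noise s.d. (median absolute successive difference
estimator, exactly zero on noiseless profiles). Maxima closer than
`min_separation` (0.4 µm ≈ 2.7 PSF s.d.) are merged keeping the higher;
positions are refined by three-point parabolic interpolation on the raw
profile. Doublet resolution declares two foci in a window iff the
smoothed profile has two maxima ≥ `min_separation` apart with an
intervening dip of at least `dip_fraction` (10 %) below the lower one.

Manual curation of false positives is replaced by a persistence rule:
time-lapse foci must be tracked in ≥ 2 consecutive frames.

## Tracking and lineage

Linking is greedy nearest-neighbour per consecutive frame pair in the
tip-distance coordinate, rejecting displacements above the gate;
unmatched foci seed tracks; tracks shorter than the persistence minimum
are dropped. The gate default is 1.5 µm/frame: anchored and coupled
origins move ≲ 0.5 µm per frame, but a replisome-bound daughter is
stationary in the material frame and recedes at the full extension rate
(0.7–1.1 µm per frame), so a 1 µm gate would fragment exactly the
tracks duplication detection needs; 1.5 µm covers the fastest class
while staying below the ≈1.8 µm inter-focus spacing. Greedy linking
equals globally optimal assignment whenever inter-focus gaps exceed
twice the gate (tested against a Hungarian oracle).

Tip indices are per-frame ranks of co-existing tracks by distance from
the tip (ties broken by track age). A duplication is called when a new
track is born (not at the movie start) within `assoc_radius` (1.5 µm)
of a persisting track, measured against the parent's position at the
split or the frame before (the daughter separates from where the parent
was). Births within twice the association radius of the recent end
(≤ 2 frames) of another track are classed as re-linked fragments —
gate breaks or transient merges — not duplications. Each event is
paired with the most recent replisome track appearing before the split
within the radius of the parent; the lag is frames × frame interval.

Branch records take the branch length per frame from the branch
centerline arclength; the first frame with any focus on the branch
defines `length_at_first_focus`. The stall rule is applied literally: a
branch is stalled iff the terminal window spanning at least 60 min
shows total elongation ≤ 0.2 µm (sub-resolution tolerance; series too
short to cover 60 min are never classified stalled), with final-length
classes <3.5, 3.5–7.0 and >7.0 µm.

## Statistics

All closed forms are written from their defining formulas and tested to
1e-10 against independent evaluations (and against scipy/pingouin where
available): Pearson r with Fisher-z 95 % CI; two-sided variance-ratio
F-test with an F-quantile CI; one-way ANOVA omnibus; Games–Howell
pairwise (Welch t, Welch–Satterthwaite d.o.f., `q = |t|√2` referred to
the studentized range with k groups — for k = 2 this collapses exactly
to Welch's t-test); classical pooled-variance Tukey HSD; uncorrected
Pearson χ². KDEs are Gaussian with Silverman bandwidth and integrate
to 1. Focus "movement" is `ΔL − Δd` (displacement in the material
frame, so an anchored focus co-moves with the tip); the alternative
`−Δd` convention is available behind a flag. The mixed-vs-pooled
comparison fits a pooled ML line and a random-intercept ML mixed model
(statsmodels MixedLM) and reports both log-likelihoods with a 1-d.o.f.
LRT on the intercept variance (conservative: the null is on the
boundary; singular fits report variance 0 and p = 1). Post hoc p-values
are reported as returned (both procedures control family-wise error);
no further correction is applied. Colocalization counts channel-a foci
whose nearest same-frame channel-b focus is strictly closer than the
cutoff (1 µm). Duplication time-courses report cumulative per-hypha
fractions with Wilson 95 % intervals and the mean daughter separation
at each lag.

One calibration caveat: a single-sample variance-ratio estimate at
n = 170 per group has a log-scale s.d. of ≈ 0.15, so individual trials
scatter ±20 % around the true ratio; recovery checks therefore assert
the mean estimate over trials, with every trial still rejecting
variance equality decisively.

## Pipeline

`run_pipeline` is a pure function of (dataset, config, seed): validate
inputs → extract profiles and detect foci (per hypha, frame, region,
channel; the fractional threshold references the hypha-wide channel
maximum) → link, index, detect duplications, associate replisomes,
score branches → population statistics. Outputs are CSV tables (header
comment carrying the config hash and seed, fixed float format for
bit-reproducibility), `stats.json` and a human-readable summary. Each
stage is separately re-runnable from the previous stage's saved output
(`detect`, `track`, `stats` subcommands). Coordinates: arclengths in µm
from the tip; pixels 0-based, x = column, y = row.

## Problem sizes used in the benchmarks

The shipped test-suite and acceptance-script simulations use 40 hyphae
× 30 frames for anchored-distance recovery, 10 × 20 × 10 replicates for
the correlation decay, 170 observations per group for the strain
contrasts, 50 single-hypha movies for duplication timing, 32 hyphae for
the duplication time-course, 41 germ tubes and 100 branches — matched
to the cohort sizes such a study would analyze, and all complete in
about a minute each on one CPU.

## Known limitations

- The simulator's trailing-origin coupling and AR(1) anchor are
  phenomenological; they reproduce observed moments and correlations,
  not nucleoid mechanics.
- Greedy linking can swap identities when distinct foci approach within
  the gate (e.g. a daughter crossing a trailing origin); duplication
  detection compensates with the fragment guard, but per-frame index
  labels during a crossing are best-effort.
- Centerlines are inputs (per frame, tip flagged); there is no
  segmentation or tracing of hyphae from transmitted-light images, no
  drift correction, and no 3-D support.
- Snapshot-mode statistics (per-frame tip-most focus) and track-based
  statistics answer slightly different questions when detections are
  intermittent; the mutant-contrast benchmark uses snapshot semantics,
  matching fixed-image analyses.
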