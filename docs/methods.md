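# Methods

`smmtracks` simulates and analyses single-molecule microscopy (SMM,
"slimfield") tracking data of fluorescently tagged complexes in
rod-shaped bacteria: CRISPR crRNP effector complexes (mNeonGreen, green
channel) and the replisome clamp-loader subunit DnaX (mScarlet, red
channel).  This note records the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic data can and
cannot establish.

## Diffusion model

Each molecule belongs to one of K diffusive populations (K = 3 for
crRNP data — slow, intermediate, mobile; K = 2 for the DnaX
static/mobile split) with population fractions f_i and diffusion
coefficients D_i.  Motion is pure 2D Brownian motion: per frame of
interval Δt each coordinate advances by an independent zero-mean
Gaussian step of standard deviation σ_i = sqrt(2 D_i Δt), equivalently
D_i = σ_i²/2Δt.  A molecule keeps its population for its whole track;
state switching within a track is deliberately not modelled, because
the downstream mixture estimators likewise assign whole jumps to
populations.  Motion is confined to the cell, a 2D spherocylinder
(stadium) of default length 2.5 μm and radius 0.5 μm, with specular
reflection at the wall; specular reflection preserves the uniform
stationary distribution.  The simulation is strictly 2D, matching an
analysis that uses only x/y displacements.

A fraction of slow-population molecules can be tethered ("anchored")
within `anchor_radius` (default 0.075 μm) of a replication-fork focus,
diffusing with their population's D but reflecting at the tether-disk
boundary.  The tether radius is deliberately below the dwelling rule's
confinement radius (below): a molecule bound at a focus must look like
a dwelling track to the classifier, and a 0.075-μm tether disk keeps
≥ 80 % of its localizations within 0.09 μm of the track centroid even
with 30-nm localization noise.

Reported positions add isotropic Gaussian localization noise
(`loc_noise_sigma`, default 0.030 μm — a typical single-fluorophore
precision at these photon counts).  Photobleaching is molecule-level
disappearance with per-frame survival probability `survival_prob`
(default 0.98, mean emissive span 50 frames); there is no blinking or
re-appearance.  The discarded pre-bleaching phase
(`bleach_phase_frames`, default 100, within the experimental 100–500
range) is applied as binomial thinning of the initial population —
statistically equivalent to simulating pre-phase motion, since the
stationary spatial distribution is uniform and pre-phase frames are
discarded.  Emitted tracks need ≥ 5 adjacent-frame displacements, the
minimum-track-length rule used throughout.

Randomness: a single master seed; every cell draws from deterministic
substreams (`SeedSequence(seed, spawn_key=(cell, stream))`), so a
dataset is bit-reproducible and independent of cell iteration order.

## Condition presets

Acquisition defaults follow the experiment: Δt = 30 ms, 300 recorded
frames per movie, localization noise 0.03 μm.  The slow and
intermediate crRNP coefficients are the published point estimates
0.023 and 0.128 μm²/s.  The mobile coefficient (0.6 μm²/s) and all
per-condition fractions were only ever shown graphically, so the
presets declare defaults: the wild type puts roughly one-third of
complexes in the slow pool (0.34/0.36/0.30); the untargeted high-copy
plasmid drains the slow pool into the intermediate, scanning pool
(0.12/0.56/0.32); a target plasmid enlarges the slow pool and tethers
most of it at replisome foci (0.45/0.35/0.20, anchor fraction 0.6).
DnaX presets use two populations (replisome-bound ≈ 0.01 μm²/s vs free
≈ 0.3 μm²/s); the plasmid-target condition shifts weight to the bound
pool, reproducing the observed MSD drop.  In the two-channel analysis
the crRNP channel is simulated with the focus positions of the paired
DnaX simulation injected, so anchored green complexes sit at the red
channel's foci as in a real cell; the plasmid-target DnaX preset draws
half of its foci in the polar caps, reflecting the enrichment of
replicating high-copy plasmids near the poles.

## Estimators

**Frame-to-frame displacement pooling.**  Only adjacent-frame pairs
enter displacement statistics; gapped pairs are excluded.  The 1D
sample pools x- and y-displacements as separate observations.

**Zero-mean Gaussian mixture (EM).**  The static/mobile split fits K
zero-mean Gaussians to the 1D displacements by expectation-
maximization with means fixed at zero; free parameters are weights and
variances.  Five deterministically seeded restarts (quantile-spread σ
seeds, multiplicative perturbations) guard against local optima; the
best likelihood is kept and D_i = σ_i²/2Δt is reported, components
sorted by ascending D.  A sample of identical values returns a
single-component result with a `degenerate_sample` flag rather than an
error.

**Squared-displacement (jump-distance) mixture.**  For Brownian
mixtures the squared 2D jump r² is, per population, exponential with
mean 4 D_i Δt, so

    P(r² ≤ u) = 1 − Σ_i f_i · exp(−u / (4 D_i Δt + 4 σ_loc²)).

The model is fitted by least squares on the empirical CDF (evaluated
at ≤ 800 quantile-spaced sample points) — bin-independent and stabler
than fitting a binned PDF.  Parameters are log-D values and softmax
weight logits, so fractions sum to one by construction and D stays
positive; five seeded restarts from quantile-spread initializations
are compared by SSE.  The localization term 4σ_loc² defaults **off**
(no correction is stated for the published coefficients); when the
precision is known it can be supplied, which matters whenever
4σ_loc² is comparable to 4DΔt (at σ_loc = 30 nm the noise floor
0.0036 μm² exceeds the slow component's 0.00276 μm²).  The *global*
variant fits several conditions jointly with shared D_i and
condition-specific fractions, the convention that makes population
sizes comparable across conditions.

Residuals for reporting are computed on the jump-distance probability
histogram — 50 equal-width bins spanning [0, 99.5th percentile of r],
observed probability = counts over the total sample size, fitted mass =
model-CDF differences — because figure residual panels use the binned
convention (the ±0.02 band), while the fit itself stays bin-free.
Fitted coefficients below 10⁻⁶ μm²/s are clipped to that floor and
flagged.

**MSD.**  The ensemble time-averaged MSD uses every same-track pair at
each lag; the SEM is over pairs.  D is extracted by a weighted (1/SEM²)
linear fit MSD(τ) = 4Dτ + b over the first four lags; the intercept b
absorbs the static localization-error offset, and a negative slope is
reported as D = 0 with a flag.  Because pairs overlap, the SEM
understates correlations between lags; the fit is used as a summary
statistic, not an efficient estimator.

**Dwelling classification and foci.**  A track is *static* (dwelling)
iff ≥ 80 % of its localizations lie within a confinement radius
(default 3 × loc_noise_sigma = 0.09 μm) of its centroid.  Each static
DnaX track contributes its centroid; centroids within 0.15 μm (single
linkage) merge by averaging into one focus reference point.  This
centroid-confinement rule is an explicit operationalization of
"dwelling"; no claim is made that it reproduces any particular
tracking suite's internal definition.

**Focus proximity.**  For each crRNP track the first five
localizations (configurably: five evenly spaced ones) are each scored
by D = sqrt((x_focus − x_i)² + (y_focus − y_i)²) against every focus
*in the same cell*, keeping the nearest (ties to the lowest focus id);
cross-cell matching is forbidden, and tracks in cells without foci are
skipped with a log message.  Distances are summarized as a
probability-normalized histogram with 0.1-μm bins.

**Standardized cell.**  Localizations are rotated/translated into the
cell frame and scaled by length (long axis) and diameter (short axis),
poles at ±0.5.  Pooled 2D histograms (default 50 × 26 bins, 1-bin
Gaussian smoothing) are normalized to total mass 1.  No mirror
symmetrization is applied by default.

**Detection and linking** (image path).  Spots are local maxima of a
difference-of-Gaussians band-pass (σ, 2.5σ) above an SNR threshold
measured against the filtered image's MAD, refined to sub-pixel
precision by a fixed-σ 2D Gaussian fit.  Linking is greedy nearest
neighbour per frame pair with a hard distance cap, deterministic
tie-breaking (distance, then detection index, then track id), optional
gap closing, and the ≥ 5-step output filter.  This is a declared
simplification adequate at post-bleaching densities (≲ 0.2 spots/μm²),
validated against simulator ground truth (≥ 95 % of true links), not a
re-implementation of a multi-hypothesis tracker.

## Parameter-recovery benchmark

`smmtracks.benchmark.wildtype_recovery` (reported by
`scripts/acceptance.py` and repeated over seeds by
`analysis/05_recovery_benchmark.py`) simulates the wild-type mixture
at Δt = 30 ms with the ≥ 5-step filter and fits it back with the
three-component squared-displacement mixture.  The benchmark runs in
the dilute regime where the exponential mixture model is *exact*: a
large cell (40 × 20 μm, so wall reflections are negligible) and zero
localization noise, about 1.8 × 10⁵ adjacent-frame jumps from 700
cells (a few seconds on one CPU).  In this regime the recovered slow
and intermediate coefficients land within a few per cent of 0.023 and
0.128 μm²/s and the 50-bin histogram residuals stay well inside ±0.02.

The regime matters, and the package is explicit about it: under
imaging-like conditions the model is misspecified in two ways.  With
σ_loc = 30 nm the measured slow-component scale is dominated by the
noise floor, and slow/intermediate separation drops to ~3×, which
makes 10 %-level recovery of the slow coefficient impossible at
realistic sample sizes for *any* estimator unless the known σ_loc is
supplied to the model — and marginal even then.  Wall reflections in a
0.5-μm-radius cell compress the mobile population's jumps, biasing its
recovered coefficient downward (~0.52 vs 0.6 μm²/s) and leaking a few
per cent of bias into the intermediate component.  Passing the
benchmark therefore certifies the estimator, not the claim that
absolute coefficients from real confined, noisy data are unbiased.

## What the synthetic data do and do not emulate

Emulated: multi-population Brownian mixtures with the published slow
and intermediate coefficients; 30-ms frame interval; tens-of-nm
localization noise; geometric photobleaching with a discarded
pre-phase; confinement in a 1 × 2.5 μm spherocylinder; per-cell DnaX
foci with optional polar bias; tethering of bound complexes at foci;
the ≥ 5-step track filter.

Not emulated: state switching within tracks, blinking and gap
re-appearance, anomalous (non-Brownian) diffusion, nucleoid structure
or chromosome-conformation effects on accessibility, motion blur
within an exposure, depth-dependent (3D) effects, camera EM-gain
statistics, cell-to-cell parameter variability, and cell growth or
division.  Tests passing on these data show that the estimators
recover the generative truth of this model class; they do not show
that the biological conclusions are insensitive to the omitted
effects.

## Problem sizes and runtimes

Defaults were sized so every stage is comfortable on a single CPU:
simulated conditions use 60 cells (~250–300 tracks, ~1.5 × 10⁴ jumps)
per condition, the recovery benchmark 700 cells (~1.8 × 10⁵ jumps),
property tests 10⁴–10⁵ samples.  The full test suite runs in well
under a minute; each analysis driver in seconds.

## Known limitations

* The squared-displacement CDF fit is consistent but not efficient;
  near-degenerate component pairs (adjacent-D ratio < 3) trade off
  fractions against coefficients, and K is not selected automatically
  (a BIC-style comparison can be done manually by refitting with
  different K).
* The MSD SEM ignores pair overlap within tracks.
* The greedy linker has no merge/split handling and will swap
  identities when two molecules pass within the per-frame search
  radius.
* Dwelling classification thresholds are heuristics tied to the
  localization noise scale; with very long tracks the centroid
  criterion becomes conservative (a bound molecule's noise cloud keeps
  a constant fraction inside the radius, but a slowly drifting focus
  does not).
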