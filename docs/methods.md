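# Methods

`gliaquant` implements the quantitative pipelines used to characterize
diet-induced remodeling of hippocampal astrocytes — morphometry of dye-filled
cells, gap-junction dye coupling, connexin cluster statistics, astrocytic
current decomposition, and field-potential plasticity measures — together
with synthetic-data generators that provide known ground truth for every
stage.  This note records the models, the parameters that matter, the
numerical choices, and the limits of what the synthetic benchmarks can show.

## Synthetic data model

Every generator is a pure function of a parameter record that includes a
mandatory `seed` (default 42); identical inputs give bit-identical outputs.
Noise is additive Gaussian for rasters and current traces, multiplicative
Gaussian for fluorescence and fEPSP amplitudes.  The study the generators
emulate characterizes its imaging and recording noise nowhere, so the noise
presets are package choices: 5% of the relevant signal peak for images and
amplitude series, SNR 20 (peak/noise) for current sweeps, 2% for step
responses.  They are deliberately conservative — strong enough that naive
estimators fail visibly, weak enough that the published effect sizes remain
resolvable at the published group sizes.

**Dye-filled astrocyte images** (`gen_astrocyte_image`).  A soma disk
(radius 4 µm) at intensity `soma_peak` (F_max = 200), straight filamentous
branches of width 0.75 µm radiating at jittered-uniform angles, and an
unresolved leaflet field filling the astrocyte domain at
`background + leaflet_vf * (soma_peak - background)`.  Outside the domain the
raster is pure background (F_0 = 10), including an annotated dye-free circle
(diameter 10 µm) near the farthest corner.  Default frame 100 × 100 µm at
0.25 µm/px, the lateral resolution to which real stacks are resampled.
The model deliberately omits the radial decline of process density, the
z-blur of two-photon imaging, and soma saturation; recovery tests therefore
show estimator correctness, not robustness to those real-data features.

**Coupled networks** (`gen_coupled_network`).  The patched cell sits at the
origin with normalized fluorescence 1; coupled cells receive isotropic
random directions and distances uniform in [15, 100] µm (the neighbor shell
visible in a 200 × 200 × 70 µm stack), with F(d) = exp(−d/C_λ) times
`1 + ε`, ε ~ N(0, noise_sd).  Uniform distances keep the semilog fit evenly
weighted along d; real networks sample distance by astrocyte tiling instead.

**Puncta frames** (`gen_puncta_frame`).  Disks of the stated diameter placed
by a sequential hard-core process (minimum separation, default twice the
diameter; placement rejected with a message if the expected coverage
`density × π r²` reaches 0.2), rendered by 4× supersampled area coverage,
blurred by a Gaussian point-spread function (σ = 0.08 µm, a tight confocal
PSF), and added to a low background (2) with a gentle linear ramp (1 across
the frame) plus noise (1.5 = 5% of the puncta amplitude 30).  These
intensity-scale choices put the segmentation threshold (below) at roughly
3 σ above the noise floor and about half the puncta amplitude — the regime
in which a percentile-plus-SD rule is meaningful.  The realized count is
Poisson with mean density × area.

**Current sweeps** (`gen_astro_sweeps`).  Phenomenological peak-normalized
biexponential kernels: a fast transporter-like component (−100 pA, rise
1 ms, decay 8 ms) and a slow potassium-like component (−30 pA, rise 20 ms,
decay 300 ms), inward negative, superposed linearly per stimulus
(5 × 50 Hz from 0.5 s; 5 kHz sampling; conditions with 1, 4 and 5 stimuli
plus a transporter-blocked condition retaining only the potassium kernel).
The n-stimulus trace is built as the (n−1)-trace plus the n-th component, so
the five-minus-four subtraction is exact to floating-point rounding.
Per-stimulus amplitude and decay-τ multipliers implement facilitation and
kinetic changes.  No uptake kinetics, receptor gating or cable filtering is
simulated.

**LTP series** (`gen_ltp_series`) and **step responses**
(`gen_step_response`).  fEPSP amplitudes sampled every 20 s: flat baseline
(15 min), then saturating growth toward `potentiation_factor` × baseline
with a 3-min onset time constant (fully converged long before the analysis
window).  The step response is a capacitive transient (τ = 2 ms) relaxing
onto the ohmic plateau ΔV/R.

## Morphometry

**Branch mask.**  Planes are resampled to 0.25 µm/px, filtered by
coherence-enhancing diffusion (structure-tensor driven; explicit scheme,
8 iterations, dt 0.15, gradient/tensor smoothing σ = 1 / ρ = 4 px,
isotropic floor α = 10⁻³, coherence scale 10⁻⁴ on a unit-range image — the
original filter settings are not published, so these are package defaults,
all config-exposed), collapsed by maximal-intensity projection, and
binarized with a local-mean adaptive threshold (window 51 px, offset 0).
At offset 0 the threshold bisects flat noise, so the synthetic experiment
driver passes `threshold_offset = −3 × noise SD` (foreground must clear the
local mean by 3 noise SDs); with that margin the mask reproduces the true
branch count at every radius on noisy synthetic cells.

**Sholl counting.**  Intersections per radius are connected runs of
foreground pixels along the angle-ordered rasterized circle (Bresenham),
with periodic boundary, plus a union-find merge of runs that touch under
8-connectivity across octant seams of the ring.  This equals brute-force
component counting on the ring pixels (property-tested on random masks).
Circles that leave the frame are reported missing (NaN), not zero.  Radius
step defaults to 1 µm.  No 3-D Sholl and no skeletonization: the analysis
operates on the 2-D projection.

**Volume fraction.**  Eight radial lines at 22.5°, bilinear sub-pixel
sampling at 1-px steps.  Branch crossings are excised where a
boxcar-smoothed profile (window 1.25 µm) exceeds a baseline by more than
10% of (F_max − F_0); within a detected run, raw samples above half that
margin are flagged.  The 10% criterion is referenced to the dynamic range
(F_max − F_0); the referent is ambiguous in the field and configurable.
The baseline is the per-distance **median across the eight lines** in the
full pipeline: a running median along a single line (retained as the
standalone default, window 5 µm) cannot flag a line that runs *along* a
branch, because the baseline itself rides the branch — on synthetic cells
this single failure mode biased VF upward several-fold whenever a line fell
within ~3° of a branch axis.  F_0 is the mean of a 10-µm circle outside the
arbor (the annotated dye-free circle when present, otherwise the darkest
feasible circle); F_max is the peak of the cross-line mean profile, taken
after averaging so that single-pixel noise does not inflate it.  VF(i) =
(F(i) − F_0)/(F_max − F_0) is averaged over 8–30 µm; values are not clamped
to [0, 1], so noise may push individual samples slightly outside.  The
estimator is exactly invariant to affine intensity rescaling of the image.

## Coupling

3-D Euclidean distances to the patched soma; least squares of ln F on d with
the intercept fixed at 0, matching the unit prefactor of
F(d) = exp(−d/C_λ) (a free-intercept variant is available, and both agree
exactly on noiseless data); C_λ = −1/slope.  Cells with non-positive
fluorescence are excluded with a warning; the patched cell is kept and
contributes nothing under the fixed intercept.  The "coupled" count uses a
configurable detection threshold (default 0.02 of the patched-soma
fluorescence, i.e. twice a 1% noise floor) because no threshold is published.

## Connexin clusters

**Segmentation.**  Per z-plane (no 3-D merging).  A pixel is foreground when
its high-pass excess over the local smoothed background (Gaussian, σ = 25 px)
clears the margin `p99(smoothed) + SD`, referenced to the local background —
equivalently, when its raw value exceeds p99(smoothed) + SD.  The local
referencing makes the rule exactly invariant to a constant intensity offset,
which the naive zero-referenced version is not.  The SD defaults to that of
the high-pass image (it tracks the noise floor; the smoothed-image variant is
selectable but leaves a sub-noise margin on low-contrast frames).  Components
of ≥ 5 pixels at 8-connectivity become clusters; both choices configurable.

**Statistics.**  Cluster diameter is the maximum pairwise distance between
member pixel centers (convex-hull accelerated; equal to the O(n²) oracle,
property-tested to 500 px).  Inter-cluster spacing is the Delaunay edge-length
distribution of unweighted pixel centroids (hull boundary edges kept by
default; collinear degeneracies fall back to path edges).  The radial profile
uses rings 2.5→50 µm in 0.5 µm steps with **areas clipped to the frame** by
pixel counting, so Σ density × area equals the in-range cluster count exactly
even when outer rings leave the field of view; rings wholly outside have NaN
density and are excluded from summaries.

**A resolution limit worth stating.**  A retained cluster must occupy ≥ 5
pixels = 0.3125 µm² at 0.25 µm/px, but a 0.5-µm disk has a true area of
0.196 µm².  Such sub-resolution puncta are only detected when PSF blur
spreads them across enough supra-threshold pixels, which at the package's
(realistic) PSF and threshold happens for roughly a third of placements:
the recovered density of 0.5-µm clusters is ≈ 0.09/µm² when 0.24/µm² were
placed.  Making them detectable would require a several-fold broader PSF
and a threshold far below half-amplitude, which in turn inflates measured
diameters of µm-scale clusters by ~0.2–0.4 µm.  The package keeps the
regime that measures µm-scale clusters faithfully (the scale of the real
biology) and documents that densities of sub-µm objects at this pixel size
are lower bounds.

## Electrophysiology

Per-condition sweeps are averaged and the pre-stimulus baseline subtracted.
The fifth-stimulus response is the pointwise 5-minus-4 difference.  I_K
amplitude is the extremum of the 20-ms-smoothed current from 200 ms after
the last stimulus to the end of the sweep; if the current only decays over
that window the value at +200 ms is used (the documented fallback), and the
decay from that point is fitted with `fit_monoexp`
(A·exp(−t/τ) + C; log-linear initialization, relative tolerance 10⁻⁸, max
10 000 evaluations; non-convergence or unphysical τ is flagged on the
result, never silently replaced — degenerate inputs such as white noise
surface as flagged fits or τ confidence intervals spanning orders of
magnitude).

The transporter-insensitive residual recorded under transporter blockade is
reconstructed as a saturating mono-exponential rise (fitted on the 10–90%
segment) spliced at the empirical peak to a mono-exponential-plus-offset
decay, both limbs tied to the peak value so the splice is exactly
continuous; on noiseless biexponential input the reconstruction is within
2% RMS of the trace.  Subtracting it (time-shifted to the stimulus of
interest; shifts are whole samples at 5 kHz) yields pure I_GluT, whose decay
is fitted over a bounded 100-ms window after the extremum — fitting to the
end of a 1.5-s sweep left the optimizer conditioned on flat noise and
occasionally divergent.

Input resistance is ΔV over the plateau current change of a −5 mV step
(plateau = last 20 ms of the step; a residual linear drift above 2% of the
step current flags the estimate as unsettled).  EPSC charge transfer is the
trapezoidal area of the baseline-subtracted current over a peaks window and
a tail window; window edges are inclusive on the right so adjacent windows
tile the trace additively.  The boundaries are required parameters (defaults:
peaks = stimulus train + 20 ms, tail from +50 ms to the end of the
depolarization) because no numeric boundaries are published.  Drug effects
are reported as percent of the untreated charge per window.  LTP magnitude
normalizes the baseline mean to 100% and averages the 50–60 min post-HFS
window by default; the 40–50 min variant that appears in parts of the
literature is selectable and the result records which window was used.

## Statistics and the synthetic experiment

Student's pooled-variance two-sample t tests (Welch selectable), two-sided
unless a direction is declared per metric in the configuration; a
Shapiro-Wilk screen is reported alongside, never used to switch tests; no
multiple-testing correction is applied — the report states per-metric
uncorrected p values.  The group × radius repeated-measures (mixed) ANOVA
with sphericity assumed and partial η² is delegated to
`pingouin.mixed_anova` behind a balance check; its sum-of-squares
decomposition is verified against a hand-worked 2-subject × 2-level table in
the test suite.  Blot normalization divides each lane's target/actin ratio
by the calibrator lane's ratio on the same blot and scales the control-group
mean to exactly 1.0; it is exactly invariant to per-blot gain and to global
actin rescaling, and calibrator lanes are excluded from group summaries.

`run_experiment` draws per-(metric, group, animal) seeds from a single
configuration seed via SHA-256, generates cohorts from group presets
parameterized at the published group means, runs every requested pipeline,
and emits mean ± SEM, test and p per metric with provenance (seed and
configuration hash); the density and diameter cluster metrics use decoupled
frame conditions (sub-µm disks for density, sparse frames for diameter)
because their preset values combined would violate the hard-core coverage
precondition.  Under identical presets the per-test false-positive rate is
calibrated at α (checked at 2000 replicates); presets differing only in
leaflet occupancy flag the volume-fraction metric and not the Sholl ANOVA.

## Problem sizes

The validation suite uses 5–12 replicates per recovery experiment (matching
the published group sizes), 50-seed fit-bias sweeps, 2000-replicate
type-I-error calibration, and an all-module experiment at n = 10 per group;
the whole suite runs in well under a minute on one CPU.
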