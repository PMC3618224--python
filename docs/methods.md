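# Methods

This note documents the models implemented in `egoflow`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the design was open.

## Stimulus model (`flowfield`)

Dots live in 2-D screen-angle coordinates (deg, x rightward, y upward,
origin at fixation). The "3D" character of the stimuli is carried by
eccentricity-dependent speed and size gradients that stand in for depth;
a true 3-D point cloud with perspective projection is deliberately out of
scope.

**Geometry.** The wide-field display is modeled by flat-screen
trigonometry: a screen point at offset *s* cm viewed from distance *d* cm
subtends atan(*s*/*d*). The default geometry (20 cm distance, half-extents
chosen to give ±34.5° horizontally and ±27.5° vertically) has an oblique
half-extent of atan(√(tan²34.5° + tan²27.5°)) = 40.77°, i.e. a full
oblique extent of 81.5° (≈82°). Eccentricity of a point (x, y) in angle
coordinates is computed as atan(hypot(tan x, tan y)) — the true angular
eccentricity of the screen point — rather than hypot(x, y), which would
exceed the oblique half-extent at the field corners (44.1° vs 40.8°).

**Speed law.** Speeds scale logarithmically with eccentricity:

    v(e) = v_min + (v_max − v_min) · ln(1 + e/e₀) / ln(1 + e_max/e₀)

The scale e₀ is calibrated by 1-D root finding (brentq on log₁₀ e₀, tensor
trapezoid quadrature for the field mean) so that the *number-weighted*
mean speed over a uniformly dense field equals the tier's nominal average.
The choice of number weighting (vs. area- or time-averaging) is a
documented assumption; for the low tier (1–20 deg/s, mean 18) and high
tier (10–70, mean 50) the constraint has a unique solution. For the mid
tier (5–50, nominal mean 30) no concave logarithmic law can reach the
target: the law's uniform-field mean is bounded below by its linear
(e₀ → ∞) limit, ≈31.05 deg/s on this field. Calibration then warns and
uses the quasi-linear limit (closest achievable mean, ~3.5% above
nominal). This is a genuine incompatibility between the three printed
numbers and the stated functional form, not an implementation limit.

**Size law.** Dot diameter maps affinely from [0, e_max] to [0.1°, 4°].
Strict proportionality to eccentricity would force zero size at fixation,
contradicting the 0.1° minimum; the affine map honors both endpoints.

**Dynamics.** Frames advance at dt = 1/60 s. Dots age by dt per frame and
are respawned at uniform-random field positions (age 0, size/speed
re-read from the laws) when their age exceeds the 350-ms lifetime
(21 frames) or they exit the field, which also holds density constant at
0.04 dots/deg². The global direction sign flips at every multiple of
500 ms of clip time; clip time restarts at 0 at each trial onset, so a
3-s trial contains reversals at 0.5 … 2.5 s exactly (a clip of duration T
spans frames 0 … T − dt; the frame at T belongs to the next trial).
Integration is explicit Euler except for circular flow, which rotates
each dot exactly around fixation (eccentricity conserved to machine
precision, satisfying the O(dt²)-per-step drift requirement trivially).
Translational and circular dots keep the speed and size assigned at
birth; radial and spiral dots re-read the speed law at their current
eccentricity every frame (they accelerate outward). Spiral flow mixes
radial and tangential unit vectors at a fixed, configurable 45°. The
random condition redraws each dot's direction (uniform on the circle) and
speed (uniform in [v_min, v_max]) every 500 ms — a 2-D collapse of
"random motion in a 3-D box" that preserves local motion in all
directions with no global flow structure. All randomness flows through
explicit integer seeds; equal seeds give bit-identical clips.

## Run designs (`design`)

The event-related run concatenates 105 contiguous 3-s trials (ITI 0):
15 per condition for translational, circular, radial, spiral, random and
static (5 per speed tier each), plus 15 null/fixation trials inserted as
consecutive triplets after every 18 non-null trials. Stimulation starts
at the beginning of the fifth volume (t = 8 s at TR = 2 s); the run needs
ceil((8 + 315)/2) = 162 volumes (324 s). Pseudo-randomization draws
permutations until no two consecutive trials share both condition and
speed tier; the stricter no-repeated-condition constraint would make
rejection sampling infeasible (acceptance probability ~e⁻¹⁴) and is not
what the constraint states. Block localizers run 8 cycles of 16 s ON /
16 s OFF (256 s, 128 volumes); the MT/MST+ localizer adds a 15°-diameter
aperture centered 10° left or right of fixation with radial motion
alternating in/out every 2 s. The retinotopy run is 8 cycles of 64 s
(512 s, 256 volumes); block runs are timed so the cycles fill the whole
acquisition.

## Synthetic BOLD (`synth_bold`)

Each ROI time series is

    baseline + drift + Σ_condition amplitude · (event train ⊛ HRF) + AR(1) noise

- **HRF**: canonical double-gamma (peak delay 6 s, undershoot delay 16 s,
  unit dispersions, undershoot ratio 6, 32-s support), peak-normalized.
  Regressors are built by fine-grid (10-ms) convolution of duration
  boxcars and sampled at volume times.
- **Noise**: stationary AR(1) with marginal s.d. σ and lag-1
  autocorrelation ρ, initialised from the stationary distribution.
- **Drift**: a single cosine of period 256 s (beyond the 128-s high-pass
  cutoff) whose *phase is drawn per run* from the seeded RNG. Scanner
  drift is not phase-locked to the paradigm; locking it would turn the
  small fraction of drift variance that leaks past the DCT basis into an
  identical additive bias on every condition estimate in every simulated
  run.

Volumes assign each ground-truth sphere's clean signal to its voxels with
independent per-voxel noise (no spatial autocorrelation — smoothing of
real data is out of scope, and the planted layouts are spheres). Under a
lateralised-aperture localizer, ROIs flagged as not ipsilaterally
responsive (MT-like) receive signal only when the stimulated hemifield is
contralateral to their hemisphere; MST-like ROIs respond to both.

The bundled validation conditions are: baseline 100, voxel σ = 1 (1% of
baseline), ρ = 0.3, drift amplitude 1; coherent-condition amplitude 0.25
in signal units, which at the unit-trial regressor peak of ≈2.79 is
≈0.7% percent signal change; 8-mm-radius spherical ROIs on the 3-mm grid
(~81 voxels), so the spatially averaged ROI series has noise s.d. ≈0.11.
One run per simulated hemisphere is used (real studies average several);
regions are placed at the coordinates typical for V6, MT, MST+, V3A, CSv
and IPSmot. For a planted coefficient R > 0 the random-condition
amplitude is 0.25/R; for negative R (CSv-like suppression) the random
amplitude is −0.25 and the coherent amplitudes 0.25·|R|, keeping all
percent signal changes below 1%.

## GLM (`glm`)

The design matrix holds one HRF-convolved regressor per modeled condition
(null/fixation periods are the implicit baseline, so condition betas are
amplitudes relative to fixation), an orthonormal DCT high-pass set with
periods above 128 s (k = 1 … floor(2·T/128)), and a constant. Estimation
is two-pass: OLS; pooled lag-1 residual autocorrelation (one ρ per run,
shared across voxels); AR(1) prewhitening of data and design; refit. The
raw pooled autocorrelation of OLS residuals is biased by the projection
(≈ −0.07 for 12 regressors over 162 volumes), so the estimate solves
E[observed autocorrelation | AR(1) ρ] = observed, using the trace
identities tr(M S M V(ρ)) / tr(M V(ρ)) with M the residual-maker and S
the symmetrized lag operator (brentq; skipped for runs longer than 2000
volumes, where the bias is negligible and the traces would need O(n²)
memory). This scheme is a documented approximation to full ReML with an
AR(1)+white model. With ρ pooled across a run's voxels the
motion-vs-static F test is calibrated (5.0% empirical size at α = 0.05
over 500 null runs); estimating ρ from a single short series inflates the
size to ≈7%, which is why regional inference always pools.

Contrasts are standard F tests on the whitened fit; motion-vs-static uses
the five rows (motion_i − static). Voxels with residual variance at
rounding-error level (noiseless fits) are assigned F = ∞ for a real
effect and F = 0 for a numerically null one, so noiseless volumes
threshold sensibly. Thresholding is Benjamini–Hochberg FDR on the
voxelwise p values followed by removal of connected components smaller
than the extent threshold (default 10 voxels, face connectivity,
configurable to 18/26). Percent signal change is
100 · β · peak(unit-trial regressor) / run mean — PSC has no universal
definition; this convention is fixed and used consistently by generator
and analysis.

## ROI rules (`roi`)

Peak-based regions collect the suprathreshold voxels within 8 mm
(world-coordinate Euclidean distance) of each strict local maximum
(26-neighborhood; plateaus yield no maxima by the strictness convention);
voxels within reach of several maxima join the nearest one, ties going to
the larger statistic. The MT/MST+ split takes the two localizer masks:
MST+ is the largest connected component of the ipsilaterally driven
voxels; MT is the largest component of the contralateral-only voxels with
every voxel lying anterior to the median MST+ coordinate removed. The
anterior axis is the world-mm posterior→anterior (y) axis, configurable;
using world coordinates rather than slice indices is a documented choice.
An empty ipsilateral mask raises a dedicated error — hemispheres without
an identifiable MST+ are a legitimate empirical outcome that callers must
be able to distinguish from failure. Regional profiles average the time
series over ROI voxels first and then fit the GLM (for a fixed whitening
matrix this equals averaging per-voxel betas, by linearity; the averaged
series gives the pooled-ρ estimate a cleaner substrate).

## Coherence (`coherence`)

MC is the mean of the four coherent-condition amplitudes, MI the random
amplitude; the MC/MI ratio is formed per hemisphere and the per-hemisphere
ratios are then averaged (ratio of means first, mean of ratios across
hemispheres), reported with the SEM across hemispheres. Ratios are never
clamped — negative values are meaningful (suppression by incoherent
motion) — but any hemisphere with |MI| < 5% of |MC| raises an instability
flag, since the ratio estimator's variance and bias explode as MI → 0
(E[MC/MI] ≈ R·(1 + σ²_MI/MI²)). The repeated-measures ANOVAs implement
the classical within-subject decomposition, F = MS_effect /
MS_(effect×subject), df = (k−1, (k−1)(n−1)); the 2×k region-by-condition
interaction reduces to a one-way RM ANOVA on the per-subject region
difference scores. Post-hoc comparisons use pairwise paired t tests with
Holm correction (a modern replacement for legacy multiple-range tests).
Sphericity corrections and mixed-effects models are out of scope.

## Retinotopy (`retinotopy`)

The stimulus-frequency F ratio divides the spectral power at the stimulus
bin (8 cycles/scan) by the mean power over the noise band. The noise band
excludes the 2nd and 3rd harmonics and additionally DC and the two bins
adjacent to the stimulus bin (standard leakage protection; a documented
addition to the minimal exclusion). The dof are the conventional
(2, 2·n_noise) — each spectral bin of real data carries a sine and a
cosine degree of freedom. The response phase negates the raw spectral
phase so that a response delayed by t₀ maps to +2π·t₀/period, then
subtracts a fixed hemodynamic delay (default 5 s, configurable; no
empirical delay estimation). Field sign is the sign of the Jacobian
determinant of the (polar angle, eccentricity) map from central
differences on a flat 2-D grid (one-sided at borders), oriented so the
identity visual-field map is +1; nodes where either gradient vanishes are
undefined. Surface meshes and cortical flattening are out of scope; the
flat grid is the flattened-cortex analog.

## Orchestration and problem sizes

`pipeline.run_full_pipeline` chains stimulus summaries, the event-related
design, per-region coefficient recovery and the localizer-driven MT/MST+
split from a single `RunConfig`; all randomness derives from the config
seed, and equal configs give bit-identical reports. The validation suite
and `scripts/acceptance.py` use 3-s clips (180 frames, ~150 dots), single
162-volume runs per simulated hemisphere, cohorts of 26/20/26 hemispheres
for the coefficient-recovery checks, 500 null runs for the F-test size
check and 5000 for the rm-ANOVA size check — sizes chosen so the whole
validation completes in well under a minute while keeping Monte-Carlo
error comfortably inside the stated tolerances.

## What passing tests do and do not show

The generator plants exactly the effect structure the analysis assumes
(canonical HRF, AR(1) noise, spherical ROIs, hemifield gating), so
parameter-recovery results validate the *implementation* of the chain,
not the biological adequacy of those assumptions. Real data add spatial
noise correlation, motion artifacts, HRF variability across regions and
subjects, non-AR(1) physiological noise, and ROI shapes far from spheres;
none of these are modeled. Group-level voxelwise inference (random
effects, non-sphericity) is likewise out of scope — group claims here are
hemisphere-averaged regional summaries.

## Known limitations

- The mid speed tier's nominal mean is unattainable under the concave
  logarithmic law (see above); the generator uses the closest achievable
  law and warns.
- The ratio-of-betas coefficient is biased upward by noise in MI
  (≈ +3% under the bundled conditions for the largest planted ratio);
  cohort averaging reduces the scatter but not this bias.
- AR(1) prewhitening with a pooled ρ is an approximation to ReML; for
  strongly heterogeneous voxel autocorrelations the shared-ρ assumption
  is wrong by construction.
- The clip-measured mean speed of radial flow sits ~1–2% below the
  calibrated uniform-field mean because outward/inward motion and edge
  respawning slightly reshape the eccentricity distribution within a
  dot's lifetime.
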