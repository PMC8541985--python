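# Methods

`stereoprf` implements two linked computational pieces: (i) population
receptive field (pRF) estimation for BOLD-like timeseries recorded under
retinotopic stimulation whose aperture is defined by different visual
properties (contrast, luminance, motion, correlated or anti-correlated
binocular disparity), and (ii) a binocular energy model simulation that
asks how the apparent pRF size of a population of disparity-tuned V1-like
complex cells depends on the stimulus class used to map it.  Because no
imaging data ship with the package, a synthetic-data module generates
ground-truth cortices and BOLD runs with the statistical structure the
analysis assumes; every pipeline stage is tested against that ground
truth.

## Visual field, apertures and stimuli

The visual field is a square raster in degrees of visual angle with
fixation at the exact centre pixel (odd pixel counts by construction),
x increasing rightward and y upward.  The default scan field has a
10 deg half-extent at 10 px/deg; the energy-model field uses 12 deg so
that the largest simulated receptive fields are untruncated.

Mapping apertures are binary masks on this raster:

* **wedge** — a 20 deg-wide sector of the annulus between the 0.5 deg
  fixation cut-out and the field edge, rotating clockwise or
  counter-clockwise in equal angular steps;
* **ring** — an annulus sweeping log-spaced eccentricities (expanding or
  contracting), with thickness a fixed duty fraction (default 0.25) of
  the log-eccentricity cycle and wrap-around at the ends;
* **bar** — a straight bar (default width 1 deg) translating across the
  field in equal steps (100 for the model sweeps).

A scan run is 168 volumes at TR 2.488 s including 24 blank volumes in
four contiguous 6-volume blocks; four runs per condition give 672
volumes.  The aperture cycle is 18 volumes (44.8 s): the paper-derived
preprocessing emulation high-passes at 0.02 Hz, and an 18-volume cycle
keeps the stimulus fundamental (0.022 Hz) above that cut-off, which a
36-volume cycle would not.  Only aperture geometry enters the design
matrix; the carrier content (chequerboard or dots) does not.

Stimulus content:

* **chequerboard** — radial pattern with 5 deg angular sectors and
  log-scaled ring widths from 0.016 to 0.49 deg (geometric widths,
  rescaled to tile the field), contrast-reversing; mid-grey is 0 and
  the pattern mean is ~0.
* **random-dot stereograms** — 40% pixel coverage, 0.12 deg dot radius,
  half white/half black per eye (balanced within one dot).  Inside the
  aperture, dots are binocularly correlated with a symmetric horizontal
  offset of ±disparity/2 per eye (right minus left = +disparity),
  anti-correlated (matched positions, right-eye polarity negated), or
  correlated at zero disparity; the background is drawn independently
  per eye for these modes.  The luminance mode is binocularly identical
  everywhere; its default model reading gives aperture and background
  dots uniform, mutually opposed polarities (variance-matched, opposed
  mean luminance).  The participants'-display reading (uniform-polarity
  foreground over a balanced background) and a polarity-flip reading
  are available as `polarity_style` options; the flip reading is
  variance-matched to its background and therefore produces no
  aperture-locked response in a squaring energy model, which is why it
  is not the default for the simulations.  The motion mode tags
  aperture dots with tangential velocities (half clockwise, half
  counter-clockwise at 7 deg/s) used for frame-to-frame displacement.

Dots are rendered with sub-pixel centres (a pixel belongs to a dot when
its centre lies within the dot radius).  Overlapping dots are resolved
by clipping the signed polarity sum to [-1, +1]; covered pixels whose
polarities cancel exactly take a balanced random sign shared between the
eyes (negated for anti-correlated content).  This rule is vectorisable
at the frame volumes the simulations need, keeps measured coverage at
the nominal 40%, and preserves the anti-correlation negation identity
exactly; it replaces draw-order occlusion, which would force per-dot
sequential compositing.

## Haemodynamics

The HRF is a difference of two gamma-density lobes parameterised by their
modes: the positive lobe peaks at `peak_delay` (default 6 s, dispersion
1 s), the undershoot at `undershoot_delay` (default 16 s, dispersion
1 s) scaled by `undershoot_ratio` (default 1/6).  Estimation averages
trial epochs pointwise and fits all six parameters by bounded least
squares from the canonical start.  Kernels are sampled to 36 s — at the
conventional 32 s the truncated tail exceeds 1e-3 of the peak once the
peak delay passes ~6.5 s — and are unit-peak normalised before
convolution: only the HRF shape is carried into pRF fitting, with
per-vertex amplitude absorbed by the prediction scaling.

## pRF estimation

The forward model is the overlap of a unit-volume isotropic 2-D Gaussian
(x, y, sigma) with the binary aperture at each volume, convolved with the
HRF kernel.  Amplitude and baseline are solved per candidate by ordinary
least squares with free sign, making the stage-1 correlation objective
and the stage-2 variance-explained objective identical (variance
explained is the squared correlation of the scaled prediction).

Stage 1 is an exhaustive grid search (defaults: 21 x and y steps across
the field, 16 log-spaced sigmas from 0.1 to 5 deg) run on spatially
smoothed series when a cortical mesh is supplied (Gaussian neighbourhood
weights, FWHM 5 mm, truncated at 3 SD, row-normalised).  Ties break to
the lowest grid index.  Stage 2 refines (x, y, log sigma) by Nelder-Mead
on the unsmoothed series (xatol 1e-5; fatol 1e-9, far below the
R-squared scale because parameter precision, not objective precision,
is what matters; max 600 iterations; an explicit initial simplex at
physical scales — half a position grid step, ~15% in size — because the
solver's default perturbation of a zero coordinate is microscopic and
strands the search).  Log-sigma parameterisation keeps sigma positive
without clipping, and the refinement never returns a fit worse than its
seed.

Drive integrals are evaluated on a block-averaged float32 raster of
about 5 px/deg (masks become fractional coverage).  The integral is
unchanged to second order in the pixel size; against data generated at
the full 10 px/deg raster, worst-case parameter error from this
approximation is ~0.1% of sigma, against a 2% recovery requirement,
while fitting runs roughly six times faster.

Model validation uses the split-half normalised correlation coefficient:
the correlation between prediction and mean observed response divided by
the maximum achievable given across-repeat reliability, with signal
power estimated as `(Var(sum of repeats) - sum of Var) / (N (N-1))` for
N = 2 contiguous half splits.  Non-positive estimated signal power flags
the vertex unreliable (NaN).  Filtering is strict: vertices survive only
with CCnorm > 0.5 (a value exactly at threshold is removed) and
eccentricity at or above the 0.5 deg fixation cut-out.

## Binocular energy model

A monocular receptive field is a vertically oriented Gabor: a horizontal
sinusoid (phase referenced to the filter centre) under an anisotropic
Gaussian envelope with vertical SD fixed at 1.5x the horizontal SD and
unit-volume normalisation.  The simple response is the inner product of
filter and image; left and right responses sum and square into an LN
element, and the four phase-quadrature LN elements (0, pi/2, pi, 3pi/2)
sum into the complex response.  Since the pi and 3pi/2 filters are exact
negatives of the 0 and pi/2 filters, the engine computes two LN elements
and doubles the sum — an identity, not an approximation — and collapses
the separable filters against each frame (vertical projection, then
horizontal inner products), which is what makes population-by-frame
sweeps tractable.

Disparity tuning is a horizontal position offset delta between the eyes
(left centre - delta/2, right + delta/2).  Populations (1000 units at
paper scale, 100 in the desk profile used by the tests) are centred at
fixation with Gaussian positional jitter (SD 0.1 deg); the horizontal
envelope SD sweeps 15 values from 0.2 to 3 deg.  The carrier spatial
frequency rule "x0.5 the horizontal size" is read physiologically as
f = 0.5 / sigma_h cycles/deg, i.e. a fixed half cycle per envelope SD
(the product f*sigma_h is the quantity macaque V1 confines to roughly
0.5-3.5); the alternative literal reading f = 0.5 * sigma_h is available
via `sf_reading`.  The three population manipulations are: size only
(fixed SF rule, all units tuned to the stimulus disparity), size + SF
(multiplier uniform in 0.5-3.5), and size + SF + disparity jitter
(tuning jittered with SD 0.25 deg).

Sweeps present each aperture step to the population and average complex
responses over frames and units.  Units are tuned to the stimulus
disparity of their condition: 0 for chequerboard and luminance, 0.2 deg
for correlated and anti-correlated disparity.  The interocular-
correlation control presents a zero-disparity correlated aperture over
an uncorrelated background to the *disparity-tuned* population — the
question being whether correlation alone can drive it.

The size read-out fits the Gaussian-overlap prediction (no HRF; these
are neural responses) to each cohort's response series with the centre
fixed at the population centre and only sigma free; amplitude and
baseline are solved per candidate with free sign, so constant offsets
and response polarity are absorbed.  A coarse log-spaced scan brackets
sigma before bounded refinement.

### Simulation design choices

Monte-Carlo structure matters at the desk scale the tests run at, so the
simulation uses three standard variance-reduction devices, all unbiased:

* **Common random numbers.**  One full-field dot sample per sweep is
  reused at every aperture step (only aperture membership changes as the
  bar moves), by every size cohort, and — through identical sub-seeding
  — by every condition.  Sampling error then varies smoothly along the
  transit profile, across the size sweep and between conditions, which
  is what the shape-sensitive size read-out needs.
* **Antithetic eye-role balancing.**  The conditions with independent
  per-eye backgrounds use two dot sets; half the frames give set A the
  foreground/left-background role, half give it to set B.  The frozen
  A-B difference inside the aperture strip, which would otherwise ride
  on the profile as a monocular-variance ripple, cancels in the
  average.
* **Fixational scene jitter.**  Every frame the whole retinal image
  (dots and aperture edges together) shifts by a uniform random offset
  (±0.25 deg; stratified horizontal phases for the deterministic
  chequerboard).  This emulates fixational eye movements and phase-
  averages carrier-locked components (bar-edge ringing, chequerboard
  phase alignment) that otherwise alias into the transit profile.  The
  read-out fits nominal aperture positions, as in the experiments.

Each cohort is simulated inside a rectangular window covering its
envelope to 3 SD (the response integrand is negligible outside).  The
contrast probe is a contrast-reversing square-wave carrier at the
cohort's median spatial frequency — the component of the display's
scale-matched radial checks that a vertically oriented filter sees at
the eccentricity the cohort stands for.  A fixation-centred population
sees only the centre of the literal display pattern, where any finite
raster either aliases the sub-pixel rings into spurious broadband
texture (the size read-out then saturates) or, fully resolved, produces
ring-locked multi-lobed responses; the matched carrier gives the
coherent response whose quadrature sum is exactly invariant to pattern
phase, so the deterministic sweep needs only the stratified jitter
offsets (8 per step) on a raster of ~8 px per carrier period.

### What the model predicts, and why

For a population tuned to the stimulus disparity, the aperture-locked
part of the mean complex response to correlated dots is the interocular
covariance term.  A useful exact property of the position-shift model:
for dot pairs at the tuned disparity, the left- and right-eye shifts
cancel inside the covariance integrand, so each dot pair at cyclopean
position u contributes the *squared envelope* evaluated at u regardless
of the tuning offset.  The transit profile is therefore the aperture
convolved with a kernel of width sigma/sqrt(2) (plus dot-footprint
smoothing) centred at the cyclopean RF centre — disparity tuning shifts
nothing and widens nothing.  Two consequences:

* Fitted size scales linearly with monocular RF size for the disparity
  condition (slope ~ 1/sqrt(2) of the envelope SD).
* The model offers *no structural mechanism* by which the
  disparity-defined size should exceed the luminance- or
  contrast-defined size at every scale.  The luminance stimulus (a
  mean-luminance step, sensed by zero-DC filters at its edges) and the
  alternative variance-defined readings all yield profiles in the same
  sigma/sqrt(2) family, offset by aperture-geometry terms of order the
  bar width squared that can carry either sign.  In this implementation
  the luminance and chequerboard sizes track the disparity sizes within
  a few percent and typically sit slightly above them; the strict
  size ordering reported for the original simulation is not reproduced,
  and the tests that assert it document that honestly rather than
  encode a tuned exception.

The chequerboard and luminance read-outs are nearly coincident — both
are aperture-geometry-dominated coherent responses — matching the
observation that contrast- and luminance-defined model sizes pattern
together.  Anti-correlation flips the sign of the covariance term: the
transit modulation has the same magnitude and width (the fitted size is
unchanged, since the read-out solves amplitude with free sign), but the
response series itself is anti-phase to the correlated one; a
correlation of the two series is therefore strongly *negative* even
though the fitted sizes agree.  A rotating wedge over the
fixation-centred population modulates the response only through
envelope anisotropy, and the fixed-centre overlap read-out carries no
size information from it: the zero-disparity correlated wedge yields no
growth of fitted size with monocular RF size, consistent with
interocular correlation alone not generating the eccentricity-scaled
responses seen in BOLD.

## Synthetic cortices and BOLD

Vertices draw eccentricities uniformly in visual-field area over a
configurable range and polar angles uniformly; ground-truth sigma
follows a linear eccentricity rule per condition (all rules synthetic
demonstrations, not empirical claims).  BOLD runs are the noiseless
forward predictions plus additive noise: white, stationary AR(1), and
slow cosine drift below the 0.02 Hz cut-off (so the preprocessing
emulation can remove it exactly).  Noise SDs may be expressed relative
to each vertex's prediction SD; white SD 1.0 (relative) gives split-half
reliability ~0.5 and fitted variance explained ~0.5, the calibration the
recovery tests use.  Test meshes are square planar lattices (exact
spacing) or Fibonacci spheres with convex-hull adjacency.

The generator shares the forward model's code for predictions but
evaluates it on the exact full-resolution raster, so the fitting path's
pooled-raster approximation is genuinely exercised by recovery tests.

## Problem sizes

Tests and the acceptance script run: 200-vertex recovery against a
336-volume wedge+ring design; the desk-profile energy simulation (100
units, 100 frames per step, 100 bar steps, 15 sizes, three conditions,
under the size+SF manipulation so that carrier diversity decorrelates
the units' squared responses and population averaging genuinely reduces
sampling noise); a single-cohort correlated/anti-correlated comparison;
the wedge control at the same desk profile (36 wedge steps); 1000
CCnorm replicates.  These sizes keep the full suite within tens of
minutes on one CPU; the paper-scale profile (1000 units, 1000 frames)
is available through the same interfaces.  The size read-out carries a
validity floor (fit R-squared >= 0.2, in the spirit of the CCnorm
threshold on the empirical fits): below it the overlap model explains
nothing and the returned size is numerical noise, as happens for every
condition when a rotating wedge sweeps a fixation-centred population.
A size-versus-RF-size slope is only quoted when at least three cohorts
yield valid read-outs.

## Limitations

* The synthetic noise model (white + AR(1) + drift) omits physiological
  spectra, motion artefacts and spatial noise correlations; recovery
  results bound estimator behaviour under the stated model only.
* The energy model is the classical position-shift form: anti-correlated
  stimuli drive it at full strength, unlike real V1 responses, and no
  output nonlinearity attenuates them (deliberately out of scope).
* All model units share one disparity tuning (plus optional jitter);
  populations mixing many preferred disparities are not simulated.
* The luminance-condition reading and the carrier-frequency constant are
  resolved as described above; both alternatives remain selectable.
* Motion-mode dots carry velocity tags and can be advanced frame to
  frame, but no motion-energy read-out is implemented: the motion
  condition enters the pRF pipeline only through its aperture design,
  mirroring how the analysis treats it.
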