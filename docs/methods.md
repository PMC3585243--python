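# Methods

This package re-creates, on synthetic data with known ground truth, the
computational chain used in adaptive-optics scanning-laser-ophthalmoscope
(AOSLO) studies that relate the structure of the foveal cone mosaic to
visual resolution: mosaic spacing metrics and Nyquist limits, the retinal
magnification chain, transverse-chromatic-aberration (TCA) measurement from
dual-wavelength calibration videos, adaptive psychophysics, cone-stimulation
maps, midget-ganglion-cell sampling limits, fixation-stability statistics,
and group comparisons. This note records the models, the parameters that
matter, and the choices made where the design was genuinely open.

## Cone mosaics and spacing metrics

**Generator.** A synthetic mosaic is a triangular lattice whose local
spacing grows linearly with eccentricity, `s(e) = peak_icd + icd_slope·e`
(arcmin, `e` in degrees from the preferred retinal locus of fixation,
PRLF). Defaults emulate a normal fovea: `peak_icd = 0.58` arcmin (a cone
Nyquist limit of ~0.50 arcmin at the PRLF, typical of normal eyes) and
`icd_slope = 0.35` arcmin/deg, which qualitatively follows empirical
normal spacing curves over the central 2.5°. Positional jitter is Gaussian
with SD a fraction (default 0.05) of the local spacing; carrier-like
mosaics additionally delete lattice sites independently with probability
`loss_fraction` (0.4 in the replica), emulating patchy cone degeneration
with preserved triangular packing of the survivors.

A radial spacing gradient cannot be realized by a defect-free distorted
lattice — the implied metric has curvature — so graded mosaics are built as
a lattice graded along the horizontal meridian: columns perpendicular to
the meridian are marched outward from the PRLF at steps `(√3/2)·s(|x|)`,
with in-column spacing `s(|x|)` and alternating half-spacing offsets. With
zero slope this reduces exactly to a triangular lattice with a site at the
PRLF. Within the small patches the pipeline analyzes (radius 0.2°, centered
on the meridian as in patch-wise AOSLO imaging), meridional distance agrees
with radial eccentricity to second order; measured mean Delaunay spacing
matches the analytic `s` to ~0.2% off-center and ~1.5% at the PRLF. The
residual radial-vs-meridional mismatch appears only off-axis (a cone at
(0, 12′) has the spacing of the PRLF rather than of 0.2°); this is the main
respect in which the generator is less realistic than a retina, along with
its lack of true disorder gradients, S-cone gaps, and vasculature.

**Metrics.** The inter-cone distance (ICD) of a cone is the mean length of
its Delaunay edges; "nearest neighbors" is deliberately the Delaunay
neighborhood, the standard choice for near-triangular mosaics, and it
reproduces the conventional printed ICD→Nyquist pairs. The mosaic Nyquist
limit is the triangular row spacing, `N_c = (√3/2)·ICD`; the density form
`N_c = (√3/2)·√(2/(√3 d))` (with `d` in cones/mm², converted through `m`
mm/deg) is derived from the same packing convention, so lattice density and
spacing round-trip exactly. Cones on the convex hull, or within 0.75 median
edge lengths of it, are flagged as boundary and excluded from summaries —
their neighborhoods are truncated by the crop, not by biology. Minimum ICD
is reported after smoothing per-cone values with a circular mean filter
(radius configurable, default 0.25°) restricted to within 3 arcmin of the
PRLF; whether boundary cones may carry the minimum is configurable
(excluded by default). For comparison with resolution thresholds, `N_c` is
averaged over the ±2 SD ellipse of the stimulus-position trace; a
degenerate (stationary) trace is given a 1-arcmin minimum semi-axis, since
a point region cannot support an average.

## Magnification chain

Spectacle magnification of a trial lens of power `F` (spherical equivalent,
D) at vertex distance `d` is `SM = 1/(1 − d·F)`; the vertex is fixed at
exactly 14 mm, which reproduces all recorded magnification values. Retinal
scale uses Bennett's adjusted axial length: `m = 1000·q·(AL − 1.82)·SM`
µm/deg with `q = 0.01306` mm/deg. The unrounded SM enters `m`. Note that
`m` moves ~13 µm/deg per mm of axial length, so axial lengths quoted to
0.01 mm determine `m` only to ±0.07 µm/deg; agreement is checked at that
precision where the inputs allow no better. Pixel scale is validated only
through the internal consistency of field size, raster and `m` (pixel
counts are instrument-specific).

## TCA estimation

Calibration videos alternate a window region at 2 Hz between the imaging
(IR) channel and a red channel displaced by the TCA shift, over a field
that moves with fixational motion. The estimator is two-pass: (1) stabilize
the video on an IR-only region by the peak of the FFT cross-correlation
against a reference frame, with 3-point parabolic sub-pixel interpolation
(the recorded shifts are quoted to 3 decimals of an arcmin, which demands
sub-pixel treatment); (2) re-run the same stabilization on the alternating
region of the stabilized video. The residual trace is a square wave
phase-locked to the alternation; per cycle, the shift is the red-phase mean
minus the preceding IR-phase mean, using only the second half of each
half-cycle (guard of 1 frame, configurable) to avoid transition frames.
Per-cycle shifts beyond 2 SD of the mean are rejected once, per axis
independently (rejection on per-cycle means rather than per-frame
differences; the alternative is noted as open), and the mean of the
retained cycles is reported. Frames whose correlation confidence falls
below 0.15 (blinks, blanks) are interpolated from neighbors; more than 50%
such frames aborts with diagnostics. On synthetic 20-cycle videos at the
default motion and noise, per-axis recovery error is < 0.01 arcmin and the
seed-ensemble bias < 0.01 arcmin; recovery error grows with drift
amplitude, as expected.

## Psychophysics

**Observers.** A simulated observer has a Weibull psychometric function
`P(x) = γ + (1−γ−δ)(1−exp(−(x/limit)^β))` on stimulus magnitude (letter
size in arcmin, or contrast), with guess rate γ (0.25 for 4AFC, 0.5 for
2IFC) and lapse rate δ ≤ 0.05. The inverse is available in closed form, so
an observer can be constructed whose, e.g., 82.5%-correct point sits
exactly at a prescribed value — the analytic oracle for all recovery tests.

**QUEST.** The Bayesian adaptive procedure maintains a posterior over the
log10 stimulus at the criterion level (82.5% correct for the acuity task),
assuming a Weibull likelihood with slope β = 3.5, lapse 0.01, and a
Gaussian prior (SD 0.5 log units) — standard defaults, since the study
protocol does not print them. Each trial is placed at the posterior mode;
the run estimate is the posterior mean after a fixed number of trials (40
for the AO protocol, 50 for the spectacle-only protocol). A location's
threshold is the mean of its runs. Against a matched observer, 40-trial
runs are unbiased to < 0.01 arcmin with run SD ≈ 0.09 arcmin.

**Staircase.** The contrast procedure is a transformed 3-down/1-up
staircase in 0.1 log-unit steps; the protocol's "3-up, 1-down … 79%"
wording is implemented as three-consecutive-correct-down / one-incorrect-up,
the only transformed rule whose convergence point, `0.5^(1/3) = 79.4%`
correct, matches the stated criterion. The threshold is the mean of the
last 6 reversals (count configurable; the protocol is silent). Stimulus
duration, ISI and feedback are metadata only — the simulated observer is
memoryless. The tumbling-E convention used throughout: letter height = 5 ×
MAR (5×5 grid, stroke width = MAR).

## Cone-stimulation maps

The letter (dark on bright field, Weber contrast −0.99) is rendered at grid
resolution 0.025 arcmin, convolved with the diffraction-limited PSF of a
6 mm pupil at 680 nm (Airy pattern, unit sum, first zero at 1.22·λ/D =
0.4755 arcmin), and the blurred darkness profile is integrated against each
cone's aperture — a unit-integral 2-D Gaussian with FWHM = 34% of the local
ICD. The integral's absolute normalization is not specified in the source
protocols, so per-cone values are divided by the maximum across cones
("normalized aperture filling"). The stimulus is a single static frame;
motion smear is out of scope. At threshold-sized letters (5 × the local
limit), the count of cones above half-maximal filling rises with
eccentricity, because beyond the cone-limited zone the mRGC limit sets the
letter size faster than cone spacing grows.

## Midget-RGC sampling limits

Total midget-RGC receptive-field density uses the Drasdo et al. (2007)
model in Watson's (2014) closed-form temporal-meridian parameterization:
`d(e) = 29609.2·(0.9851·(1 + e/1.058)^−2 + 0.0149·exp(−e/22.14))` per
deg². ON- and OFF-center sub-mosaics are taken as spatially redundant, so
the Nyquist-relevant density is `d/2`, and
`N_mRGC = (√3/2)·√(2/(√3·(d/2)))` (deg → arcmin). The model is a pluggable
function; its contract is a calibration checkpoint, not the parameter
values: the inverse at 1.41 arcmin must land at 2.3 ± 0.15° (it lands at
2.39°). With normal mosaic parameters, `N_c` and `N_mRGC` cross once below
1° (at ~0.36°), delimiting the foveal "private line" zone where resolution
is cone-limited. `eccentricity_shift` inverts the model by bisection on
[0°, 10°]; predicted resolution at any location is `max(N_c, N_mRGC)`. The
coupled-loss hypothesis is modeled by rescaling the density so the local
mRGC limit tracks the local cone limit.

## Fixation and motion

Synthetic fixational motion is a mean-reverting (AR(1)) random walk (step
SD `drift_sd`, reversion 0.05/frame — chosen so the positional spread is
stationary and controllable, which a pure Brownian walk is not) plus
Poisson microsaccades of fixed amplitude and uniform direction at a default
30 Hz frame rate (made explicit in the video sidecar since real AOSLO frame
rates vary). Fixation stability at a location is the per-trial positional
SD averaged over x and y (per-trial SDs averaged across trials, rather than
SD of concatenated traces). The normal envelope is an OLS regression of SD
on eccentricity with a 95% **prediction** band — prediction-style rather
than mean-response, because the band classifies individual eyes; the choice
is configurable.

## Group statistics

Descriptive summaries use the sample SD (n−1) and SEM = SD/√n. The
cortical foveal-confluence statistics are computed over the 8 hemisphere
areas, not 4 subject means — the convention that reproduces the printed
median (1435 mm²). Two-sample comparisons default to the pooled-variance
Student t (the protocols say only "t-test, two sample"), with Welch
available by flag; Cohen's d = |Δmean| / pooled SD. Printed comparisons
from summary inputs reproduce to ~±0.01–0.02 in p and d, the precision the
rounded inputs allow.

## Replica run and problem sizes

`run_replica` composes everything: 5 normal and 4 carrier eyes; per eye,
mosaic patches (radius 0.2°) at 0–2.5° in 0.5° steps; region-averaged
`N_c` from a 240-frame fixation trace; the true observer limit
`max(N_c, N_mRGC)` (carrier mRGC limits rescaled to local `N_c`); three
40-trial QUEST runs per location; one 8-cycle TCA video; fixation envelope
from the normal cohort with carrier spread generated three band-widths
above it; pooled t at the PRLF. These sizes keep a full replica under ten
seconds while leaving every recovery well-resolved; the TCA acceptance
ensemble uses the full 20-cycle, 300-frame videos. All randomness descends
from a single seed; a fixed seed regenerates the report bit-identically.

## Known limitations

- The generator's eccentricity dependence is linear and meridionally
  graded; real mosaics have curved density profiles, radial gradients, and
  disorder that this construction idealizes. Passing tests demonstrate the
  pipeline's correctness on such mosaics, not performance on real imagery.
- Cone localization is tuned for rendered Gaussian blobs over uniform
  background; real AOSLO frames have raster distortion, vignetting and
  speckle that are out of scope (no desinusoiding physics).
- The mRGC model is a normal-eye average; individual variation is absorbed
  only through the calibration-checkpoint tolerance.
- Simulated observers are stationary and memoryless: no learning, fatigue,
  or response bias, so psychophysical recoveries bound estimator error
  only.
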