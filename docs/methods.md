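# Methods

`cbct4d` simulates a gantry-speed study for four-dimensional cone-beam CT
(4DCBCT) on a linac-mounted kV imager, end to end: a moving digital QA
phantom, a virtual cone-beam scanner, retrospective respiratory phase
sorting, FDK reconstruction, and the image-quality / motion / dose metric
suite evaluated per protocol. This note records the models, the parameters
that matter, the numerical choices, and what the simulation does and does
not capture.

## The physical question

At a fixed detector frame rate `F` and arc `theta`, the gantry speed
`omega` sets the number of projections,

    N = F * theta / omega,

and, at fixed tube output per frame, the total mAs and imaging dose scale
with `N`. Slower rotation buys lower noise (CNR), better bar-pattern
resolution, and denser angular sampling per respiratory phase bin, at the
cost of dose and time. The package reproduces this trade-off and the
bookkeeping around it (projection counts, acquisition times in minutes,
total mAs, dose in cGy from a measured rate table).

## Respiratory motion model

Platform displacement follows the idealized breathing waveform

    A(phi) = A0 * (1 - cos(2 pi phi))^2,  phi in [0, 1],

with phase advancing linearly in time over period `T`. Phase 0 is
end-exhale (`A(0) = 0`), phase 0.5 peak inhale, and the peak-to-peak
excursion is `4 A0`. Defaults: `T = 5 s`, `A0 = 0.75 cm`, i.e. a 3.0 cm
superior-inferior excursion — regular breathing of a thoracic target.
`A0` is a derived configuration value: the excursion (3.0 cm) is the
stated condition and the waveform forces `excursion = 4 A0`.

Two useful closed forms, both verified numerically in the tests:

* excursion = max over phase of `A(phi)` = `4 A0`;
* mean inter-frame motion = `8 A0 / (T F)`; at 15 fps with the default
  waveform this is 0.08 cm — the imager misses 0.8 mm of motion between
  frames on average (total variation per period is twice the excursion).

The surrogate trace emulates an infrared-marker respiratory monitor: the
waveform sampled at 30 Hz (the monitor's rate is not a study condition;
30 Hz is a typical marker-camera rate), with optional Gaussian position
jitter (default 0). The surrogate platform moves in phase with the imaged
platform; an amplitude scale between them would only rescale the trace and
is irrelevant to phase sorting, so it is not modelled.

## Phantom

The phantom is an analytic attenuation model, not a voxel grid: a
water-equivalent cylinder (radius 10 cm) with four axial modules —
bar-pattern groups of 1–8 lp/cm at +500 HU (spatial resolution), a 1.5 cm
diameter insert at +10 HU = 1.0% contrast (low-contrast detectability), a
homogeneous section (uniformity), and a sensitometry section whose seven
density inserts (air −1000 HU through teflon +990 HU, 1.25 cm diameter)
span z −8..−4 cm inside a water column extending to z = −13 cm. The
extended column matters: the phantom is longer than the imaged region, so
no open air below it enters the tracked sensitometry volume at peak
inhale. Insert HU values and bar frequencies are configuration with
packaged defaults typical of solid QA-phantom materials; the bar range
brackets the few-lp/cm regime where a kV cone-beam system's 10% MTF
crossing falls.

Attenuation is `mu = mu_water (1 + HU/1000)` with `mu_water = 0.2 /cm`
(water at the effective energy of a 125 kVp beam). Motion enters as a rigid
shift of the sampling coordinate along +z, so
`sample_mu(P, x, s) == sample_mu(P, x - (0,0,s), 0)` holds exactly.

## Virtual scanner

Circular cone-beam trajectory about z, flat panel, source-axis distance
100 cm, source-detector distance 150 cm; full-fan centered geometry (no
bowtie, no scatter, no focal-spot blur, no detector lag, monochromatic
beam). The arc is exactly 360 degrees: the technique chart's projection
counts match `F * 360 / omega` exactly, so the small over-scan of a real
rotation is ignored. Frame times are `t_i = i/F`, angles `omega * t_i`;
line integrals are computed by fixed-step sampling along source-to-bin
rays (default step 0.1 cm, configurable; oracles in the tests use 0.02 to
0.05 cm), with the integration interval clipped to the housing cylinder.

Photon noise: each bin receives mean fluence `I0 = photons_per_mAs * mAs`
per projection, transmitted counts are Poisson(`I0 exp(-p)`) clamped at
one count, and the noisy line integral is `-ln(counts/I0)`. mAs per
projection defaults to 1.057, the mean total-mAs/N ratio of the six
published protocols; the ratio actually varies 1.054–1.059 across them and
the per-pulse tube parameters are not public, so the constant-ratio model
is an explicit approximation. `photons_per_mAs = 2e5` per bin gives
low-contrast CNR of a few, comparable to clinical kV CBCT; noiseless mode
(`None`) is used wherever a deterministic oracle is wanted.

## Phase sorting

Sorting uses only the surrogate trace — never the ground-truth phase.
Cycle anchors are the detected local maxima of the trace (peak inhale,
phase 0.5), found with a prominence of 10% of the trace range and a
minimum separation of half the cycle length (the cycle length itself taken
from a prominence-only first pass when not supplied); phase advances
linearly in time between consecutive anchors, and times beyond the
first/last anchor are extrapolated with the nearest cycle length and
flagged. The displacement maximum is quadratic in phase and therefore a
robust anchor; the end-exhale minimum of this waveform is quartic (flat)
and would anchor poorly. Fewer than two detected cycles is an error.

Bin assignment supports two conventions:

* `floor` (default of `assign_bins`): half-open bins `[k/n, (k+1)/n)`;
* `centered`: bin k spans `[k/n - 1/2n, k/n + 1/2n)`, wrapping at 1.

The 4D pipeline uses centered bins, the convention of clinical
retrospective sorting (the peak-inhale bin straddles phase 0.5). The
choice is not cosmetic: a thresholded reconstruction of a structure moving
with `A(phi)` recovers, per bin, approximately the bin's median
displacement. For 10 floor bins the extreme bin is `[0.4, 0.5)` with
median `A(0.45) = 2.85 cm` — a built-in ~5% excursion underestimate —
while the centered extreme bin `[0.45, 0.55)` has median `A(0.475) = 2.96
cm`, within 2% of the true 3.0 cm. Measured values in this package match
both predictions.

A note on bin occupancy: at 15 fps and `T = 5 s` there are exactly 75
frames per breathing cycle, so 10 bins receive 7.5 frames per cycle and
occupancies necessarily alternate 8/7 within every cycle; over a 5400
projection scan the bins hold 540 +/- 36 projections, not exactly 540.
Occupancy conservation (sum = N, bins disjoint) is exact and tested.

## Reconstruction

Standard FDK filtered backprojection: cosine pre-weighting, row-wise
Ram-Lak ramp filtering in the frequency domain (kernel `h(0) = 1/(4 d^2)`,
`h(k) = -1/(pi k d)^2` odd k, zero-padded to the next power of two;
optional Hann apodization), voxel-driven backprojection with bilinear
detector interpolation and distance weighting `sad^2/(sad - t)^2`. A
subset of `n` projections spanning the full circle is backprojected with
angular weight `2 pi / n` per view, so sparse phase bins reconstruct at
correct amplitude with the characteristic angular-undersampling streaks
(within one bin, views cluster every `omega*T` degrees of arc). Output is
`mu`; HU calibration against water is an explicit separate step. A 2D
parallel-beam FBP (view weight `pi/n`) exists for analytic cross-checks
and is validated against an independent textbook implementation within 1%
RMS. Short-scan redundancy weighting is unnecessary at a full 360 degrees.

## Metrics

* **Spatial resolution.** Line profiles are taken across each bar group
  perpendicular to the bars (five parallel lines over the central half of
  the bar length, three depths over the central half of the bar height,
  averaged), shifted by +1000 HU so the modulation denominator cannot
  vanish near air. Raw modulation is (mean per-cycle maximum − mean
  per-cycle minimum)/(sum), using interior cycles only — the outermost gap
  borders open background and dips deeper than a true gap — and is
  normalized by the nominal bar/background modulation so an unblurred
  pattern scores 1. Groups whose bar width falls below two in-plane voxels
  are excluded as unresolvable. A Gaussian `exp(-f^2/2 sigma^2)` is fitted
  by least squares; the maximal resolution is the 10% crossing,
  `f_max = sigma sqrt(2 ln 10) ≈ 2.146 sigma`. The profile-measurement
  route is validated against the closed-form square-wave response of a
  Gaussian PSF (the alternating odd-harmonic series).
* **CNR.** `|mean_signal − mean_background| / sd_background` per slice on
  the 1.5 cm low-contrast insert, averaged over the slice range with its
  standard error. Background is a concentric annulus outside the insert
  (defaults 0.95–1.45 cm radii). Under the Poisson noise model CNR scales
  as `sqrt(N)` across the protocol sweep.
* **Uniformity.** UI = max − min of the mean HU of a central ROI and four
  peripheral ROIs 5.0 cm away (1 cm diameter), per slice, averaged.
* **HU sensitivity.** Per sensitometry insert, mean ROI HU over the slice
  range minus the same measurement on a static-phantom baseline scan.
* **Excursion.** Per phase volume, the air insert position is the
  z-centroid of voxels below −500 HU inside a tracking box covering the
  full expected travel; excursion is max − min position, reported with the
  percent difference from 3.0 cm and, across protocols, the RMSE
  `sqrt(mean((E_i − 3.0)^2))`. The −500 HU threshold is the 50% air
  occupancy level, which is what makes the centroid track the bin-median
  displacement. Threshold and box are configurable.
* **sqrt-mAs normalization.** Any metric divided by the square root of the
  scan's total mAs, the benefit-per-noise-budget comparison.

A known inconsistency in the published excursion table is documented in
the test suite: applying the RMSE definition to the printed per-protocol
percent-difference rows yields 0.035 cm (4-phase) and 0.024 cm (10-phase),
the reverse of the RMSE column printed beside them (0.025 / 0.035). The
implementation follows the definition.

## Problem sizes

Defaults are desk-scale and configurable. The protocol sweep driver
reduces the frame rate by a `scale` factor (preserving the `N omega = F
theta` ratios; full-scale N, time and mAs are always reported alongside)
and reconstructs each metric on a module-specific grid: 96^3 voxels
(0.25/0.25/0.1 cm) over the sensitometry volume of interest for excursion,
160^2 x 10 slices for CNR/UI/HU, 240^2 for the bar module. The excursion
study runs at `scale = 1/6` (2.5 fps, 150–900 projections per protocol,
at least 15 projections per 10-phase bin at 6 deg/s) with photon noise off
and the detector rows narrowed to the band covering the tracked volume.
The phase lattice is coarser at a reduced frame rate (at 2.5 fps there are
12.5 frames per cycle, 25 distinct phases), which slightly quantizes the
per-bin displacement medians; measured percent differences stay within the
2% band.

Absolute scanner measurements (the published 5.93–3.82 lp/cm resolutions,
4.80–1.82 CNR values, dose rates) are properties of a physical imager and
are not reproduction targets; the dose-rate table is packaged as measured
constants, and resolution/CNR are validated as formulas, trends and
scaling laws.

## Limitations

The simulation omits scatter, beam hardening, bowtie fluence shaping,
detector lag and glare, focal-spot blur, and the half-fan offset-detector
geometry of wide-FOV thoracic protocols; HU accuracy effects that stem
from them are outside scope. Breathing is perfectly periodic — the sorter
handles period drift by construction (per-cycle anchors) but irregular
amplitude patterns, baseline drift and missed cycles are not exercised.
Dose is bookkeeping on measured rates, not radiation transport. Passing
tests therefore demonstrate the internal consistency of the acquisition /
sorting / reconstruction / measurement chain under idealized physics, not
the absolute image quality of any physical scanner.
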