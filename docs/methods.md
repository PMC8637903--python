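# Methods

`tuvi` reconstructs super-resolved maps of vessel phantoms from simulated
transcranial ultrasound acquisitions. This note records the models,
parameter choices, numerical decisions, and what the synthetic experiments
do and do not demonstrate.

## Acoustic model

The simulator is a linear far-field point-scatterer model. Each microbubble
returns a delayed, scaled copy of the transmit waveform on every receive
element; for steering angle θ and a scatterer at (x, z) the two-way delay to
element at x_e is

    τ = (z cos θ + x sin θ)/c + sqrt((x − x_e)² + z²)/c ,

with c = 1.54 mm/µs by default. Amplitudes carry spherical spreading 1/r
(1 mm reference), bulk attenuation at the 2 MHz center frequency
(0.5 dB/(cm·MHz) default) over the two-way path, an optional bulk
transcranial loss in dB, and optional per-channel receive-delay jitter as a
crude aberration stand-in. Echoes are inserted with linear-interpolation
(fractional-sample) placement; receiver noise is white Gaussian per RF
sample. Deliberately omitted: transducer impulse/element responses,
nonlinear bubble dynamics and harmonics, elevation focusing, tissue motion.
The model preserves what the downstream stages consume — timing geometry,
spreading/attenuation amplitude structure, and SNR — not waveform
fidelity.

Internally the package works in a self-consistent mm / µs / MHz system
(c = 1.54 mm/µs), which avoids unit conversions entirely; all interfaces
are in mm, s, and mm/s as documented.

The transmit waveform is a linear FM chirp, 1.3–2.7 MHz over 6 µs
(time-bandwidth product 8.4), Tukey(0.2)-tapered, unit peak. A single-cycle
2 MHz burst serves as the conventional short-pulse reference.

## Study conditions (generator defaults)

The default acquisition mirrors the compounded-chirp protocol: a
128-element, 0.3 mm-pitch linear array; five plane-wave transmits per frame
at −6°, −3°, 0°, +3°, +6°; 1500 Hz compounded frame rate; 600 frames;
20 MHz sampling. The receiver noise default (σ = 0.03 per RF sample against
a unit-amplitude bubble at 30 mm, i.e. raw per-channel echo SNR ≈ −5 dB)
places the experiments in the low-SNR transcranial regime that motivates
chirp compounding: the ~9 dB compression gain, ~15–21 dB of aperture gain
and ~7 dB of angle compounding recover bubbles to tens of σ above the
image noise floor while beamforming sidelobes stay below the detection
threshold.

Bubble populations are Poisson-seeded along the vessel centerlines
(concentration in bubbles/mm of vessel), with uniform radial offsets inside
the lumen and mildly lognormal scattering amplitudes (σ = 0.3). Flow is
plug by default (a single pump rate; each bubble rides one streamline), a
Poiseuille profile is available. Bubbles leaving a segment are recycled at
its entrance on a fresh streamline. The two density regimes map the
reported low/high contrast dilutions onto line densities giving ≈1 bubble
in the field at a time (low) versus tens (high); the elevation slice that
would link volumetric concentration to in-plane counts is never specified,
so the regimes are defined by their in-plane effect.

Static scatterers (frozen speckle) model tank-wall / tissue / skull
clutter and are on by default for generic pipeline runs. The tank and
pure-simulation experiments disable them: the reference experiments used an
absorber-lined tank and vessel-only simulations, and with no static scene
there is no clutter for the spatiotemporal filter to find (see below).

## Beamforming

Channel RF is pulse-compressed by correlation with the known chirp,
normalized so a unit echo compresses to a unit peak. The image pipeline
applies a Hamming-weighted (slightly mismatched) compression filter: at
time-bandwidth 8.4 the exact matched filter leaves −17 dB range sidelobes
spread over ±1.5 mm, which detection would mistake for bubbles; the taper
buys ~20 dB of sidelobe suppression for ~1 dB of SNR and a slightly wider
axial lobe (≈0.7 mm at −6 dB).

Delay-and-sum runs on the analytic signal (Hilbert transform) with linear
inter-sample interpolation, a receive f-number of 1.5 (f/1.0 for the
diameter study), Hann apodization, and coherent (complex mean)
compounding over angles. Apodization weights are normalized to unit noise
gain (Σw² = 1) rather than unit DC gain, which makes the additive-noise
floor flat across depth so one global detection threshold applies
everywhere. Default grid: λ/4 ≈ 0.19 mm.

An eigenspace-projected minimum-variance beamformer (subaperture
covariance averaging, eigenvalue threshold δ × λ_max, diagonal loading,
DAS fallback on degenerate covariances) is provided as an optional mode.
It is an approximation in the fast-eigenspace family, is much slower than
DAS, and is excluded from the quantitative acceptance experiments.

## Spatiotemporal clutter filtering

The complex stack is reshaped to a Casorati matrix (pixels × frames) and
leading singular components are removed. The automatic cutoff takes the
largest log₁₀ drop within the leading quarter of the singular spectrum —
the corner where the clutter plateau falls to the blood + noise continuum
— and warns and defaults to one component when no clear drop exists.

Two regime notes. First, at 1500 Hz a 30 mm/s bubble crosses a PSF in
~50–150 frames, so over short windows bubble signal is itself slowly
varying and sits just below the clutter plateau: cutting deeper than the
plateau destroys bubbles (this rules out noise-floor-multiple rules).
Second, on clutter-free scenes (absorber-lined tank, vessel-only
simulation) there is no plateau at all and any cut lands inside the bubble
subspace — even a rank-1 cut subtracts the temporal-mean trail and thereby
*adds* a stationary anti-trail ghost (≈ peak × dwell-fraction, easily
above threshold) wherever a bubble ever was, whose creeping notch seeds
slow spurious tracks. The tank/simulation experiments therefore run the
filter stage with the identity band (cut 0). Filtering runs before
envelope detection so phase is preserved.

## Localization

Detection takes regional maxima of the envelope above
median + 5σ_MAD (σ via 1.4826 × MAD). Five σ keeps the expected
false-alarm count near one per ~4·10⁴-pixel frame for a Rayleigh
background. The minimum peak separation and the refinement window scale
with the predicted PSF: lateral FWHM ≈ 1.2 λ f_eff with
f_eff = max(f#, z/aperture), axial FWHM ≈ 1.4 c/2B. Peaks dimmer than 15%
of a brighter peak inside that peak's cross-shaped sidelobe footprint
(±3 mm laterally at the same depth; ±1.8 mm axially at the same lateral
position) are rejected as beam-sidelobe / compression-shoulder ghosts —
the footprint is a cross, not a box, so dim bubbles on neighboring
streamlines survive.

Refinement is a background-subtracted intensity-weighted centroid over a
window that covers the full lateral mainlobe but only ~¾ of the axial
lobe (anisotropic window): laterally, anything smaller inherits the noise
wander of the argmax of a flat-topped blob; axially, anything larger
admits neighbors and compression shoulders into the depth estimate. A 2-D
Gaussian least-squares fit is available for precision studies on isolated
targets; it is biased on partially resolved pairs and is not the default.

With this chain, replicate localization of an isolated point target at
realistic SNR has a spread of ~5–20 µm — two orders below the ~1–3 mm
diffraction width, which is what the ~30-fold and larger resolution-gain
figures measure. Coherent interference between bubbles closer than about
two PSF widths biases positions by up to a few hundred µm; sparsity (below
~1 bubble per 2 PSF widths per vessel) is the operating regime, as in all
localization microscopy.

## Tracking

Detections from all frames are partitioned into tracks plus clutter.
A partition's log-posterior sums, per track: a birth prior (birth rate
spread uniformly over the field), per-detection log p_detect, per-gap
log(1 − p_detect), and constant-velocity Kalman innovation densities (the
x and z axes share one covariance recursion; position and velocity process
noise per frame; a broad initial velocity prior of half the speed gate).
Unassigned detections pay a uniform Poisson clutter density. Defaults:
p_detect 0.9, clutter rate 1/frame, max gap 2 frames, min track length 5,
process/measurement σ 0.05 mm, speed gate 100 mm/s.

A Metropolis–Hastings chain explores partition space with eight reversible
moves — birth/death (geometric-growth proposals with exact reverse
densities), extend/reduce, split/merge, tail switch, endpoint update —
each restricted to the speed-and-gap gate
(max_speed·Δf/framerate + 3σ_meas). Per-track likelihood caches make a
move cost proportional to the affected tracks only. The chain starts from
the greedy nearest-neighbor partition by default: at realistic detection
densities a cold chain would spend its whole budget rediscovering obvious
links, while the sampler's job is to repair the hard cases (crossings,
gaps, clutter). The maximum-a-posteriori partition visited is returned;
tracks shorter than min_track_length, and tracks whose end-to-end
displacement rate is below 5 mm/s (stationary residue, not flowing
bubbles), are dropped from the output.

Correctness is checked three ways: the posterior against closed forms; the
MAP against exhaustive enumeration of all valid partitions on ≤8-detection
instances (both cold and warm starts); and the long-run visit distribution
against the enumerated, normalized posterior by χ² on a flat-landscape
instance — the last is the sharp test that every move's proposal density
is right.

Velocities are central finite differences of position over time (actual
frame spacing across gaps) by default. Differentiation amplifies
localization noise by the frame rate (20 µm at 1500 Hz → ~21 mm/s per
axis), and speed magnitudes are biased upward by that noise, so pipeline
velocimetry uses a local linear regression over a configurable window
(7 frames generic; 31 for the straight-tube flow study, where the
constant-velocity assumption is exact).

## Reconstruction and metrics

Tracks are densified by linear interpolation at ≤ one 10 µm cell per step;
each sample increments its cell and deposits a linearly interpolated
speed; the velocity map is the per-cell mean. Samples can be rendered as
unit-mass Gaussians with σ equal to the run's own localization precision,
estimated as the robust RMS residual of local linear track fits
(uncertainty rendering; "auto" default in the pipeline).

MSE compares the density map (scaled by its maximum, or binarized) with
the designed binary vessel map over the full shared field — the designed
distribution is compared as a whole image; a bounding-box evaluation
region is available as a mode. Vessel diameters are full widths at half
maximum of cross-sectional profiles, averaged over a slab along the vessel
with sub-cell interpolation. On sparsely filled maps the pipeline takes
the profile of the occupancy (density > 0) rather than raw counts — raw
counts peak wherever two transits overlap, and half-maximum then discards
legitimately visited lumen; on densely filled maps the two coincide. A
0.05–0.08 mm profile smoothing bridges gaps between discrete streamlines;
smoothing a binary plateau does not move its half-maximum edges. Image
SNR is 20 log₁₀(peak signal ROI / RMS background ROI). The resolution
gain divides the conventional lateral FWHM by 2.355 × the replicate
localization spread.

## The diameter / flow-speed study

In a circulating-loop phantom each bubble rides one streamline, so a
single acquisition samples as many radial offsets as it has bubbles plus
pump turnover (offset flux = concentration × pump speed per tube).
Mapping a 0.7–1.0 mm cross-section at 10 µm therefore uses the
repeated-injection protocol: fifty 50-frame acquisitions, each with a
fresh sparse population (0.13 bubbles/mm), pooled into one map — roughly
80–90 distinct streamlines per tube. That count matters because the
measurable width is bounded by the span of the sampled offsets, whose
expectation for n uniform draws is D(n−1)/(n+1): tens of streamlines are
needed before the sampling deficit drops below the localization blur.
More, shorter injections beat fewer, longer ones at fixed total frames,
because each fresh population contributes its full standing count of new
streamlines. Sparsity matters twice over: simultaneous bubbles that share
a lateral PSF bias each other's positions, and axially unresolved
neighbors pull edge streamlines toward the lumen interior, shaving the
measured width — both scale with concentration, which is why the study
trades concentration for injections. For this study the centroid window
is further narrowed axially to half the compressed-pulse lobe.

## Scaled-down problem sizes

The package's evaluation experiments run at desk scale on one CPU core:
the density-regime reconstructions use 150 frames × 32 channels; the
depth-coverage study 150 frames × 32 channels with bulk plus 6 dB
skull-mimicking attenuation; the diameter/flow study 10 × 250 frames ×
128 channels over a 14 × 20 mm imaging window; SNR and resolution-gain
studies use single-bubble scenes with 8–50 noise replicates. These sizes
were chosen so a full evaluation completes in minutes while every stage
operates in its intended regime; the full 600-frame, 128-channel protocol
runs unchanged through the same code path (the streaming
simulate-and-beamform loop never materializes the raw RF volume).

## Known limitations

- The echo model is linear and frequency-flat per path; harmonic imaging
  and frequency-dependent attenuation are out of scope, so conclusions
  about contrast-specific imaging modes cannot be drawn from it.
- Skull aberration is reduced to bulk loss plus optional per-channel delay
  jitter; true phase-screen aberration degrades localization in ways these
  experiments do not probe.
- Plug flow plus streamline recycling means cross-sections fill by
  discrete lines; real dispersion fills lumens faster than this simulator
  does.
- Velocity maps are accurate for straight, steady flow at the tested
  rates; near the speed gate (large vessels) tracking saturates and
  speeds are qualitative, consistent with the method's reported limits.
- The eigenspace beamformer is a reference implementation for small grids,
  not an optimized production mode.
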