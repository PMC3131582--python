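# Methods

## System modeled

A microfluidic imaging flow cytometer: particles in a sample stream are
hydrodynamically focused to a narrow ribbon, imaged in bright field by a
high-speed camera while crossing a short "sorting segment" flanked by agarose
gel electrodes, recognized in real time from their blob features, and — when a
gate fires — deflected electrophoretically into an alternative outlet. The
package reproduces this computational chain at desk scale: a synthetic frame
generator with exact ground truth, the recognizer, the gating logic, the
sorting physics, and the throughput arithmetic.

Coordinates: x is lateral (the sorting axis, origin on the channel
centerline), y points downstream; images are (row, col) = (y, x). Lengths are
in μm, speeds in mm/s, times in s, voltages in V; volumes are carried in μm³
(= fL) with explicit converters.

## Chip and flow model

The default geometry is a sorting channel 50 μm wide × 25 μm high whose
imaged, electrode-facing segment is 100 μm long (sensing volume 125 pL), with
15 × 45 μm junction channels to the gel electrodes. Flow is ideal plug flow —
no velocity profile, no turbulence, no diffusion. A 1:10 sheath:sample width
ratio narrows the stream to 5 μm and, by flux conservation, speeds it up 10×.
The electrode gap defaults to the channel width; the field path length is not
a measured quantity, so the gap is a declared parameter, not an inference.

## Synthetic imaging

Frames are 8-bit, 500 × 220 px at 0.25 μm/px (plausible for a 40× objective
on a small high-speed sensor; the real optics are not numerically specified
anywhere, so these are package defaults). Particles are dark discs
(contrast −60 ADU) on a bright background (180 ADU) with additive Gaussian
camera noise (σ = 5 ADU per frame, and independently in the stored background
image), i.e. a detection SNR of 12. A projected disc is anti-aliased by 8×
supersampling — needed because a 2.5 μm particle is only 10 px across — then
convolved with an isotropic Gaussian PSF (σ = 0.4 μm).

Particle kinematics: arrivals are Poisson. The expected snapshot count in the
sensing segment equals density × sensing volume (λ = 0.125 at 10⁶/mL),
following the instrument's own occupancy accounting, which applies the sample
density to the full sensing cross-section; consequently the per-frame arrival
mean is density × W × H × (v/frame rate). Coincidences are *not* suppressed:
two particles may share a frame and even merge into one blob, which is
exactly the entanglement effect the Poisson model prices in. Lateral
positions are uniform within the focused stream; each particle advances
v/frame-rate per frame (at the default 20 mm/s and 200 frames/s, exactly one
segment length, so each particle is imaged once). The frame is 25 μm taller
than the segment so that in-segment particles never touch the border and get
clipped by the recognizer's edge policy.

Diameters are Normal(mean, CV·mean) with CV 2% — typical monodisperse
polystyrene; truncated at zero. The RNG is split into independent
arrival/particle and camera-noise streams, so a truth-only run (no rendering)
draws exactly the same particles as a rendered run with the same seed; a
fixed seed reproduces the stack bit for bit.

Not modeled: fluorescence, optical aberrations, shot noise, motion blur,
out-of-focus defocus, illumination gradients. Passing benchmarks therefore
show the pipeline's behaviour under clean bright-field statistics, not its
robustness to real-microscope artifacts.

## Recognition

Per frame: signed difference F − B (no clipping), binarize |F − B| ≥ θ with
θ = 25 ADU (5× the camera noise, ~42% of the default contrast: far from both
the noise floor and the contrast ceiling). The absolute value makes the same
pipeline work for dark and bright particles; whether the original instrument
thresholded the signed or absolute difference is unknown, so this is a
declared choice. Connected components use 8-connectivity by default; blobs
under 20 px (≈1/4 of the smallest benchmark particle, large enough to kill
noise specks) are dropped, and blobs touching the frame border are discarded
because their features are truncation-biased (both configurable).

Features: mean |difference| over the region; pixel count and μm² area; axes
of the equivalent ellipse from the second central moments of the pixel
coordinates (4√eigenvalue); circularity 4πA/P² clipped into (0, 1]. The
perimeter is an 8-connected Moore boundary trace whose steps are weighted
0.948 (axial) / 1.340 (diagonal) — the standard bias-corrected chain-length
estimator; raw (1, √2) weights overestimate smooth contours by ~5% and would
push a digital disc's circularity down to ≈0.89 at some radii, while the
corrected weights keep it ≥0.99 for radii 5–20 px. A single-pixel region
degenerates to axes = one pixel pitch and circularity 1.

## Gating and the size benchmark

Gate rules are interval predicates over the feature vector with all/any
combination; rule order is priority and the first match wins (the conflict
resolution is a package choice). No match → no voltage, default outlet.

The two-population benchmark gates on area only. The area threshold is fitted
by exhaustive scan over all candidate split points (midpoints of consecutive
distinct pooled values plus sentinels beyond the extremes), minimizing total
misclassification; ties break toward the midpoint of the two sample means.
The benchmark protocol: simulate an equal mix at 10⁶/mL until ≥2000 particles
(at 20 mm/s — the instrument's images were recorded between 1 and 200 mm/s
depending on the experiment; the package default of one segment length per
frame is used), detect every frame, match detections to ground truth by
nearest centroid (a merged blob may serve several coincident particles — it
is the measured event for each of them), split particles 50/50 by a seeded
permutation, fit on the calibration half, score the held-out half. An
undetected particle counts as misclassified. Errors are reported per particle.

With the default optics the projected areas (4.9 vs 7.1 μm² for 2.5/3.0 μm;
19.6 vs 78.5 μm² for 5/10 μm) are separated by far more than the 4% area CV
plus measurement noise, so the residual error is dominated by Poisson
coincidences that merge two particles into one blob — a fraction bounded by
the 0.8% entanglement probability at this density.

## Sorting model

Deflection Δx = μ·(V/gap)·(L_eff/v), sign = charge sign × field sign; the
physics carries no equation in the source description, so this drift model is
declared. L_eff is the sorting length minus the transit distance consumed by
the decision latency (default 1 frame — a decision is available only after
the triggering frame is processed), capped by the pulse duration if finite.
This latency explains why event-triggered sorting must collapse at high flow
speed: above one segment length per frame the field arrives after the
particle has left.

Routing: two-way chips keep the particle on the same-side outlet unless its
final lateral position reaches the branch line (half the focused stream width
+ 0.5 μm margin = 3 μm by default; geometry-derived). A particle exactly on
the branch line crosses. Three-way chips use the same constant as a branch
half-width around the center outlet.

The characterization sweeps (efficiency vs voltage, vs flow rate) use
continuous DC (zero latency), matching how that dependence is measured on
hardware. Stochasticity comes from the uniform lateral position within the
stream and a 5% mobility CV; the same particle draws are reused at every
sweep setting (common random numbers), so the monotone trends are exact per
run rather than blurred by resampling noise. The default mobility,
1.11 × 10⁴ μm²/(V·s) ≈ 1.1 × 10⁻⁴ cm²/(V·s) (physically typical for
polystyrene), is a **calibration anchor**: it is chosen so the default chip
sorts ~90% at 45 V and 200 mm/s, because no mobility, field strength, or gap
value is available to predict that operating point from first principles.
The voltage/speed *trends* are model properties; the 90% *value* is not a
prediction.

## Throughput model

Pure arithmetic on the constants, kept exact and rounded only at reporting:
2.5 nL/s, 20 mm/s, 8 × 10⁶ /mL, 5 μL → 33.3 min (38.3 with the 5 min setup).
"Entanglement" is interpreted as the unconditional P(N ≥ 2) per sensing
volume, 1 − e^{−λ}(1+λ) = 0.72% at λ = 0.125 — consistent with the stated
<0.8% bound, which the conditional form P(N≥2 | N≥1) ≈ 5.6% is not. The
analytic value is cross-checked against the Monte-Carlo occupancy of the
frame simulator in the test suite.

## Problem sizes and numerical choices

Test and acceptance runs use 10⁴ frames for occupancy statistics and 2000
particles per size benchmark (≈16,000 rendered frames each at λ = 0.125) —
sizes at which the binomial standard errors are several times smaller than
the margins being checked. Threshold fitting is O(n log n); all randomness
flows from explicit integer seeds through `numpy.random.Generator` (seeds in
configs are mandatory). Degenerate inputs are defined rather than left to
chance: zero-density streams yield empty truth, single-pixel blobs get
circularity 1, identical-mean threshold fits warn and return the midpoint,
neutral particles never deflect, and a boundary particle exactly on the
branch line crosses.

## Known limitations

Plug flow (no parabolic profile, no lift forces, no particle–wall or
particle–particle hydrodynamics); no dielectrophoresis, electro-osmosis, or
Joule heating; the optics model omits every aberration a real microscope has;
the sorting calibration anchor substitutes for unavailable electrokinetic
parameters, so absolute efficiencies transfer to real chips only after
re-calibration. The fluorescein/small-molecule separation the hardware also
demonstrates is representable (a charged, near-zero-diameter tracer) but not
a supported, tested surface.
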