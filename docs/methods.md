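# Methods

`cbctiq` simulates a megavoltage cone-beam CT (MV-CBCT) image-quality study
at desk scale: phantom scans under a family of acquisition protocols that
vary the gantry arc (360° full scan vs 200° short scan), the number of
projections (100–600), and the total exposure (13.5 vs 7.2 monitor units,
MU), followed by filtered-backprojection reconstruction and the four
standard phantom metrics — uniformity, noise, contrast-to-noise ratio
(CNR), and spatial resolution (f50 from an edge-derived MTF).

This note records the model, its assumptions, the parameters that matter,
and what the synthetic study can and cannot say about a physical scanner.

## Phantoms and materials

Three voxelized phantoms emulate the physical quality-assurance objects:

* **water cylinder**, 220 mm diameter × 170 mm height, for uniformity and
  noise;
* the **same cylinder half filled**, giving a sharp planar water/air
  interface (perpendicular to the vertical in-slice axis, through the
  isocentre) for resolution;
* a **pelvis-shaped slab** (elliptical outline, default semi-axes
  170 × 120 mm, 5 cm thick axially) carrying 3 cm diameter cylindrical
  inserts on a 12 cm diameter circle: muscle (relative electron density
  rED = 1.043), trabecular bone (1.117), dense bone (1.513), and lung at
  exhale (0.459).

At megavoltage energies attenuation is Compton dominated, so linear
attenuation is taken proportional to electron density:
`mu = rED * mu_water`, with `mu_water = 5.0e-3 mm^-1` as a configurable
reference (the physical value depends on the beam spectrum, which is not
modelled). The pelvis outline is a simplification — only the slab thickness
of the physical phantom is documented — and the insert angular positions
are a convention (equally spaced from 0°); both are configurable.

Voxel membership is centre-in-region on half-open extents, coordinates sit
at voxel centres with the grid centred on the isocentre, and the generators
contain no randomness, so regeneration is bit-identical.

## Acquisition model

The default simulation is a per-slice **fan beam** (one detector row);
this keeps the full nine-protocol sweep tractable on one CPU and is
faithful to the analysis, which is slice-based throughout. Geometry:
source–axis distance 1000 mm; source–detector distance 1450 mm (not
published for the modelled system; configurable); flat detector. The
physical panel is 1024 pixels at 0.4 mm pitch with 16-bit depth; the
desk-scale geometry uses 512 pixels at 1.0 mm pitch so that its isocentre
field of view (±174 mm) covers the default pelvis phantom without lateral
truncation. Truncation is detected from the phantom's support radius and
raises by default (`allow_truncation=True` downgrades it to a warning).

Gantry angles follow IEC 61217; the single conversion used everywhere is
`math_angle = 90° + gantry_angle`, placing gantry 0° above the isocentre.
Protocol angle lists start at the arc start with spacing
`arc_length / n_projections` (a full circle therefore does not duplicate
its endpoint). Short-scan arcs that would carry the gantry through the
180° line only warn — the simulator has no couch to collide with.

**Forward projection** is a sampled-ray line integral: for every
source→pixel ray, the attenuation grid is sampled at half-voxel steps with
bilinear interpolation and summed. Against the analytic chord length
through the cylinder it agrees to better than 1% away from grazing
incidence (where pixelisation necessarily dominates any ray rule).

**Exposure noise.** Expected counts per detector pixel are

    N = fluence_per_mu * (total_mu / n_projections) * exp(-line integral)

and realised counts are Poisson with that mean, optionally plus zero-mean
Gaussian electronic noise (off by default), clipped to the 16-bit ceiling
with a saturation warning. `fluence_per_mu` is the free detector-gain
constant; the default 4.0e5 photons/pixel/MU is calibrated so that the
13.5 MU protocols reconstruct with roughly 2% noise on 4.8 mm display
slabs while the hottest protocol (0.135 MU/projection) stays below
saturation (peak expected counts 5.4e4 < 65535).

**Detector point-spread function.** An optional Gaussian PSF acts on the
expected fluence along the detector row (off by default in the acquisition
module). The study driver enables it at sigma = 3.2 mm at the detector
plane (~3 detector pixels, ~2.2 mm at isocentre magnification). This
models the broad optical spread (scintillator glare) of megavoltage flat
panels, which is what makes MV-CBCT resolution panel-limited rather than
view-sampling-limited; without it the desk-scale chain shows
angular-aliasing ringing at 2°/projection that sharpens the apparent edge
by ~25% — an artifact a physical panel never resolves. A consequence of
the glare worth knowing: the wide 2.5 cm signal ROI inside the 3 cm lung
insert absorbs blurred boundary pixels, so the measured lung CNR drops
below dense bone (whose tight 0.8 cm ROI is immune) even though lung has
the larger electron-density contrast. The CNR-vs-contrast monotonicity
property of the metric chain is therefore tested with the PSF off.

## Reconstruction

Filtered backprojection for the equidistant fan geometry: log transform
`ln(N0/counts)` (counts floored at 0.5 to avoid infinities), cosine
pre-weighting, short-scan redundancy weighting, row-wise ramp filtering,
and distance-weighted backprojection with linear interpolation. Pixels
outside the grid's inscribed circle are zeroed and excluded from metrics.

* **Redundancy weights.** Full scans measure every ray twice and use
  uniform weights of 1/2. Short scans use the sin²-tapered short-scan
  window with half over-scan angle `(arc − 180°)/2`; complementary rays
  sum to unit weight. Two implementation details matter and are covered by
  tests: the weights multiply the data *before* filtering (they vary
  strongly across the detector inside the taper wedges), and the fan-angle
  sign must match the arc direction (for increasing-gantry arcs the
  complement of (β, γ) sits at β + 180° − 2γ in this geometry). With both
  in place, a noiseless 200° short scan agrees with the 360° full scan to
  an RMSE below 1% of `mu_water` inside the water ROI.
* **Filter.** The vendor "smoothing" kernel is unpublished; the substitute
  is a band-limited ramp (exact discrete kernel, assembled in frequency
  space from its spatial form) times an apodizing window — Hann at 0.8 of
  Nyquist by default, with ramp/Hann/Hamming/cosine and the cutoff
  configurable.
* **Grid.** 512×512 pixels over the 27.4 cm cross-plane field at full
  scale; the desk-scale default is 256×256 over the same field
  (1.07 mm pixels), 1 mm slices displayed at 4.8 mm.
* **Display binning.** Thin slices are averaged in groups of
  `round(display/slice) = 5` (the published ratio 4.8 is not an integer;
  nearest-integer grouping keeps the average exact), dropping a trailing
  partial group. Binning is strictly post-reconstruction.

## Desk-scale study design

A single transverse slice per phantom is simulated. Each analysis slice is
a **display slab**: the average of 5 independent Poisson realisations of
the projections, reconstructed once — by linearity of FBP this is
identical to reconstructing five 1 mm slices with independent axial noise
and bin-averaging them, at one fifth of the cost. The "six consecutive
slices" of the physical protocol become six such independent slabs; their
mean and sample standard deviation form the per-seed metric, and
everything is repeated over `n_seeds` independent repetitions (default 10;
the acceptance script uses 3 and the bundled figures state the counts
used). Per-protocol seeds derive from SHA-256 hashes of
(base_seed, protocol, phantom, indices), so extending the sweep never
shifts existing results; base_seed 20120105 by default.

## Metrics

With `m()` the ROI mean and `s()` the sample (n−1) standard deviation:

* uniformity = `[1 − |m(centre) − m(periphery)| / (m(water) − m(air))] × 100`
* noise = `s(water) / (m(water) − m(air)) × 100`
* CNR = `|m(insert) − m(background)| / (½ [s(insert) + s(background)])`

ROI geometry on the water phantom: 2.5 cm central circle, 2 cm thick
peripheral ring kept 5 mm clear of the phantom wall (to exclude edge
blur), 19 cm water circle, 2 cm air ring outside the phantom with 5 mm
clearance. On the pelvis: a 2.5 cm signal circle per insert (0.8 cm for
dense bone, matching the smaller physical insert), with a 1 cm background
ring starting at the 3 cm insert boundary. ROIs are placed from
ground-truth phantom geometry rather than segmentation, and an ROI below
25 pixels is refused. A non-positive water−air contrast raises (it signals
a broken reconstruction; the formulas use the plain difference, not an
absolute value).

## Resolution chain

The edge spread function (ESF) is sampled along lines perpendicular to the
water/air interface, averaged over 64 parallel lines (a single-line
profile is far too noisy; averaging is consistent with the six-slice
averaging used everywhere else), oriented air-first. The line spread
function is the first derivative (central differences). A zero-baseline
Gaussian `A exp(−(x−c)²/2σ²)` is least-squares fitted, initialised from
moments, with failures (no detectable peak, σ at the span bound) raised as
errors. The MTF is evaluated as the analytic Fourier transform of the fit,
`MTF(f) = exp(−2π²σ²f²)`, normalised to 1 at f = 0 — a numerical-FFT path
is kept as a cross-check and agrees to 0.5% — and f50 solves
`MTF(f50) = ½` by linear interpolation on the frequency grid
(closed form `sqrt(ln 2 / 2)/(π σ)` for a Gaussian). Frequencies are in
mm⁻¹ throughout; reports may quote lp/cm (×10).

## Logistics

MU/projection = total MU / n; sampling rate = arc / n; acquisition time =
arc / gantry speed (the speed is an *input* — on the real machine it is
set by the control system around detector readout and is not derivable
from the published readout period). Storage = n × 1012² active pixels ×
2 bytes, in MB of 10⁶ bytes truncated to an integer — the one convention
that reproduces the published 204 MB (100 projections) and 409 MB (200);
the published 738 MB for 360 projections appears rounded up (this
arithmetic gives 737). The simulator's detector uses the full 1024-pixel
row; storage uses the 1012 active pixels as published.

## What the synthetic study shows — and does not

The simulated sweep reproduces the study's qualitative structure:
uniformity and f50 flat across protocols; noise drifting mildly downward
with more projections at fixed exposure; noise and CNR scaling with the
square root of dose (noise ratio ≈ √(13.5/7.2) ≈ 1.37 between the 7.2 and
13.5 MU full scans); CNR ordered by electron-density contrast (up to the
glare/ROI interaction noted above).

It does not model scatter, beam hardening, the polyenergetic spectrum,
detector lag/ghosting, extrafocal radiation, the vendor's actual
reconstruction kernel, or 3D cone-angle effects (the fan-beam slice is the
default; stacks are supported by extrusion but carry no cone-angle
weighting). Absolute metric values therefore are not comparable to scanner
measurements — a physical 100-projection scan measured ~1.96% noise where
this chain's absolute number depends on the free gain constant — and only
the *relative* behaviour across protocols is meaningful, which is also how
the original measurements were interpreted.

## Numerical conventions

Sample (n−1) standard deviations everywhere. Zero counts floored at 0.5
before the log transform. Angles equally spaced and validated as such.
Short-scan fan angles clamped infinitesimally inside the over-scan wedge.
Single-slice aggregation reports SD 0 with a warning. All randomness flows
from explicit seeds (kept below 2³¹); same seed, same bytes out.

One more interaction worth recording: CNR dose scaling. At matched
MU/projection (13.5 MU/600 projections vs 7.2 MU/360) the CNR of the
low-contrast inserts scales as √(13.5/7.2) ≈ 1.37, as the Poisson model
predicts. The high-contrast inserts scale more weakly (≈1.1–1.2): their
signal and background ROIs straddle strong attenuation gradients, so their
standard deviations carry a deterministic, dose-independent component
(filter ringing at the insert boundary, plus panel glare when enabled)
that floors the CNR denominator. The same saturation is visible in
physical measurements, which report the low-exposure CNR "approximately
25%" lower rather than the full 37% square-root gap.
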