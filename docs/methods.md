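# Methods

## Acquisition model

The scanner holds four identical vertical 128-element linear arrays on a
ring of diameter *D* = 180 mm, at rest angles 0°, 90°, 180° and 270°. A
rotary table (precision 0.05°) turns the assembly through 90°, so the four
arrays jointly tile the full circle; per-array coverage is half-open,
`[base, base + 90°)`, so an angle shared by adjacent arrays at a sector
boundary is acquired exactly once and a full-circle plan holds exactly
360°/Δθ angles (7200 at the 0.05° precision limit). Acquisition is
monostatic: the N-th element transmits toward the rotation axis and
receives its own echo; there is no transmit focusing and no cross-element
beamforming. Angles are degrees counter-clockwise from +x; element indices
are 1-based; z runs downward from element 1 at z = 0 in steps of the 1 mm
element pitch (the hardware convention for array orientation is not
dictated by the physics, so this is declared as a convention).

## Pulse-echo simulator

The simulator is ray-based and first-order: a straight ray from the
element toward the axis crosses each reflector surface at analytically
computed entry/exit points, and every crossing returns one echo at the
round-trip delay t = 2d/c. No refraction, multiple scattering,
diffraction, element directivity or speckle texture is modelled — the
reconstruction itself assumes straight rays at constant c, so simulator
and algorithm share one geometry model, which is exactly what makes the
closed-form oracles in the tests possible.

Echo amplitude for a crossing at one-way distance d, incidence angle γ
(against the inward surface normal) and surface reflectivity R:

    A = A₀ · R · cos²γ · 10^(−α_total/20),   A = 0 for γ > 60°

The cos² factor with a hard 60° cutoff reproduces the qualitative
observation that flat faces tilted away from the beam go dark while curved
surfaces stay visible; it is a surrogate, not a measured directivity.
Attenuation is frequency-linear: α_total = α_medium · (round-trip path in
cm) · (f₀ in MHz), with the water coefficient (default 0 dB/(cm·MHz) —
negligible at 3.5 MHz over 9 cm) applied up to the first interface and the
tissue coefficient (default 0.65, midpoint of the 0.6–0.7 dB/(cm·MHz)
range quoted for soft tissue) beyond it. Rays tangent to a surface within
numerical tolerance produce no crossing.

The transmit pulse is a Gaussian-modulated sinusoid at f₀ = 3.5 MHz with a
0.6 fractional bandwidth at −6 dB (`scipy.signal.gausspulse`); the
hardware pulse shape is not specified beyond its centre frequency, so this
standard impulse-response surrogate is used. A-scans are sampled at
12 MHz; the default 2048 samples cover 131 mm of one-way range, comfortably
past the 90 mm half depth (minimum 1403 samples, enforced). Additive white
Gaussian noise models the acquisition chain, default σ = 1% of the pulse
amplitude. Every A-scan's noise seed is derived from the master seed and
the acquisition counter through `numpy.random.SeedSequence`, so any single
A-scan — and therefore the whole sinogram — is bit-reproducible.

Reflectivities are not physically calibrated (no impedance model): iron
fixtures use 0.95, the breast body 0.3 and its mass 0.8. The breast
phantom is an ellipsoid body (semi-axes w/2, w/2, h) containing a centred
sphere; its centre sits at z = 63 mm so the slice plane of element 64 is
exactly equatorial.

## Reconstruction

The six stages run strictly in acquisition order; a regression test pins
the order by recomposing the pipeline stage by stage.

* **Bandpass**: order-4 Butterworth, 1.75–5.25 MHz (±50% around f₀),
  applied forward–backward (`sosfiltfilt`) so echo delays are not
  phase-shifted. The band edges are a design choice — wide enough to pass
  the 0.6-fractional-bandwidth pulse, narrow enough to reject out-of-band
  noise — and are exposed in the configuration.
* **Envelope**: magnitude of the analytic signal (Hilbert transform) per
  column.
* **Log compression**: y = clip((20·log₁₀(x/x_max) + DR)/DR, 0, 1) with
  DR = 50 dB by default; an all-zero matrix maps to all zeros. There is
  deliberately no time-gain compensation stage: depth contrast is handled
  entirely by the compression.
* **Half-depth truncation**: samples whose one-way range exceeds D/2 are
  zeroed (last kept index ceil(2·(D/2)·fs/c) = 1403 at defaults), plus a
  2 µs dead zone after t = 0 that suppresses the transmit-breakthrough
  artifact. Truncation loses nothing for objects inside the ring: the
  opposing element sees the far wall as its own near wall, and with the
  maximum combine rule the truncated and untruncated reconstructions of a
  centred object agree pixelwise (verified as a property test).
* **Scan conversion**: the sample at range r along the beam at angle θ is
  deposited at T(θ) + r·b(θ) (rotation axis at the image centre; a sample
  at r = D/2 lands exactly on the axis), rounded to the nearest pixel of a
  0.5 mm grid over a 180 mm extent. Colliding deposits combine by
  **maximum** (preserves thin specular interfaces; mean is available).
  The coverage mask records pixels that received a nonzero deposit.
* **Morphology**: uncovered pixels are filled by bicubic (Clough–Tocher)
  interpolation of the covered ones; interpolation is restricted to the
  convex hull of the coverage, so nothing leaks outside the scanned ring.
  The subsequent "inflation" is grayscale dilation with a disk, default
  radius 2 px (1 mm, the element-pitch scale); the radius is recorded on
  the slice for the measurement stage. The fill operates on the Cartesian
  image, not the polar matrix — filling in the domain where the gaps
  actually are (between beams at large radius).

Order caveat: log compression precedes scan conversion, so the per-matrix
normalisation x_max is computed in the polar domain; the pipeline makes no
claim that stages commute, and the stage order is part of the contract.

## Measurement

**Ranging** picks the global envelope maximum after the dead zone
(`first_crossing` picker available for layered targets) and converts with
s = t·c/2. A trace that is identically zero past the dead zone yields a
"no echo" result, not an exception. Opposing-pair sizing is
D − d₁ − d₂ and rejects d₁ + d₂ > D as inconsistent.

**Image calipers.** A solid object images as its specular outline (a thin
bright ring), so sizing conventions matter more than usual:

* Thresholding is defined in *echo amplitude*: on log-compressed pixels an
  amplitude ratio ρ is an offset of 20·log₁₀(ρ)/DR pixel units below the
  reference, so the default 0.5 threshold is the conventional −6 dB
  caliper. A flat 0.5 cut on compressed pixels would sit −25 dB down the
  echo skirt and bias every size upward.
* The recorded inflation is compensated: thresholding commutes with flat
  grayscale dilation, so eroding the binary mask with the same disk
  restores the pre-inflation support (a morphological closing of the
  half-amplitude outline). Without this, every diameter would inherit a
  +2·(dilation radius) bias.
* The selected component is hole-filled before sizing (the outline of a
  solid object encloses its interior); the reported size is the
  equivalent-circle diameter 2·√(area/π), with minimum and maximum chords
  through the centroid reported alongside — the minimum chord is the
  face-to-face extent of a square and is the right reading for edge
  lengths.
* Component selection is `largest` (default) or `innermost`. On compressed
  slices the innermost path measures a centred inclusion hierarchically,
  the way a reader calipers a lesion inside an organ: find the enclosing
  boundary at −6 dB of the global peak, search the central half of its
  radius, and cut at half the *display contrast* between that region's
  background (median) and its peak. The inclusion is deeper and more
  attenuated than the outer wall, and the maximum-combine scan conversion
  builds an extreme-value noise floor where all beams converge near the
  axis, so a single global threshold either misses the inclusion or merges
  it with the floor. The detected outline arrives as dots (one per beam);
  isolated single-pixel speckle is discarded and the dots are completed by
  their convex hull, which presumes a convex inclusion.

Relative error is 100·|measured − nominal|/nominal; all sizes are mm
internally, cm only at display level.

## Volume assembly

Slices with consistent shape and pixel size and strictly increasing
element indices stack into a volume with one z-plane per element at
z = (element − 1) · pitch; 128 slices at the 1 mm pitch span 127 mm.
Export: multi-page TIFF, NIfTI with voxel sizes in the header, and an
HDF5 mirror.

## Problem sizes in the test suite

The canonical sizing checks run the full protocol (2° interval, 180
angles, one element, 0.5 mm pixels). Structural property tests use
reduced settings chosen for desk-scale iteration — 8 to 36 angles and 1–2 mm
pixels — because the properties they check (stage order, determinism,
geometric fidelity, coverage monotonicity, half-depth invariance) are
scale-free. The all-element volume check uses a 10° interval and 2 mm
pixels: it verifies plane count and spacing, not image quality.

## What passing tests do and do not show

The simulator emulates the geometry, timing, attenuation and
incidence-angle physics of the ring scanner, with white noise for the
electronics. It does not emulate speckle from sub-resolution scatterers,
refraction at sound-speed boundaries, element directivity/diffraction, or
transmit focusing, and reflectivities are arbitrary rather than derived
from impedance contrasts. Passing sizing tests therefore demonstrate that
the reconstruction and measurement chain is geometrically and
radiometrically self-consistent under the stated physical model — not
that a physical scanner will reach the same accuracy on real tissue.

## Known limitations

* First-order echoes only; a strongly reflective interface in front of a
  target does not shadow it (no transmission loss at interfaces).
* The innermost caliper assumes one convex, roughly centred inclusion.
* Scan conversion deposits by nearest-pixel rounding; there is no
  sub-pixel splatting, so sizes carry up to half a pixel of quantisation.
* The equivalent-diameter caliper reads the outer half-amplitude edge and
  therefore overestimates object size by roughly the range-envelope width
  plus pixelisation (a few percent at 20 mm, matching the positive bias of
  manual readings on B-mode displays).
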