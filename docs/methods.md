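# Methods

`phasemct` implements a complete analysis chain for modulation-based (MBI)
and propagation-based (PBI) X-ray phase-contrast micro-tomography of weakly
absorbing specimens, together with a wave-optics virtual beamline that
generates fully characterised synthetic scans so every stage can be tested
quantitatively without experimental data.

## Physical model

A monochromatic plane wave (default 20 keV, wavelength 0.62 Å) traverses, in
order, a wavefront marker, the specimen and a free-space gap to the
detector.  Both marker and specimen are treated in the thin-object
projection approximation: an object with complex refractive index
`n = 1 − δ + iβ` multiplies the field by
`exp(−k β t) · exp(−i k δ t)` with `t` its projected thickness and
`k = 2π/λ`.  Free-space propagation uses the paraxial angular-spectrum
transfer function `H(f) = exp(−iπ λ z |f|²)`, which is unitary (total
intensity conserved to FFT round-off) and is validated against the Talbot
self-imaging of a weak sinusoidal grating: the modulation of a grating of
period `p` peaks at `z = p²/(2λ)` with amplitude `2φ`, both reproduced
exactly by the propagator.

The geometry is parallel-beam (source 85 m upstream, magnification ≈ 1):
modulator → 115 mm → sample → 175 mm (MBI) or 93 mm (PBI) → detector, with
an effective pixel of 1.28 µm in the sample plane.  The printed setup
distance for MBI is interpreted as sample-to-detector; the
displacement-to-angle conversion distance `z_eff` is nonetheless an explicit
knob because the proportionality distance of a given setup can also be read
as modulator-to-detector.

### Wavefront markers

* **Hexagonal phase grating (TAI)** — circles of etched silicon on a
  hexagonal lattice (period 7 µm, duty cycle 1/3, etch depth 17 µm).  At
  20 keV the etch produces a phase step of `k δ_Si t = 2.077 rad ≈ 2π/3`,
  the canonical design for high-visibility self-images.  The etched-area
  fraction of the generated map matches the duty cycle to ±0.02
  (supersampled rasterisation).
* **Sandpaper diffuser** — six layers of randomly placed spherical grains
  whose lateral diameters are log-normal with mean 5.8 µm (the shape
  parameter σ = 0.35 is a modelling choice; only the mean is a physical
  datum).  Layers are summed into one projected-thickness map; the
  layer-to-layer gap is negligible at these propagation distances.

Modulator stepping uses a tilted grid that tiles one lattice unit cell (16
steps, the full-design count) for the grating and a golden-angle spiral (20
steps) for the diffuser.

### Detector

The point-spread function has two components: a Gaussian core of FWHM
1.67 px (the measured 2.14 µm system resolution) and a broad halo
(fraction 0.79, σ = 25 px) standing in for scintillator veiling glare and
optical cross-talk.  The halo fraction is calibrated so the simulated
reference visibility of the grating pattern matches the ~15% measured on
the real system; an ideal single-Gaussian detector would show ~70%
visibility and make photon noise unrealistically benign relative to
systematic errors.  With this calibration the simulated diffuser visibility
comes out near 14% rather than the 22.5% measured — interference
enhancement of speckle contrast by grain micro-structure is not captured at
this sampling — so conclusions that hinge on the *absolute* diffuser
visibility should not be drawn from the simulator; pattern sharpness
(autocorrelation width), which governs tracking sensitivity, is reproduced
with the correct ordering (grating ~2.2 px finer than diffuser ~3.1 px).
Photon noise is Poisson at a configurable fluence plus a flat dark current;
each scan includes dark frames and per-step reference frames.  The
experiment-level default photon budget (250 photons/pixel) is the second
calibration to a printed system measurement: it places the simulated
angular sensitivity in the few-hundred-nanoradian regime of the real
beamline (simulated 304/433 nrad for grating/diffuser against measured
means of 318/399 nrad), absorbing noise sources the wave-optics model does
not represent — system vibrations and beam instabilities — into the photon
budget.  In this regime, as on the real system, volume-domain noise is
photon-dominated and the finer grating pattern delivers the better phase
sensitivity; with an uncalibrated bright, halo-free detector the retrieval
systematics of the miniaturised geometry dominate instead and that ordering
is not reproduced.

### Phantom

A paraffin cylinder (radius 0.34 of the field of view, matching the
specimen-to-FOV ratio of a ~4.5 mm block in a ~6.5 mm field) containing:
one thick "stem villus" (tissue cylinder, radius 0.16 of the volume, with a
wax-filled lumen) providing the extended homogeneous regions that ROI
statistics need; recursive branching tubular villi with lumina; and sparse
~6 µm spheres mimicking single blood cells.  Materials carry tabulated
optical constants at the beam energy (δ from electron density via
`r0 λ² n_e / 2π`; β from mass attenuation coefficients anchored at 20 keV).
The wax-block boundary is tapered over 3 voxels: at full experimental scale
the rim region where pattern tracking fails spans ~0.2% of the specimen
radius, and a hard voxel edge at desk scale would inflate that fraction a
hundred-fold, so the taper keeps the boundary phase gradient in the
trackable regime that the real geometry occupies.  Ground-truth δ/β volumes
and per-angle phase maps are retained for every simulated scan.

## Retrieval chain

**Preprocessing.**  Dark subtraction, then division by the beam profile
(the 50 px boxcar low-pass of the mean reference), which flattens the
illumination while preserving the modulation that the matcher tracks.
Outlier pixels deviating more than 8 robust standard deviations from their
3×3 median (with the robust scale floored at 1% of the image magnitude so
smooth noise-free structure is never flagged) are replaced by the median of
their 8 neighbours; the repair is idempotent.  Modulator drift is
estimated, when enabled, by sub-pixel cross-correlation of each frame
against its stored reference and compensated by resampling the reference.

**Pattern matching.**  For every pixel, the stack of sample frames is
compared inside a (2h+1)² window (default 3×3) and across modulator steps
against `T · [Ī(r−u) + D · (I_m(r−u) − Ī(r−u))]`, where `Ī` is the
step-mean reference, `T` the transmission, `u` the pattern displacement and
`D` the dark-field factor.  Because the step-mean of `I_m − Ī` vanishes,
the least-squares optima of `T` and `T·D` decouple and are closed-form per
candidate shift.  The integer minimiser over the search range is found
exhaustively (verified per-pixel against brute force); sub-pixel refinement
then performs one Gauss–Newton step that linearises the shifted reference
using spectral (FFT) derivatives.  Two numerical choices matter here and
were fixed after measurement on synthetic stacks: candidate evaluation at
fractional shifts uses Fourier translation rather than bilinear
interpolation (bilinear attenuates the modulation depending on the
fractional part and biases the minimum toward integer shifts by up to
~0.3 px), and the Gauss–Newton step uses spectral rather than
finite-difference derivatives (central differences under-estimate gradients
of band-limited patterns by ~25%, which propagates directly into the
displacement scale).  With both choices the displacement error on injected
sub-pixel shifts is ~0.014 px RMS noise-free and the amplitude response is
flat to ~1% for |u| ≤ 0.5 px.  Windows are evaluated on the periodic grid;
a margin of `search_radius + window_half` pixels at the border wraps and is
masked downstream.  Where the windowed reference variance vanishes the
dark-field is undefined and is set to 1 (counted and reported).

**Displacement to phase.**  `α_i = u_i · pixel / z_eff` (small-angle
refraction), `∂φ/∂i = k α_i`.  A first-order 2D polynomial fitted on
sample-free background is subtracted from each gradient channel; the
channels are integrated by the Fourier (Frankot–Chellappa) least-squares
projection with mirror extension (with the sign flips that keep the
extension the gradient of an even field); a second-order polynomial fitted
on the same background removes residual low frequencies.  The background
mask defaults to the left/right frame margins only: the specimen extends
through the full detector height, so the top/bottom margins are *not*
sample-free, and including them corrupts the plane fit badly enough to
destroy the low-frequency phase.  The DC term of the phase is
unrecoverable from gradients and is set to zero.  The integrated signal is
the wavefront phase (negative of the object's phase delay); the pipeline
reports `Φ = k∫δ ds ≥ 0`, with the sign fixed once and verified against
simulator ground truth.

**Single-distance (Paganin) retrieval.**  The flat-corrected PBI intensity
is filtered by `1/(1 + π λ z γ |f|²)` (frequencies in cycles/m) and
converted to thickness via `t = −ln(·)/µ` with `µ = 4π δ/(γ λ)`.  The
frequency convention is pinned by an exact single-frequency transfer test.
`γ = δ/β` defaults to 202.43; the helper `tune_gamma` computes the
differential ratio `(δ_a−δ_b)/(β_a−β_b)` for a material pair.  With ICRU-44
soft tissue (1.06 g/cm³) against paraffin C₂₅H₅₂ (0.93 g/cm³) it yields
≈ 226; the ratio moves ~15% per 2% change in assumed density, which is the
honest agreement limit with tabulated literature choices.

**Reconstruction.**  Phase projections are scaled to line integrals of δ
(`Φ/k`), optionally cleaned by a Butterworth band-pass stripe filter along
the detector axis of the angle-mean (ring suppression; cutoffs in
cycles/px), and reconstructed by a built-in parallel-beam ramp-filtered
back-projection (discrete Ram–Lak kernel, linear interpolation), verified
against an independent FBP implementation and against analytic disk
phantoms (interior recovery error < 0.1% noise-free).  Transmission
projections reconstruct β via `−ln T/(2k)`.  Conversions:
`ρe = δ k²/(2π r0)` (reported in electrons/Å³) and `µ = 2 k β`.

## Quality metrics

Visibility (sliding-window std/mean, 15 px window — at least two grating
periods), autocorrelation FWHM of the mean-subtracted pattern (axis
profiles through the peak, sub-pixel crossings, averaged), Fourier-spectrum
resolution (azimuthally averaged power spectrum against the white-noise
floor `N σ²` predicted from a homogeneous ROI via Parseval, crossing located
by log-domain interpolation, Nyquist-limited results flagged), angular
sensitivity (per-axis std of the refraction-angle maps in a sample-free
ROI, in nrad), phase sensitivity (std of ρe in a homogeneous ROI pooled
over the 5 central slices), and CNR `|I_s − I_b|/σ_b` over disjoint 40×40
ROIs.  Noise ROIs are auto-placed on label-pure regions kept clear of the
specimen boundary, where FBP edge ringing would otherwise masquerade as
noise.

## Scaled-down benchmark

The default three-arm experiment runs a 128² detector / 128³ phantom with
181 angles over 180°, keeping the study's acquisition structure (16/20
modulator steps, photon noise, 20 dark / per-step reference frames) while
scaling spatial size.  On this benchmark the noise-free MBI arm recovers
the tissue-vs-paraffin δ contrast to a few percent, and under photon noise
the finer grating pattern yields better angular sensitivity than the
coarser speckle, as in the full-scale study.  Deliberate consequences of
the scaling, documented above, are the rim taper and the relatively larger
share of systematic (pattern-locked) errors in volume-domain noise
statistics.

## Known limitations

* Thin-object, monochromatic, fully coherent model: no partial coherence
  beyond the PSF, no polychromatic hardening, no multi-slice propagation.
* Sharp high-contrast boundaries produce Fresnel fringes that the shift
  model cannot track; at desk scale this is mitigated by the phantom's rim
  taper rather than by resolution.
* The dark-field channel is retained but experimental: propagation fringes
  contaminate it (as they do in real data), and only the synthetic blur
  test binds it.
* Absolute diffuser visibility is under-predicted (see above).
* Drift correction models rigid translation only.
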