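# Methods

This note records the models, conventions, estimators and numerical choices
behind `powderchain`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Geometry model and conventions

The detector is a flat grid of `n_slow x n_fast` pixels with pitches in mm.
Pixel indices are 0-based and `(0.0, 0.0)` is the **centre** of the corner
pixel; "fast" is the second array axis (`image[slow, fast]`).  In the lab
frame the direct beam runs along +z, +x is horizontal and +y vertical; the
untilted detector has fast along +x and slow along +y.

The six calibration parameters are the sample–detector distance `D` (mm,
measured along the direct beam to the beam-piercing point), the fractional
beam-centre pixel coordinates, two tilts (degrees) and the wavelength (Å).
The detector pose is built by rotating the plane first by `tilt_pitch` about
the lab horizontal axis, then by `tilt_yaw` about the lab vertical axis, and
finally translating it so the direct beam pierces it at the beam-centre
pixel at distance `D`.  This rotation order and the azimuth convention
(χ = 0 along +fast, counter-clockwise seen from the sample, range
(−180°, 180°]) are declared package-wide conventions — any self-consistent
choice works, but it must be one choice everywhere, including the synthetic
generator.  The wavelength is stored; the energy is derived through
`E[keV]·λ[Å] = 12.398419843…` and exact to double precision both ways.

A powder ring at spacing `d` is the intersection of the scattering cone of
half-opening `2θ = 2 asin(λ/2d)` with the detector plane.  The predicted
conic is computed in closed form by substituting the plane parametrisation
into the cone quadric and converting the general conic coefficients to
centre/axes/orientation; the cone–plane sampling oracle in the tests pins
this closed form to 1e-6 relative.  When `λ ≥ 2d` or the conic is not an
ellipse (ring never closes on the plane), an "unreachable reflection" error
is raised.

## Calibrants

Built-in line lists are generated from certified cubic lattice parameters
rather than hard-coded d tables: CeO₂ SRM 674b (fluorite/fcc,
a = 5.411651 Å) and Si SRM 640c (diamond cubic, a = 5.4311946 Å), with the
standard reflection conditions (fcc: h,k,l all even or all odd; diamond:
additionally h+k+l ≡ 0 mod 4 for even triples).  At most the first 50 rings
are emitted.  User line lists are plain text, one d-spacing per line.

## Ring finding

* **Beam-centre estimate.** A ring pattern is centro-symmetric about the
  beam centre, so the linear auto-convolution of the background-subtracted
  image peaks at exactly twice the centre coordinate.  It is computed by FFT
  with zero-padding to twice the image size (padding removes the circular
  modulo-N ambiguity of the peak position) and refined by a 3-point
  parabola.  Unlike a plain intensity centroid this is robust against rings
  partially clipped by the detector edge.
* **Radial peaks.** Mean intensity vs radius about the centre at ~1-pixel
  bins; peaks from prominence-based detection with parabolic sub-bin
  refinement.  Rings smeared by tilt or clipped at the edge may appear as
  split double peaks; the matcher tolerates them.
* **Radius→ring assignment.** With λ known, candidate distances are proposed
  from every (peak, ring) pair via `D = r/tan 2θ`; each candidate is scored
  by how many detected peaks coincide with its predicted radii (1.5 %
  relative tolerance), minus the number of *predicted* rings inside the
  detected radial span that were never observed.  That "missed-ring" penalty
  is essential: the near-geometric ladder of high-order tan 2θ values can
  otherwise match almost any radius set.  With λ free, candidate (D, λ)
  pairs come from assigning two peaks to two rings and solving the radius
  ratio for λ by bracketed root finding, scored the same way and polished by
  least squares.  Matching is restricted to rings with 2θ < 85° (a flat
  detector cannot see backscattering).
* **Point extraction.** For each of `n_profiles` (default 256) directions
  along the visible arc of a predicted conic, the image is sampled by
  bilinear interpolation at unit-pixel steps within ±half_width of the conic
  along the outward direction from the ellipse centre, and fitted with a
  Gaussian plus linear baseline.  Accepted fits (amplitude > 3× rms
  residual, centre inside the middle 80 % of the window, no masked sample in
  the window) become sub-pixel points weighted by the inverse variance of
  the fitted centre (floored at 1e-4 px so noiseless fits stay finite).
  Profiles whose window leaves the detector are skipped, which is what makes
  partial arcs workable.  During lock-on from an approximate geometry the
  per-ring window is capped at 0.45× the radial separation to the nearest
  neighbouring ring so a wide search window cannot swallow the neighbour's
  peak; the manual route starts at ±60 px (a few-percent guess error moves
  highly elliptical rings by tens of pixels), the automatic route at ±15 px,
  both shrinking to the ±10 px default on the second pass.
* **Ellipse fitting.** Direct algebraic least squares with the
  ellipse-specific constraint, in the numerically stable partitioned
  formulation, after centring and isotropic scaling; weighted rows; exact
  for noiseless conic points.  Collinear input or a non-elliptical best
  conic raises a degenerate-conic error.

## Geometry refinement

All routes end in damped least squares (Levenberg–Marquardt) over the free
subset of the six parameters, minimising Σ wᵢ (q(pᵢ) − 2π/dᵢ)².  The
residual is defined in *q*, not ring-radius pixels: it weights every ring
uniformly and is exact for the Gaussian-in-q generator.  Per-point σ_q is
frozen at the start from the profile-fit positional variance times the local
|∇q| of the initial geometry, so the weighted residuals are unit-variance
under the fitted point errors and the reduced χ² is meaningful.  Relative
tolerances 1e-12, iteration cap 200 per free parameter, internal scaling per
parameter magnitude.  After the fit the column-normalised Jacobian's
condition number is checked (threshold 1e7); beyond it a singular-calibration
error names the most strongly coupled parameters — the classic case being
distance and wavelength both free with a single ring or a low-angle-only
pattern.  Uncertainties are the square roots of the diagonal of
`inv(JᵀJ)·χ²_red`; the algebraic multi-distance output is always polished by
this refinement before uncertainties are quoted.

The automatic route additionally rejects solutions whose final rms(q)
exceeds 0.02 Å⁻¹: a genuine calibration leaves residuals two orders of
magnitude below that, so a large rms means the route silently mislocked
(beam centre off the detector, large tilt) and the user is directed to the
manual route.

The multi-distance regression uses the ellipse semi-major axis in mm
(semi-major pixels × pixel pitch), which assumes square pixels for the
algebraic seed; the joint least-squares polish afterwards is exact for any
pixel aspect ratio.

## Reduction

* **Threshold mask** adds out-of-range pixels to the mask without touching
  counts.  **Error inference** is Poisson with a one-photon floor,
  `σ = gain·sqrt(max(counts/gain, 1))`.
* **Solid angle**: each pixel subtends `Ω = A cos α / L²`; the correction
  multiplies by `Ω₀/Ω` normalised to 1 at the beam-centre pixel, reducing to
  `1/cos³ 2θ` untilted.  **Polarization** divides by the Kahn-convention
  factor `P = ½(1 + cos² 2θ − ξ cos 2χ sin² 2θ)`; several polarization
  conventions circulate and the Kahn form is the declared choice here.
  Pixels with P < 1e-10 are masked.
  The two corrections are elementwise multiplications and commute.
* **Binning** (azimuthal integration and cake remapping) uses the weighted
  mean as the bin statistic — flat fields stay flat — with the weight sums
  retained so sums are recoverable, and errors propagated as
  `sqrt(Σ w²σ²)/Σ w`.  `splitting="none"` assigns each unmasked pixel to the
  bin of its centre coordinate (the brute-force per-pixel histogram oracle in
  the tests is bitwise identical); `"bbox"` spreads each pixel's bounding
  interval over the bins it overlaps, computed from the four pixel corners —
  full polygon clipping is out of scope.  With bbox the default radial range
  covers the pixel-corner extremes so the total distributed weight equals
  the unmasked pixel count to 1e-9.  The bbox approximation degrades for
  pixels whose azimuth footprint wraps most of the circle (pixels containing
  the beam centre); azimuth bins live on (−180°, 180°] and a requested
  window crossing the seam is handled by rotating the coordinate first.
  Empty bins carry NaN and zero weight, never silent zeros.  Collapsing a
  cake over azimuth with its weights reproduces the direct integration to
  floating-point round-off because both partition the same per-pixel sums.
* **Dynamic background subtraction** estimates the background as the
  iteratively clipped smooth lower envelope of the azimuthally integrated
  profile: values above `envelope + clip_factor·local_error` are replaced by
  the envelope and the smoothing repeated.  The smoothing window must exceed
  the widest peak (default `n_bins/8`) or the envelope tracks the peak; with
  that satisfied the tests show peak area preserved within 2 %.  For frames
  the 1D background is remapped to pixels through q.  Negative results are
  allowed and errors are left unchanged.

## Analysis

Single peaks are fitted as Gaussian (FWHM = 2√(2 ln 2)·σ, exact by
construction) or pseudo-Voigt plus linear baseline, using the profile's
error bars as absolute weights so the reported uncertainties are calibrated
— the 3σ coverage test demands ≥ 99/100 under Poisson noise.  A fit whose
amplitude is not significant (≤ 3× its own σ) is flagged failed rather than
reporting a fabricated peak.  Series tracking fits frames independently but
warm-starts from the last success, and records per-frame failures without
aborting.

Orientation metrics summarise an azimuthal profile I(χ) over a q-band: the
isotropic level is a low percentile of the valid bins (default 5th — a
percentile, not the minimum, for noise robustness), the **degree of
orientation** is `Σ(I − I_iso)₊ / ΣI` (scale-invariant, in [0, 1]) and the
fibre **direction** is half the circular-mean angle of the excess at 2χ,
π-periodic in (−90°, 90°].  For I = 1 + cos²(χ − φ) with the floor at the
minimum the degree is exactly (½)/(3/2) = 1/3 and the direction φ.
`orientation_map` applies this per cell of an N-d scan; output rank equals
the stage rank and the stage axes propagate verbatim.

## Chain engine and provenance

Steps are registered with a typed parameter schema (validated, with defaults
filled; the same schema backs CLI help), an input kind and an output kind
(`image`, `profile`, `azprofile`, `cake`, `scalars`); chain validation walks
the kinds so a 1D-consuming step cannot follow a forwarding 2D producer.
Each innermost frame is processed independently; outputs are reassembled to
preserve the scan rank, failed frames become NaN-flagged gaps with recorded
indices (never silent drops), and serial and thread-parallel execution are
bitwise identical because frame tasks share no mutable state and results are
assembled in frame order.  A step may save its output and either forward it
or pass the unmodified input downstream (save & pass-through), so e.g. a
cake can be archived while integration consumes the pre-cake frame.

Chains serialize to a versioned JSON document — diff-able, hand-editable —
and the full verbatim serialization is stored in every output file under
`/entry/process` (NXprocess: program, version, date, input reference,
calibration reference, one sequenced NXnote per step).  Results live under
`/entry/result` (NXdata: signal `data`, `errors`, axis datasets with an
`axes` attribute), saved intermediates under `/entry/intermediate/<n>-<step>`.
Calibration files store the six parameters with units, uncertainties,
fixed-parameter set, calibrant, routine and the detector description under
`/entry/calibration`.  The field names are this package's own versioned
layout, self-consistent rather than byte-compatible with any other program.
ASCII export writes `#`-headed 2- or 3-column text, one file per frame with
a zero-padded suffix.

## Synthetic data: what it does and does not cover

The generator renders ring images as background plus ring profiles
**Gaussian in q** (not in radius) — this makes the calibration and
integration oracles exact in q-space — under any geometry, optionally
dividing out the solid-angle/polarization factors so that applying the
corrections recovers the ideal pattern, with Poisson noise applied last
under a stated seed (bit-reproducible; grid scans use per-cell spawned seed
sequences).  Gap pixels carry the detector saturation value as sentinel so
threshold masking exercises the hot/overexposed path.  Defaults (ring
amplitude 2000 counts on background 100) put the peak signal-to-noise near
44, comfortably in the regime of a well-exposed calibrant exposure.

Not modelled: point-spread, flat-field and dark-current structure, detector
distortion, beam divergence and finite sample thickness, texture/spottiness
of real powders, and amorphous halos.  Passing tests therefore demonstrate
the correctness of the geometry algebra, the estimators and the chain
engine under the declared noise model — not robustness to every detector
artefact of a real beamline, where masking and the manual route carry more
of the load.

## Problem sizes used in tests and the acceptance script

Unit tests run on 64²–512² detectors.  The statistical calibration sweep
uses twenty random geometries on a 1024² detector (distances 200–500 mm,
tilts ≤ 3° and beam centre in the central region — the automatic route's
applicability regime of near-circular, centred rings — 5–8 rings, Poisson
noise) in the test suite, and eight geometries in the acceptance script;
peak-tracking coverage uses 100 noise realisations; orientation mapping a
3×4 grid of 64² frames.  These sizes were chosen to exercise every code
path at full detector scale while keeping the whole suite fast.
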