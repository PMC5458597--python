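"""Locating Debye-Scherrer rings as sub-pixel point sets and fitting ellipses.

The automatic route first estimates an approximate tilt-free geometry from the
image alone: the beam centre from the intensity-symmetry centre, ring radii
from peaks of the azimuthally integrated radial profile, and a distance (and
wavelength, if free) from matching those radii to the calibrant d-spacings.
Rings are then located precisely by taking a few hundred interpolated line
profiles across the predicted conic and fitting a Gaussian plus linear
baseline to each; accepted fit centres become weighted sub-pixel points.
Ellipses are fitted to such point sets by the direct algebraic least-squares
method with the ellipse-specific constraint (Fitzgibbon; stable
Halir-Flusser partitioning) after centring/scaling normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit, least_squares

from .calibrant import Calibrant, ring_positions
from .errors import DegenerateConic, RingFindError
from .geometry import Conic, DetectorSpec, DiffractionGeometry, ellipse_from_conic_coefficients

#: "several hundred line profiles" across each ring circumference
DEFAULT_N_PROFILES = 256
#: minimum accepted points for an ellipse / geometry fit
MIN_POINTS = 6


@dataclass
class ProfileFit:
    """Result of a Gaussian + linear-baseline fit to one radial line profile."""

    centre: float
    sigma: float
    amplitude: float
    baseline_offset: float
    baseline_slope: float
    rms_residual: float
    centre_sigma: float


@dataclass
class RingPointSet:
    """Sub-pixel (fast, slow) points of maximum intensity on one ring."""

    ring_index: int
    d_spacing: float
    points: np.ndarray  # (n, 2) fractional pixels, columns (fast, slow)
    weights: np.ndarray  # inverse variance of the radial centre, 1/px^2

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.points.shape[0] < MIN_POINTS:
            raise RingFindError(
                f"ring {self.ring_index}: {self.points.shape[0]} points < {MIN_POINTS}"
            )
        if np.any(self.weights <= 0) or self.weights.size != self.points.shape[0]:
            raise RingFindError("weights must be positive, one per point")

    def __len__(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# initial estimation
# ---------------------------------------------------------------------------


def _parabolic_peak(values, i):
    """Sub-sample peak refinement by a 3-point parabola (cyclic indexing)."""
    n = values.size
    ym, y0, yp = values[(i - 1) % n], values[i], values[(i + 1) % n]
    denom = ym - 2 * y0 + yp
    return i + (0.5 * (ym - yp) / denom if denom != 0 else 0.0)


def _symmetry_centre(frame) -> tuple[float, float]:
    """Beam-centre estimate from the 180-degree intensity symmetry.

    A ring pattern is centro-symmetric about the beam centre, so the
    auto-convolution of the background-subtracted image (image correlated
    with its 180-degree rotation) peaks at *twice* the centre coordinate.
    Computed by FFT; robust against rings partially clipped by the detector
    edge, which badly bias a plain intensity centroid.
    """
    counts = np.where(frame.mask, np.nan, frame.counts)
    med = np.nanmedian(counts)
    weight = np.clip(counts - med, 0, None)
    weight = np.where(np.isnan(weight), 0.0, weight)
    total = weight.sum()
    if total <= 0:
        raise RingFindError("no rings detected: image has no above-median structure")
    # zero-pad to twice the size: the linear (non-circular) auto-convolution
    # peaks at exactly twice the centre coordinate, with no modulo ambiguity
    padded_shape = (2 * weight.shape[0], 2 * weight.shape[1])
    f = np.fft.rfft2(weight, s=padded_shape)
    conv = np.fft.irfft2(f * f, s=padded_shape)
    i_slow, i_fast = np.unravel_index(int(np.argmax(conv)), conv.shape)
    two_cs = _parabolic_peak(conv[:, i_fast], i_slow)
    two_cf = _parabolic_peak(conv[i_slow, :], i_fast)
    return (two_cf / 2.0, two_cs / 2.0)


def _radial_intensity_profile(frame, detector: DetectorSpec, centre):
    """Mean intensity vs radius (mm) about a centre, at ~1-pixel bins."""
    cf, cs = centre
    slow_idx, fast_idx = np.indices(frame.counts.shape)
    r = np.hypot(
        (fast_idx - cf) * detector.pixel_size_fast,
        (slow_idx - cs) * detector.pixel_size_slow,
    )
    step = min(detector.pixel_size_fast, detector.pixel_size_slow)
    valid = ~frame.mask
    idx = (r[valid] / step).astype(np.int64)
    n_bins = int(idx.max()) + 1
    sums = np.bincount(idx, weights=frame.counts[valid], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    radii = (np.arange(n_bins) + 0.5) * step
    return radii, profile


def _detect_radial_peaks(radii, profile):
    y = profile.copy()
    valid = np.isfinite(y)
    if valid.sum() < 10:
        raise RingFindError("no rings detected: radial profile too short")
    idx = np.arange(y.size)
    y[~valid] = np.interp(idx[~valid], idx[valid], y[valid])
    base = np.median(y)
    prominence = 0.05 * max(np.max(y) - base, 1e-12)
    peaks, props = signal.find_peaks(y, prominence=prominence)
    if peaks.size < 1:
        raise RingFindError("no rings detected in the radial profile")
    # refine each peak position by a 3-point parabola
    refined = []
    for p in peaks:
        if 0 < p < y.size - 1:
            denom = y[p - 1] - 2 * y[p] + y[p + 1]
            shift = 0.5 * (y[p - 1] - y[p + 1]) / denom if denom != 0 else 0.0
            refined.append(radii[p] + shift * (radii[1] - radii[0]))
        else:
            refined.append(radii[p])
    order = np.argsort(props["prominences"])[::-1]
    # keep the most prominent peaks, in radius order
    keep = np.sort(np.asarray(refined)[order[:24]])
    return keep


#: relative radius tolerance when matching detected peaks to predicted rings;
#: generous enough to absorb the peak splitting of partially clipped rings
MATCH_RTOL = 0.015


def _greedy_match(peak_radii, predicted):
    """Match each predicted radius to the closest unused detected peak.

    Returns (ring_indices, matched_radii); a prediction with no peak inside
    ``MATCH_RTOL`` relative stays unmatched.  Spurious extra peaks (e.g. the
    split doublets of edge-clipped rings) are simply ignored.
    """
    used = np.zeros(peak_radii.size, dtype=bool)
    rings, radii = [], []
    for j, r_pred in enumerate(predicted):
        if not np.isfinite(r_pred) or r_pred <= 0:
            continue
        err = np.abs(peak_radii - r_pred) / r_pred
        err[used] = np.inf
        i = int(np.argmin(err))
        if err[i] <= MATCH_RTOL:
            used[i] = True
            rings.append(j)
            radii.append(float(peak_radii[i]))
    return rings, np.asarray(radii)


def _missed_predictions(predicted, n_matched, peak_radii):
    """Number of predicted rings inside the detected radial span with no peak.

    A physically correct assignment cannot predict extra rings between the
    innermost and outermost detected peaks: those would have been seen.  This
    penalty rejects the spurious high-order assignments where the nearly
    geometric ladder of tan(2theta) values matches almost any radius set.
    """
    finite = np.isfinite(predicted)
    in_span = (
        finite
        & (predicted >= 0.98 * peak_radii.min())
        & (predicted <= 1.02 * peak_radii.max())
    )
    return max(int(in_span.sum()) - n_matched, 0)


def _match_radii_known_wavelength(peak_radii, cal_rings):
    """Assign observed radii to calibrant rings sharing one distance.

    Candidate distances come from every (peak, ring) pair ``D = r / tan(2
    theta)``; each candidate is scored by how many detected peaks coincide
    with its predicted ring radii, ties broken toward lower residual.
    Returns ``(ring_indices, matched_radii, distance)``.
    """
    # forward cone only: a flat detector can never see 2theta >= 90
    usable = [(j, t) for j, (_, _, t) in enumerate(cal_rings) if t < 85.0]
    tans = {j: np.tan(np.deg2rad(t)) for j, t in usable}
    if len(usable) == 1:
        # single-line calibrant: the assignment is unambiguous
        j = usable[0][0]
        return [j], np.array([peak_radii[0]]), float(peak_radii[0] / tans[j])
    best = None
    for j, _ in usable:
        for r in peak_radii[:12]:
            dist = r / tans[j]
            if dist <= 0:
                continue
            predicted = np.array([dist * tans[k] for k, _ in usable])
            rings_rel, radii = _greedy_match(peak_radii, predicted)
            if len(rings_rel) < 2:
                continue
            rings = [usable[k][0] for k in rings_rel]
            pred = np.array([dist * tans[k] for k in rings])
            resid = float(np.sqrt(np.mean(((radii - pred) / pred) ** 2)))
            missed = _missed_predictions(predicted, len(rings_rel), peak_radii)
            score = (-(len(rings) - missed), resid)
            if best is None or score < best[0]:
                dist_ref = float(np.median(radii / np.array([tans[k] for k in rings])))
                best = (score, rings, radii, dist_ref)
    if best is None:
        raise RingFindError(
            "no consistent radius-to-ring assignment found for this calibrant"
        )
    _, rings, radii, distance = best
    return rings, radii, distance


def _match_radii_free_wavelength(peak_radii, calibrant: Calibrant):
    """Joint (distance, wavelength) estimate over candidate assignments.

    With only ring radii the product D*lambda is nearly degenerate at small
    angles; the curvature of r(d) at higher angles breaks it.  Candidate
    (D, lambda) pairs come from assigning two detected peaks to two calibrant
    rings and solving the radius ratio for lambda (monotone in lambda), then
    each candidate is scored by matched-peak count and polished by least
    squares over its matches.  Returns ``(ring_indices, radii, D, lambda)``.
    """
    from scipy.optimize import brentq

    d_all = np.asarray(calibrant.d_spacings, dtype=float)
    n_rings_try = min(len(d_all), 10)
    best = None

    def radius(dist, lam, d):
        s = lam / (2.0 * d)
        with np.errstate(invalid="ignore"):
            return np.where(s < 0.999, dist * np.tan(2.0 * np.arcsin(np.minimum(s, 0.999))), np.inf)

    for i1 in range(min(peak_radii.size, 4)):
        for i2 in range(i1 + 1, min(peak_radii.size, 8)):
            ratio = peak_radii[i1] / peak_radii[i2]
            for j1 in range(n_rings_try - 1):
                for j2 in range(j1 + 1, n_rings_try):
                    d1, d2 = d_all[j1], d_all[j2]

                    def g(lam):
                        t1 = np.tan(2.0 * np.arcsin(lam / (2.0 * d1)))
                        t2 = np.tan(2.0 * np.arcsin(lam / (2.0 * d2)))
                        return t1 / t2 - ratio

                    lam_hi = 1.999 * d2 * min(1.0, np.sin(np.deg2rad(42.0)))
                    try:
                        if g(1e-4) * g(lam_hi) > 0:
                            continue
                        lam = brentq(g, 1e-4, lam_hi, xtol=1e-10)
                    except ValueError:
                        continue
                    dist = peak_radii[i1] / np.tan(2.0 * np.arcsin(lam / (2.0 * d1)))
                    if dist <= 0:
                        continue
                    predicted = radius(dist, lam, d_all)
                    rings, radii = _greedy_match(peak_radii, predicted)
                    if len(rings) < 3:
                        continue
                    pred = radius(dist, lam, d_all[rings])
                    resid = float(np.sqrt(np.mean(((radii - pred) / pred) ** 2)))
                    missed = _missed_predictions(predicted, len(rings), peak_radii)
                    score = (-(len(rings) - missed), resid)
                    if best is None or score < best[0]:
                        best = (score, rings, radii, float(dist), float(lam))
    if best is None:
        raise RingFindError("no consistent assignment found with free wavelength")
    _, rings, radii, dist, lam = best

    def model(params):
        return radius(params[0], params[1], d_all[rings]) - radii

    res = least_squares(model, [dist, lam], method="lm", max_nfev=400)
    return rings, radii, float(res.x[0]), float(res.x[1])


def estimate_initial_rings(
    frame,
    detector: DetectorSpec,
    calibrant: Calibrant,
    beam_centre_guess: Optional[tuple[float, float]] = None,
    wavelength: Optional[float] = None,
):
    """Approximate tilt-free geometry and per-ring radii from a single image.

    Applicable to near-circular rings with the beam centre on the detector.
    Returns ``(geometry, matches)`` where the geometry has tilt 0 and
    ``matches`` is a list of ``(ring_index, d_spacing, radius_mm)`` for the
    detected rings, ``ring_index`` indexing the calibrant line list.
    """
    centre = beam_centre_guess or _symmetry_centre(frame)
    radii, profile = _radial_intensity_profile(frame, detector, centre)
    peak_radii = _detect_radial_peaks(radii, profile)
    if wavelength is not None:
        cal_rings = ring_positions(calibrant, wavelength)
        if not cal_rings:
            raise RingFindError("no calibrant reflection reachable at this wavelength")
        rings, radii, distance = _match_radii_known_wavelength(peak_radii, cal_rings)
        lam = wavelength
        d_sel = [cal_rings[j][0] for j in rings]
    else:
        rings, radii, distance, lam = _match_radii_free_wavelength(peak_radii, calibrant)
        d_sel = [float(calibrant.d_spacings[j]) for j in rings]
    geom = DiffractionGeometry(
        distance=distance,
        beam_centre_fast=centre[0],
        beam_centre_slow=centre[1],
        tilt_pitch=0.0,
        tilt_yaw=0.0,
        wavelength=lam,
        detector=detector,
    )
    matches = [
        (rings[i], float(d_sel[i]), float(radii[i])) for i in range(len(rings))
    ]
    return geom, matches


# ---------------------------------------------------------------------------
# point extraction
# ---------------------------------------------------------------------------


def _gauss_linear(u, amp, u0, sigma, off, slope):
    return amp * np.exp(-((u - u0) ** 2) / (2.0 * sigma**2)) + off + slope * u


def _fit_profile(u, y) -> Optional[ProfileFit]:
    i_max = int(np.argmax(y))
    off0 = 0.5 * (y[0] + y[-1])
    slope0 = (y[-1] - y[0]) / (u[-1] - u[0])
    amp0 = max(y[i_max] - off0, 1e-3)
    p0 = [amp0, u[i_max], max((u[-1] - u[0]) / 8.0, 1.0), off0, slope0]
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(_gauss_linear, u, y, p0=p0, maxfev=400)
    except Exception:
        return None
    amp, u0, sigma, off, slope = popt
    resid = y - _gauss_linear(u, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    var = pcov[1, 1] if np.all(np.isfinite(pcov)) else np.nan
    centre_sigma = float(np.sqrt(var)) if np.isfinite(var) and var > 0 else 0.0
    return ProfileFit(
        centre=float(u0),
        sigma=float(abs(sigma)),
        amplitude=float(amp),
        baseline_offset=float(off),
        baseline_slope=float(slope),
        rms_residual=rms,
        centre_sigma=centre_sigma,
    )


#: floor on the per-point centre uncertainty (px) so noiseless fits keep
#: finite inverse-variance weights
MIN_CENTRE_SIGMA = 1e-4


def extract_ring_points(
    frame,
    predicted: Conic,
    n_profiles: int = DEFAULT_N_PROFILES,
    half_width: Optional[float] = None,
    ring_index: int = 0,
    d_spacing: float = 1.0,
    amplitude_snr: float = 3.0,
    centre_window: float = 0.8,
) -> RingPointSet:
    """Sub-pixel ring points from radial line profiles across a predicted conic.

    For each of ``n_profiles`` directions along the visible arc, the image is
    sampled by bilinear interpolation at unit-pixel steps within
    ``+-half_width`` of the conic along the direction from the ellipse centre,
    and fitted with a Gaussian plus linear baseline.  A fit is accepted when
    the amplitude exceeds ``amplitude_snr`` times the rms residual, the centre
    lies within the middle ``centre_window`` fraction of the window and no
    sample in the window is masked.  Partial arcs (profiles off the detector)
    are skipped, which supports the manual route's highly tilted images.
    """
    if half_width is None:
        half_width = 10.0
    half_width = max(float(half_width), 3.0)
    n_slow, n_fast = frame.counts.shape
    t = np.linspace(0.0, 2.0 * np.pi, n_profiles, endpoint=False)
    pf, ps = predicted.sample(t=t)
    # radial direction: outward from the ellipse centre
    dirf = pf - predicted.centre_fast
    dirs = ps - predicted.centre_slow
    norm = np.hypot(dirf, dirs)
    ok = norm > 0
    dirf, dirs = dirf / np.where(ok, norm, 1.0), dirs / np.where(ok, norm, 1.0)
    offsets = np.arange(-np.floor(half_width), np.floor(half_width) + 1.0)

    # sample positions for all profiles at once: (n_profiles, n_samples)
    sf = pf[:, None] + offsets[None, :] * dirf[:, None]
    ss = ps[:, None] + offsets[None, :] * dirs[:, None]
    on_det = (sf >= 0) & (sf <= n_fast - 1) & (ss >= 0) & (ss <= n_slow - 1)
    profile_ok = ok & on_det.all(axis=1)
    if not np.any(profile_ok):
        raise RingFindError("predicted conic lies entirely off the detector")

    vals = map_coordinates(frame.counts, [ss[profile_ok], sf[profile_ok]], order=1)
    masked = map_coordinates(
        frame.mask.astype(float), [ss[profile_ok], sf[profile_ok]], order=1
    )
    idx_ok = np.flatnonzero(profile_ok)

    points, weights = [], []
    n_masked = 0
    for row, i in enumerate(idx_ok):
        if np.any(masked[row] > 1e-9):
            n_masked += 1
            continue
        fit = _fit_profile(offsets, vals[row])
        if fit is None:
            continue
        if fit.amplitude <= amplitude_snr * max(fit.rms_residual, 1e-12):
            continue
        if abs(fit.centre) > centre_window * half_width:
            continue
        points.append(
            (pf[i] + fit.centre * dirf[i], ps[i] + fit.centre * dirs[i])
        )
        sig = max(fit.centre_sigma, MIN_CENTRE_SIGMA)
        weights.append(1.0 / sig**2)
    if len(points) < MIN_POINTS:
        raise RingFindError(
            f"ring {ring_index}: only {len(points)} accepted profile fits "
            f"(of {n_profiles}; {n_masked} rejected on mask)"
        )
    return RingPointSet(
        ring_index=ring_index,
        d_spacing=d_spacing,
        points=np.asarray(points),
        weights=np.asarray(weights),
    )


# ---------------------------------------------------------------------------
# direct ellipse fit
# ---------------------------------------------------------------------------


def fit_ellipse(points, weights=None) -> Conic:
    """Direct algebraic least-squares ellipse fit with ellipse constraint.

    Stable partitioned formulation of the Fitzgibbon constrained fit, applied
    after centring and isotropic scaling of the coordinates for conditioning;
    exact for noiseless points on an ellipse.  Raises
    :class:`DegenerateConic` for collinear input or when the best conic is
    not an ellipse.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < MIN_POINTS:
        raise DegenerateConic("need at least 6 points")
    if weights is None:
        w = np.ones(pts.shape[0])
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    w = w / w.mean()

    mean = pts.mean(axis=0)
    centred = pts - mean
    scale = np.sqrt(np.mean(centred**2))
    if scale == 0:
        raise DegenerateConic("all points coincide")
    x, y = (centred / scale).T
    sw = np.sqrt(w)

    d1 = np.column_stack([x * x, x * y, y * y]) * sw[:, None]
    d2 = np.column_stack([x, y, np.ones_like(x)]) * sw[:, None]
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConic("degenerate point configuration") from exc
    m = s1 + s2 @ t
    c1_inv = np.array([[0.0, 0.0, 0.5], [0.0, -1.0, 0.0], [0.5, 0.0, 0.0]])
    try:
        evals, evecs = np.linalg.eig(c1_inv @ m)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConic("eigen decomposition failed") from exc
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    candidates = np.flatnonzero(np.isreal(evals) & (cond > 0))
    if candidates.size == 0:
        raise DegenerateConic("best-fitting conic is not an ellipse")
    i = candidates[np.argmin(np.abs(evals[candidates]))] if candidates.size > 1 else candidates[0]
    a1 = np.real(evecs[:, i])
    coeffs_n = np.concatenate([a1, t @ a1])

    # de-normalise: conic matrix transform under x_n = (x - mx) / s
    a, b, c, d, e, f = coeffs_n
    cn = np.array([[a, b / 2, d / 2], [b / 2, c, e / 2], [d / 2, e / 2, f]])
    tr = np.array(
        [[1 / scale, 0, -mean[0] / scale], [0, 1 / scale, -mean[1] / scale], [0, 0, 1.0]]
    )
    co = tr.T @ cn @ tr
    return ellipse_from_conic_coefficients(
        co[0, 0], 2 * co[0, 1], co[1, 1], 2 * co[0, 2], 2 * co[1, 2], co[2, 2]
    )
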