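"""Geometry calibration: automatic (single- and multi-distance) and manual routes.

All routes end in the same damped least-squares refinement of the six
geometry parameters against the ring point sets, with the residual defined in
momentum transfer: for point *i* on the ring of spacing *d*,
``r_i = (q(point_i; params) - 2 pi / d) / sigma_q,i``.  Working in q gives a
uniform metric across rings and is exact for the Gaussian-in-q synthetic
generator.  Uncertainties come from the covariance of the solution scaled by
the reduced chi-square; the algebraic multi-distance solution is always
polished by this least-squares step before uncertainties are quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .calibrant import Calibrant
from .errors import (
    CalibrationError,
    RingFindError,
    SingularCalibration,
    UnreachableReflection,
)
from .geometry import (
    _PARAM_NAMES,
    DetectorSpec,
    DiffractionGeometry,
    pixel_to_angles,
    predict_ring,
)
from .ringfind import (
    RingPointSet,
    estimate_initial_rings,
    extract_ring_points,
    fit_ellipse,
)

PARAMETER_NAMES = tuple(_PARAM_NAMES)

#: damped least-squares settings: relative tolerance and iteration cap
FIT_TOL = 1e-12
MAX_ITER = 200
#: condition-number threshold (column-normalised Jacobian) above which the
#: free-parameter set is reported as degenerate/ambiguous
COND_LIMIT = 1e7


@dataclass
class CalibrationResult:
    """A calibrated geometry with per-parameter uncertainties and provenance."""

    geometry: DiffractionGeometry
    uncertainties: dict  # free parameter name -> 1-sigma, same units
    fixed_parameters: tuple
    residual_rms_q: float
    n_points: int
    n_rings: int
    routine: str  # auto_single | auto_multi | manual
    calibrant_name: str
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 0 for v in self.uncertainties.values()):
            raise CalibrationError("uncertainties must be >= 0")
        free = set(self.uncertainties)
        fixed = set(self.fixed_parameters)
        if free | fixed != set(PARAMETER_NAMES) or free & fixed:
            raise CalibrationError(
                "free and fixed parameters must partition the 6 geometry parameters"
            )


def _point_q_sigma(geom: DiffractionGeometry, point_sets: Sequence[RingPointSet]):
    """Per-point 1-sigma in q, frozen from the initial geometry.

    The profile fits deliver positional variance in pixels along the radial
    direction; this converts it through the local gradient |grad q| so the
    q-residuals are unit-variance under the fitted point errors.
    """
    sigmas = []
    eps = 0.05
    for ps in point_sets:
        fast = ps.points[:, 0]
        slow = ps.points[:, 1]
        q0 = pixel_to_angles(geom, fast, slow).q
        dqf = (pixel_to_angles(geom, fast + eps, slow).q - q0) / eps
        dqs = (pixel_to_angles(geom, fast, slow + eps).q - q0) / eps
        grad = np.hypot(dqf, dqs)
        sigma_px = 1.0 / np.sqrt(ps.weights)
        sigmas.append(np.maximum(grad * sigma_px, 1e-15))
    return sigmas


def _assemble(point_sets: Sequence[RingPointSet]):
    fast = np.concatenate([ps.points[:, 0] for ps in point_sets])
    slow = np.concatenate([ps.points[:, 1] for ps in point_sets])
    q_target = np.concatenate(
        [np.full(len(ps), 2.0 * np.pi / ps.d_spacing) for ps in point_sets]
    )
    return fast, slow, q_target


def _refine_blocks(
    blocks,
    initial: DiffractionGeometry,
    fixed: Sequence[str],
):
    """Core refinement over one or more frames sharing all parameters.

    ``blocks`` is a list of ``(point_sets, distance_increment)``; the distance
    parameter refined is the base distance, each block evaluated at
    ``distance + increment`` (multi-distance series).  Returns the refined
    geometry, per-free-parameter uncertainties, the rms q-residual and counts.
    """
    fixed = tuple(fixed)
    unknown = set(fixed) - set(PARAMETER_NAMES)
    if unknown:
        raise CalibrationError(f"unknown parameter names in fixed: {sorted(unknown)}")
    free_idx = [i for i, n in enumerate(PARAMETER_NAMES) if n not in fixed]
    if not free_idx:
        raise CalibrationError("no free parameters")
    detector = initial.detector
    x_full0 = initial.parameter_vector()

    data = []
    n_points = 0
    for point_sets, delta in blocks:
        fast, slow, q_target = _assemble(point_sets)
        geom_block = initial.replace(distance=initial.distance + delta)
        sigma_blocks = _point_q_sigma(geom_block, point_sets)
        sigma = np.concatenate(sigma_blocks)
        data.append((fast, slow, q_target, sigma, delta))
        n_points += fast.size
    if n_points < 2 + len(free_idx):
        raise CalibrationError(
            f"{n_points} points cannot constrain {len(free_idx)} free parameters"
        )

    def residuals(x_free):
        x = x_full0.copy()
        x[free_idx] = x_free
        out = []
        for fast, slow, q_target, sigma, delta in data:
            geom = DiffractionGeometry.from_parameter_vector(x, detector).replace(
                distance=x[0] + delta
            )
            q = pixel_to_angles(geom, fast, slow).q
            out.append((q - q_target) / sigma)
        return np.concatenate(out)

    scale = np.array([max(abs(x_full0[i]) * 1e-3, 1e-4) for i in free_idx])
    res = least_squares(
        residuals,
        x_full0[free_idx],
        method="lm",
        xtol=FIT_TOL,
        ftol=FIT_TOL,
        gtol=FIT_TOL,
        x_scale=scale,
        max_nfev=MAX_ITER * (len(free_idx) + 1),
    )
    if not res.success and res.status <= 0:
        raise CalibrationError(f"refinement did not converge: {res.message}")

    jac = res.jac
    col_norm = np.linalg.norm(jac, axis=0)
    if np.any(col_norm == 0):
        dead = [PARAMETER_NAMES[free_idx[i]] for i in np.flatnonzero(col_norm == 0)]
        raise SingularCalibration(
            f"parameters unconstrained by the data: {dead}", parameters=dead
        )
    jn = jac / col_norm
    sv = np.linalg.svd(jn, compute_uv=False)
    cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
    if cond > COND_LIMIT:
        _, _, vt = np.linalg.svd(jn)
        null = np.abs(vt[-1])
        worst = np.argsort(null)[::-1][:2]
        names = [PARAMETER_NAMES[free_idx[i]] for i in worst]
        raise SingularCalibration(
            "singular normal matrix: free parameters "
            f"{names} are degenerate with the available rings "
            f"(condition number {cond:.2g}); fix one or add rings/angular span",
            parameters=names,
        )

    dof = max(res.fun.size - len(free_idx), 1)
    chi2_red = float(2.0 * res.cost / dof)
    jtj = jac.T @ jac
    cov = np.linalg.inv(jtj) * chi2_red
    sig = np.sqrt(np.clip(np.diag(cov), 0, None))
    uncertainties = {
        PARAMETER_NAMES[free_idx[i]]: float(sig[i]) for i in range(len(free_idx))
    }
    x = x_full0.copy()
    x[free_idx] = res.x
    geometry = DiffractionGeometry.from_parameter_vector(x, detector)

    # rms residual in q, unweighted
    sq = []
    for fast, slow, q_target, sigma, delta in data:
        geom = geometry.replace(distance=geometry.distance + delta)
        q = pixel_to_angles(geom, fast, slow).q
        sq.append(q - q_target)
    rms_q = float(np.sqrt(np.mean(np.concatenate(sq) ** 2)))
    return geometry, uncertainties, rms_q, n_points


def refine_geometry(
    ring_point_sets: Sequence[RingPointSet],
    initial: DiffractionGeometry,
    fixed: Sequence[str] = ("wavelength",),
    routine: str = "manual",
    calibrant_name: str = "",
) -> CalibrationResult:
    """Least-squares refinement of the geometry against ring point sets.

    Minimises the weighted sum of squared q-residuals over the free
    parameters; raises :class:`SingularCalibration` when the free-parameter
    set is degenerate for the available rings (e.g. distance and wavelength
    both free with a single ring).
    """
    geometry, unc, rms_q, n_points = _refine_blocks(
        [(list(ring_point_sets), 0.0)], initial, fixed
    )
    return CalibrationResult(
        geometry=geometry,
        uncertainties=unc,
        fixed_parameters=tuple(fixed),
        residual_rms_q=rms_q,
        n_points=n_points,
        n_rings=len(ring_point_sets),
        routine=routine,
        calibrant_name=calibrant_name,
    )


# ---------------------------------------------------------------------------
# automatic routes
# ---------------------------------------------------------------------------


def _extract_for_geometry(
    frame, geom: DiffractionGeometry, ring_indices_d, n_profiles, half_width
):
    """Extract point sets for the given rings from predicted conics.

    The profile window of each ring is capped at just under half the radial
    separation to its nearest neighbouring ring, so a wide search window on a
    densely ringed pattern cannot swallow the neighbour's peak.
    """
    conics = {}
    for idx, d in ring_indices_d:
        try:
            conics[idx] = predict_ring(geom, d)
        except UnreachableReflection:
            conics[idx] = None
    radii = {i: c.semi_major for i, c in conics.items() if c is not None}
    sets = []
    counts = {}
    for idx, d in ring_indices_d:
        if conics[idx] is None:
            counts[idx] = 0
            continue
        hw = float(half_width)
        others = [abs(radii[idx] - r) for j, r in radii.items() if j != idx]
        if others:
            hw = max(min(hw, 0.45 * min(others)), 3.0)
        try:
            ps = extract_ring_points(
                frame,
                conics[idx],
                n_profiles=n_profiles,
                half_width=hw,
                ring_index=idx,
                d_spacing=d,
            )
            sets.append(ps)
            counts[idx] = len(ps)
        except RingFindError:
            counts[idx] = 0
    return sets, counts


def _default_half_width(geom, ring_width_q=None):
    # max(10 px, 4 x expected ring sigma in px); the expected sigma is only
    # known for synthetic data, so 10 px is the practical default
    if ring_width_q is None:
        return 10.0
    return max(10.0, 4.0 * ring_width_q)


def calibrate_auto_single(
    frame,
    detector: DetectorSpec,
    calibrant: Calibrant,
    wavelength: Optional[float] = None,
    fixed_extra: Sequence[str] = (),
    n_profiles: int = 256,
    half_width: Optional[float] = None,
) -> CalibrationResult:
    """Fully automatic calibration from a single image.

    Estimates an approximate tilt-free geometry from the image, extracts ring
    points along the predicted circles, refines all six parameters (wavelength
    fixed when supplied), then re-extracts from the refined conics and refines
    once more.  Requires near-circular rings with the beam centre on the
    detector; pass a wavelength when only low-angle rings are available,
    otherwise the distance-wavelength ambiguity is reported.
    """
    geom0, matches = estimate_initial_rings(
        frame, detector, calibrant, wavelength=wavelength
    )
    rings = [(idx, d) for idx, d, _ in matches]
    hw = half_width if half_width is not None else _default_half_width(geom0)
    fixed = tuple(fixed_extra) + (("wavelength",) if wavelength is not None else ())
    # first pass with a widened window: the tilt-free initial conics can sit
    # several pixels off the true (slightly eccentric) rings
    sets, counts = _extract_for_geometry(frame, geom0, rings, n_profiles, max(hw, 15.0))
    if not sets:
        raise RingFindError(f"ring finding failed on every ring: {counts}")
    result = refine_geometry(
        sets, geom0, fixed=fixed, routine="auto_single", calibrant_name=calibrant.name
    )
    # second pass: lock on to the refined conics
    sets2, counts2 = _extract_for_geometry(frame, result.geometry, rings, n_profiles, hw)
    if sets2:
        result = refine_geometry(
            sets2,
            result.geometry,
            fixed=fixed,
            routine="auto_single",
            calibrant_name=calibrant.name,
        )
        counts = counts2
    # lock-on sanity: a genuine calibration leaves q-residuals far below the
    # ring spacing; a large rms means the automatic route silently mislocked
    # (beam centre off the detector, large tilt, wrong assignment)
    if result.residual_rms_q > 0.02:
        raise RingFindError(
            f"automatic route failed to lock on (rms(q) = "
            f"{result.residual_rms_q:.3g} 1/A); the beam centre may be off "
            "the detector or the tilt large - use the manual route"
        )
    result.details["accepted_points_per_ring"] = counts
    return result


def calibrate_manual(
    frame,
    detector: DetectorSpec,
    calibrant: Calibrant,
    initial_guess: DiffractionGeometry,
    fixed: Sequence[str] = ("wavelength",),
    n_profiles: int = 256,
    half_width: Optional[float] = None,
    max_rings: Optional[int] = None,
) -> CalibrationResult:
    """Manual route: refine from a user-supplied initial geometry.

    Predicted conics from the guess seed the point extraction on whatever
    arcs are visible (large tilts and off-centre beams supported).  If too few
    rings lock on, a ring-finding error with per-ring acceptance counts is
    raised, signalling that the guess must be adjusted before re-running.
    """
    from .calibrant import ring_positions

    hw = half_width if half_width is not None else _default_half_width(initial_guess)
    rings_all = ring_positions(calibrant, initial_guess.wavelength)
    if max_rings is not None:
        rings_all = rings_all[:max_rings]
    rings = [(i, d) for i, (d, _, _) in enumerate(rings_all)]
    # wide first-pass window: a few-percent guess error displaces highly
    # elliptical rings by tens of pixels on a large detector
    sets, counts = _extract_for_geometry(
        frame, initial_guess, rings, n_profiles, max(hw, 60.0)
    )
    if not sets or sum(len(s) for s in sets) < 12:
        raise RingFindError(
            "ring finding failed from the initial guess; accepted points per ring: "
            f"{counts}; adjust the guess and re-run"
        )
    result = refine_geometry(
        sets, initial_guess, fixed=fixed, routine="manual", calibrant_name=calibrant.name
    )
    sets2, counts2 = _extract_for_geometry(frame, result.geometry, rings, n_profiles, hw)
    if not sets2 or sum(len(s) for s in sets2) < 12:
        raise RingFindError(
            "ring finding failed from the initial guess; accepted points per "
            f"ring after lock-on: {counts2}; adjust the guess and re-run"
        )
    result = refine_geometry(
        sets2, result.geometry, fixed=fixed, routine="manual",
        calibrant_name=calibrant.name,
    )
    counts = counts2
    result.details["accepted_points_per_ring"] = counts
    return result


def solve_multi_distance(
    frames_with_increments,
    detector: DetectorSpec,
    calibrant: Calibrant,
    wavelength_known: Optional[float] = None,
    n_profiles: int = 256,
    half_width: Optional[float] = None,
) -> CalibrationResult:
    """Multi-distance calibration from images at known distance increments.

    Non-iterative core: for every frame, ellipses are fitted to all rings; per
    ring the semi-major axis (in mm) is regressed against the increment, whose
    slope is tan(2theta) independent of the unknown base distance and of the
    wavelength.  Matching the slopes to the calibrant d-spacings yields the
    wavelength (when free) and the base distance from the intercepts.  The
    full six-parameter solution is then polished by least squares over all
    frames jointly before uncertainties are quoted.
    """
    frames = [f for f, _ in frames_with_increments]
    deltas = np.array([float(d) for _, d in frames_with_increments])
    if len(frames) < 2:
        raise CalibrationError("need at least 2 frames with distance increments")
    if np.unique(deltas).size != deltas.size:
        raise CalibrationError("distance increments must be distinct")

    # per-frame ring point sets keyed by calibrant ring index
    per_frame_sets: list[dict[int, RingPointSet]] = []
    lam_hint = wavelength_known
    centre0 = None
    for frame in frames:
        # the free-wavelength assignment search runs on the first frame only;
        # later frames reuse that wavelength for a cheap, robust assignment
        geom_i, matches = estimate_initial_rings(
            frame, detector, calibrant, wavelength=lam_hint
        )
        if lam_hint is None:
            lam_hint = geom_i.wavelength
        if centre0 is None:
            centre0 = (geom_i.beam_centre_fast, geom_i.beam_centre_slow)
        hw = half_width if half_width is not None else _default_half_width(geom_i)
        sets, _ = _extract_for_geometry(
            frame, geom_i, [(i, d) for i, d, _ in matches], n_profiles, hw
        )
        per_frame_sets.append({ps.ring_index: ps for ps in sets})

    common = set.intersection(*(set(d) for d in per_frame_sets))
    if not common:
        raise CalibrationError("no ring found in every frame of the series")

    pix = min(detector.pixel_size_fast, detector.pixel_size_slow)
    slopes = {}
    intercepts = {}
    for idx in sorted(common):
        semi_major = []
        for d_sets in per_frame_sets:
            ps = d_sets[idx]
            conic = fit_ellipse(ps.points, ps.weights)
            semi_major.append(conic.semi_major * pix)  # mm
        a = np.asarray(semi_major)
        slope, intercept = np.polyfit(deltas, a, 1)
        if slope <= 0:
            raise CalibrationError(
                f"ring {idx}: semi-major axis does not grow with distance "
                f"(slope {slope:.3g}); check the increments"
            )
        slopes[idx] = slope
        intercepts[idx] = intercept

    # slope_k = tan(2theta_k) -> theta_k; D0 from intercept = D0 * slope
    d_by_index = {i: float(d) for i, d in enumerate(calibrant.d_spacings)}
    theta = {i: 0.5 * np.arctan(s) for i, s in slopes.items()}
    if wavelength_known is None:
        lam_values = [2.0 * d_by_index[i] * np.sin(theta[i]) for i in slopes]
        lam = float(np.median(lam_values))
    else:
        lam = float(wavelength_known)
    d0_values = [intercepts[i] / slopes[i] for i in slopes]
    d0 = float(np.median(d0_values))
    if d0 <= 0:
        raise CalibrationError("non-positive base distance from the regression")

    initial = DiffractionGeometry(
        distance=d0,
        beam_centre_fast=centre0[0],
        beam_centre_slow=centre0[1],
        tilt_pitch=0.0,
        tilt_yaw=0.0,
        wavelength=lam,
        detector=detector,
    )
    fixed = ("wavelength",) if wavelength_known is not None else ()
    blocks = [
        ([ps for ps in per_frame_sets[i].values()], float(deltas[i]))
        for i in range(len(frames))
    ]
    geometry, unc, rms_q, n_points = _refine_blocks(blocks, initial, fixed)
    n_rings = len({idx for d_sets in per_frame_sets for idx in d_sets})
    return CalibrationResult(
        geometry=geometry,
        uncertainties=unc,
        fixed_parameters=tuple(fixed),
        residual_rms_q=rms_q,
        n_points=n_points,
        n_rings=n_rings,
        routine="auto_multi",
        calibrant_name=calibrant.name,
        details={
            "increments_mm": deltas.tolist(),
            "algebraic_distance_mm": d0,
            "algebraic_wavelength_A": lam,
        },
    )


# ---------------------------------------------------------------------------
# persistence (NeXus layout shared with the pipeline module)
# ---------------------------------------------------------------------------


def save_calibration(result: CalibrationResult, path: str) -> None:
    """Save a calibration with provenance to a NeXus file (see nexus module)."""
    from .nexus import write_calibration

    write_calibration(result, path)


def load_calibration(path: str) -> CalibrationResult:
    """Load a calibration saved by :func:`save_calibration`."""
    from .nexus import read_calibration

    return read_calibration(path)
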