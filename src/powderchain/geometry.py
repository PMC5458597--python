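"""Six-parameter diffraction geometry of a flat 2D detector.

The geometry of a scattering experiment on a flat area detector is fixed by six
independent parameters: the sample–detector distance along the direct beam, two
orthogonal detector tilt angles, the two (fractional-pixel) coordinates of the
beam centre, and the X-ray wavelength (equivalently the energy).  This module
parametrises that geometry and provides the exact forward transforms used
everywhere else in the package:

* pixel coordinates -> scattering angle 2theta, azimuth chi, momentum transfer
  q and d-spacing (:func:`pixel_to_angles`, :func:`q_map`, :func:`chi_map`);
* d-spacing -> the predicted Debye-Scherrer conic on the detector
  (:func:`predict_ring`), in closed form from the cone-plane intersection.

Conventions (declared once, used everywhere including the synthetic generator):

* Pixel indices are 0-based; the point (0.0, 0.0) is the **centre** of the
  corner pixel.  "fast" is the second array axis of an image, "slow" the first,
  i.e. ``image[slow, fast]``.
* Lab frame: the direct beam runs along +z; +x is the lab horizontal axis and
  +y the lab vertical axis.  The untilted detector has its fast axis along +x
  and its slow axis along +y.
* Detector pose: the plane is first rotated by ``tilt_pitch`` about the lab
  horizontal (x) axis, then by ``tilt_yaw`` about the lab vertical (y) axis,
  then positioned so the direct beam pierces it at the beam-centre pixel at the
  stated distance.
* Azimuth chi is measured in the lab x-y plane: chi = 0 along +fast (+x),
  counter-clockwise as seen from the sample, range (-180, 180] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DegenerateConic, GeometryError, UnreachableReflection

#: hc in keV * Angstrom (CODATA); energy_keV * wavelength_A = HC_KEV_ANGSTROM.
HC_KEV_ANGSTROM = 12.398419843320026

_PARAM_NAMES = (
    "distance",
    "beam_centre_fast",
    "beam_centre_slow",
    "tilt_pitch",
    "tilt_yaw",
    "wavelength",
)


@dataclass(frozen=True)
class DetectorSpec:
    """Static description of a flat detector.

    Parameters
    ----------
    n_slow, n_fast:
        Pixel counts along the slow (first) and fast (second) array axes.
    pixel_size_slow, pixel_size_fast:
        Pixel pitch in mm along each axis.
    static_mask:
        Optional boolean array of shape ``(n_slow, n_fast)``; ``True`` marks
        pixels that are always excluded (module gaps, dead pixels).
    saturation:
        Full-well / saturation count value; used by the synthetic generator as
        the sentinel for gap pixels so that threshold masking catches them.
    """

    n_slow: int
    n_fast: int
    pixel_size_slow: float
    pixel_size_fast: float
    static_mask: Optional[np.ndarray] = None
    saturation: float = float(2**20)

    def __post_init__(self):
        if self.n_slow < 16 or self.n_fast < 16:
            raise GeometryError("detector pixel counts must be >= 16")
        if self.pixel_size_slow <= 0 or self.pixel_size_fast <= 0:
            raise GeometryError("pixel sizes must be positive")
        if self.static_mask is not None:
            m = np.asarray(self.static_mask, dtype=bool)
            if m.shape != (self.n_slow, self.n_fast):
                raise GeometryError(
                    f"static_mask shape {m.shape} != detector shape {(self.n_slow, self.n_fast)}"
                )
            object.__setattr__(self, "static_mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_slow, self.n_fast)

    def mask_array(self) -> np.ndarray:
        """Boolean static mask, all-False if none was given."""
        if self.static_mask is None:
            return np.zeros(self.shape, dtype=bool)
        return self.static_mask.copy()


@dataclass
class DiffractionGeometry:
    """The six calibration parameters plus the detector description.

    ``distance`` (mm) is measured from the sample to the point where the direct
    beam pierces the detector, ``beam_centre_fast/slow`` are fractional pixel
    coordinates of that point, tilts are in degrees and ``wavelength`` in
    Angstrom.  The wavelength is the stored quantity; the photon energy is
    derived through ``E[keV] * lambda[A] = 12.3984...``.
    """

    distance: float
    beam_centre_fast: float
    beam_centre_slow: float
    tilt_pitch: float
    tilt_yaw: float
    wavelength: float
    detector: DetectorSpec = field(repr=False)

    def __post_init__(self):
        if not np.isfinite(self.distance) or self.distance <= 0:
            raise GeometryError("distance must be positive and finite")
        if not np.isfinite(self.wavelength) or self.wavelength <= 0:
            raise GeometryError("wavelength must be positive and finite")
        if abs(self.tilt_pitch) >= 90 or abs(self.tilt_yaw) >= 90:
            raise GeometryError("|tilt| must be < 90 degrees")

    # --- energy/wavelength duality -------------------------------------
    @property
    def energy_kev(self) -> float:
        return HC_KEV_ANGSTROM / self.wavelength

    @energy_kev.setter
    def energy_kev(self, value: float):
        if value <= 0:
            raise GeometryError("energy must be positive")
        self.wavelength = HC_KEV_ANGSTROM / value

    @classmethod
    def from_energy(cls, energy_kev: float, **kwargs) -> "DiffractionGeometry":
        return cls(wavelength=HC_KEV_ANGSTROM / energy_kev, **kwargs)

    # --- pose -----------------------------------------------------------
    def rotation(self) -> np.ndarray:
        """Detector-plane rotation: pitch about lab x, then yaw about lab y."""
        p = np.deg2rad(self.tilt_pitch)
        y = np.deg2rad(self.tilt_yaw)
        rx = np.array(
            [[1, 0, 0], [0, np.cos(p), -np.sin(p)], [0, np.sin(p), np.cos(p)]]
        )
        ry = np.array(
            [[np.cos(y), 0, np.sin(y)], [0, 1, 0], [-np.sin(y), 0, np.cos(y)]]
        )
        return ry @ rx

    def frame_vectors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(origin, f, s): beam-piercing point in mm and the per-pixel step
        vectors of the fast and slow axes in the lab frame (mm/pixel)."""
        r = self.rotation()
        f = r @ np.array([1.0, 0.0, 0.0]) * self.detector.pixel_size_fast
        s = r @ np.array([0.0, 1.0, 0.0]) * self.detector.pixel_size_slow
        origin = np.array([0.0, 0.0, self.distance])
        return origin, f, s

    def lab_positions(self, fast, slow) -> np.ndarray:
        """Lab-frame positions (mm) of (fractional) pixel coordinates; shape (..., 3)."""
        fast = np.asarray(fast, dtype=float)
        slow = np.asarray(slow, dtype=float)
        origin, f, s = self.frame_vectors()
        df = fast - self.beam_centre_fast
        ds = slow - self.beam_centre_slow
        return origin + df[..., None] * f + ds[..., None] * s

    def replace(self, **kwargs) -> "DiffractionGeometry":
        return replace(self, **kwargs)

    def parameter_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _PARAM_NAMES], dtype=float)

    @classmethod
    def from_parameter_vector(cls, vec, detector: DetectorSpec) -> "DiffractionGeometry":
        return cls(*(float(v) for v in vec), detector=detector)


@dataclass
class AngularCoords:
    """Angular coordinates of detector points: 2theta/chi in degrees, q in 1/A, d in A."""

    two_theta: np.ndarray
    chi: np.ndarray
    q: np.ndarray
    d: np.ndarray


@dataclass
class Conic:
    """An ellipse on the detector in pixel coordinates.

    ``orientation`` is the angle (degrees, in [0, 180)) of the semi-major axis
    measured from the +fast axis towards the +slow axis.
    """

    centre_fast: float
    centre_slow: float
    semi_major: float
    semi_minor: float
    orientation: float

    def __post_init__(self):
        if not (self.semi_major >= self.semi_minor > 0):
            raise DegenerateConic("require semi_major >= semi_minor > 0")

    def sample(self, n: int = 360, t=None) -> tuple[np.ndarray, np.ndarray]:
        """(fast, slow) coordinates of ``n`` points on the ellipse (or at
        parametric angles ``t`` in radians)."""
        if t is None:
            t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        t = np.asarray(t, dtype=float)
        phi = np.deg2rad(self.orientation)
        x = self.semi_major * np.cos(t)
        y = self.semi_minor * np.sin(t)
        fast = self.centre_fast + x * np.cos(phi) - y * np.sin(phi)
        slow = self.centre_slow + x * np.sin(phi) + y * np.cos(phi)
        return fast, slow


def pixel_to_angles(geom: DiffractionGeometry, fast, slow) -> AngularCoords:
    """Angular coordinates of the rays from the sample through pixel centres.

    Vectorized over arrays of (fractional, possibly off-detector) pixel
    coordinates.  At the beam centre 2theta = 0, q = 0 and d is +inf.
    """
    p = geom.lab_positions(fast, slow)
    length = np.sqrt((p * p).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_tth = np.clip(p[..., 2] / length, -1.0, 1.0)
    tth = np.arccos(cos_tth)
    chi = np.degrees(np.arctan2(p[..., 1], p[..., 0]))
    q = 4.0 * np.pi * np.sin(tth / 2.0) / geom.wavelength
    with np.errstate(divide="ignore"):
        d = np.where(q > 0, 2.0 * np.pi / np.where(q > 0, q, 1.0), np.inf)
    return AngularCoords(two_theta=np.degrees(tth), chi=chi, q=q, d=d)


def _pixel_grids(detector_shape) -> tuple[np.ndarray, np.ndarray]:
    n_slow, n_fast = detector_shape
    slow, fast = np.indices((n_slow, n_fast), dtype=float)
    return fast, slow


def q_map(geom: DiffractionGeometry, detector_shape=None) -> np.ndarray:
    """Per-pixel momentum-transfer grid (1/A) over the detector."""
    shape = detector_shape or geom.detector.shape
    fast, slow = _pixel_grids(shape)
    return pixel_to_angles(geom, fast, slow).q


def chi_map(geom: DiffractionGeometry, detector_shape=None) -> np.ndarray:
    """Per-pixel azimuth grid (degrees in (-180, 180])."""
    shape = detector_shape or geom.detector.shape
    fast, slow = _pixel_grids(shape)
    return pixel_to_angles(geom, fast, slow).chi


def two_theta_map(geom: DiffractionGeometry, detector_shape=None) -> np.ndarray:
    """Per-pixel scattering-angle grid (degrees)."""
    shape = detector_shape or geom.detector.shape
    fast, slow = _pixel_grids(shape)
    return pixel_to_angles(geom, fast, slow).two_theta


def ellipse_from_conic_coefficients(a, b, c, d, e, f) -> Conic:
    """Geometric ellipse parameters from general conic coefficients.

    The conic is ``a x^2 + b x y + c y^2 + d x + e y + f = 0`` with x along
    fast, y along slow (pixels).  Raises :class:`DegenerateConic` if the conic
    is not a real ellipse.
    """
    disc = b * b - 4 * a * c
    if not np.isfinite(disc) or disc >= 0:
        raise DegenerateConic("conic is not an ellipse (discriminant >= 0)")
    m = np.array([[a, b / 2.0], [b / 2.0, c]])
    centre = np.linalg.solve(2.0 * m, [-d, -e])
    x0, y0 = centre
    g = a * x0 * x0 + b * x0 * y0 + c * y0 * y0 + d * x0 + e * y0 + f
    evals, evecs = np.linalg.eigh(m)
    with np.errstate(invalid="ignore", divide="ignore"):
        axes_sq = -g / evals
    if np.any(axes_sq <= 0) or not np.all(np.isfinite(axes_sq)):
        raise DegenerateConic("conic has no real ellipse (imaginary axes)")
    axes = np.sqrt(axes_sq)
    i_major = int(np.argmax(axes))
    vec = evecs[:, i_major]
    orientation = np.degrees(np.arctan2(vec[1], vec[0])) % 180.0
    return Conic(
        centre_fast=float(x0),
        centre_slow=float(y0),
        semi_major=float(axes[i_major]),
        semi_minor=float(axes[1 - i_major]),
        orientation=float(orientation),
    )


def predict_ring(geom: DiffractionGeometry, d_spacing: float) -> Conic:
    """Predicted Debye-Scherrer conic for a d-spacing, in pixel coordinates.

    The powder ring is the intersection of the scattering cone of half-opening
    2theta = 2 arcsin(lambda / 2d) about the direct beam with the detector
    plane, computed in closed form.  For zero tilt it degenerates to a circle
    of radius ``distance * tan(2theta)`` centred at the beam centre.

    Raises
    ------
    UnreachableReflection
        If ``lambda >= 2 d`` (Bragg condition unsatisfiable) or the cone does
        not intersect the detector plane in an ellipse (ring never closes).
    """
    lam = geom.wavelength
    if lam >= 2.0 * d_spacing:
        raise UnreachableReflection(
            f"wavelength {lam} A >= 2 d = {2 * d_spacing} A: reflection unreachable"
        )
    tth = 2.0 * np.arcsin(lam / (2.0 * d_spacing))
    t2 = np.tan(tth) ** 2
    origin, fvec, svec = geom.frame_vectors()

    # Cone x^2 + y^2 - tan^2(2theta) z^2 = 0; bilinear form with diag(1,1,-t2).
    def quad(u, v):
        return u[0] * v[0] + u[1] * v[1] - t2 * u[2] * v[2]

    a = quad(fvec, fvec)
    b = 2.0 * quad(fvec, svec)
    c = quad(svec, svec)
    d_ = 2.0 * quad(fvec, origin)
    e = 2.0 * quad(svec, origin)
    f = quad(origin, origin)
    try:
        conic = ellipse_from_conic_coefficients(a, b, c, d_, e, f)
    except DegenerateConic as exc:
        raise UnreachableReflection(
            f"ring at 2theta = {np.degrees(tth):.3f} deg does not close on the detector plane"
        ) from exc
    # Conic coefficients above are in pixel offsets from the beam centre.
    conic.centre_fast += geom.beam_centre_fast
    conic.centre_slow += geom.beam_centre_slow
    return conic
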