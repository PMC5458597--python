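"""Synthetic fixtures: calibrant ring images, distance series, peak-shift
series and oriented-scatter grid scans.

The generators define the study conditions for every test in the package.
Ring profiles are Gaussian in q (not in radius), which makes the calibration
and integration oracles exact in q-space; gap pixels carry the detector
saturation value as sentinel so threshold masking exercises the hot/overexposed
path.  Everything is bit-reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union
import warnings

import numpy as np

from .calibrant import Calibrant, ring_positions
from .geometry import DetectorSpec, DiffractionGeometry, q_map, chi_map
from .reduce import Frame, polarization_factor, solid_angle_factor

#: defaults chosen for a peak signal-to-noise ratio well above 30 under
#: Poisson statistics (amplitude / sqrt(amplitude + background) ~ 44).
DEFAULT_AMPLITUDE = 2000.0
DEFAULT_BACKGROUND = 100.0
DEFAULT_RING_WIDTH_Q = 0.01


@dataclass
class RingRenderSpec:
    """Recipe for a calibrant ring image under an arbitrary geometry.

    ``background`` is either a constant (counts) or a sequence of polynomial
    coefficients in q (ascending powers).  ``apply_inverse_corrections``
    divides the pattern by the solid-angle (and, if ``polarization_fraction``
    is set, polarization) correction factors so that applying the corrections
    of :mod:`powderchain.reduce` recovers the ideal pattern.
    """

    geometry: DiffractionGeometry
    calibrant: Calibrant
    ring_amplitudes: Union[float, Sequence[float]] = DEFAULT_AMPLITUDE
    ring_width_q: float = DEFAULT_RING_WIDTH_Q
    background: Union[float, Sequence[float]] = DEFAULT_BACKGROUND
    noise: str = "none"  # none | poisson
    seed: int = 0
    apply_inverse_corrections: bool = False
    polarization_fraction: Optional[float] = None
    max_rings: Optional[int] = None

    def __post_init__(self):
        if self.ring_width_q <= 0:
            raise ValueError("ring_width_q must be positive")
        amps = np.atleast_1d(np.asarray(self.ring_amplitudes, dtype=float))
        if np.any(amps < 0):
            raise ValueError("ring amplitudes must be >= 0")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")


def _background_map(background, qmap):
    coeffs = np.atleast_1d(np.asarray(background, dtype=float))
    if coeffs.size == 1:
        return np.full(qmap.shape, float(coeffs[0]))
    return np.polynomial.polynomial.polyval(qmap, coeffs)


def reachable_rings(spec: RingRenderSpec) -> list[tuple[float, float, float]]:
    """(d, q, 2theta) of calibrant rings reachable on this detector."""
    geom = spec.geometry
    qm = q_map(geom)
    q_max = float(np.nanmax(qm))
    rings = [r for r in ring_positions(spec.calibrant, geom.wavelength) if r[1] <= q_max]
    if spec.max_rings is not None:
        rings = rings[: spec.max_rings]
    return rings


def render_calibration_image(spec: RingRenderSpec) -> Frame:
    """Render a calibrant powder pattern under the given geometry.

    Per-pixel intensity is background plus a sum of rings Gaussian in q:
    ``sum_k A_k exp(-(q_pix - q_k)^2 / (2 sigma_q^2))``.  Poisson noise is
    applied last with the stated seed; static-mask pixels are set to the
    detector saturation sentinel and masked.
    """
    geom = spec.geometry
    qm = q_map(geom)
    rings = reachable_rings(spec)
    if not rings:
        warnings.warn("no calibrant ring reachable on the detector; background only")
    amps = np.atleast_1d(np.asarray(spec.ring_amplitudes, dtype=float))
    if amps.size == 1 and len(rings) > 1:
        amps = np.full(len(rings), amps[0])
    if len(rings) and amps.size < len(rings):
        raise ValueError("ring_amplitudes shorter than number of reachable rings")

    img = _background_map(spec.background, qm)
    s2 = 2.0 * spec.ring_width_q**2
    for (d, q_k, _), a_k in zip(rings, amps):
        img = img + a_k * np.exp(-((qm - q_k) ** 2) / s2)

    if spec.apply_inverse_corrections:
        img = img / solid_angle_factor(geom)
        if spec.polarization_fraction is not None:
            img = img * polarization_factor(geom, spec.polarization_fraction)

    if spec.noise == "poisson":
        rng = np.random.default_rng(spec.seed)
        img = rng.poisson(np.clip(img, 0, None)).astype(float)

    mask = geom.detector.mask_array()
    img = np.where(mask, geom.detector.saturation, img)
    return Frame(counts=img, mask=mask, metadata={"synthetic": True, "seed": spec.seed})


def render_distance_series(
    spec: RingRenderSpec, distance_increments: Sequence[float]
) -> list[Frame]:
    """One image per distance increment; geometry identical except distance.

    Frame i is rendered at distance ``D0 + increments[i]``; the beam centre
    and tilts are shared across the series (no drift).
    """
    frames = []
    for i, delta in enumerate(distance_increments):
        dist = spec.geometry.distance + float(delta)
        if dist <= 0:
            raise ValueError(f"increment {delta} drives distance non-positive")
        geom_i = spec.geometry.replace(distance=dist)
        spec_i = RingRenderSpec(
            geometry=geom_i,
            calibrant=spec.calibrant,
            ring_amplitudes=spec.ring_amplitudes,
            ring_width_q=spec.ring_width_q,
            background=spec.background,
            noise=spec.noise,
            seed=spec.seed + i,
            apply_inverse_corrections=spec.apply_inverse_corrections,
            polarization_fraction=spec.polarization_fraction,
            max_rings=spec.max_rings,
        )
        frame = render_calibration_image(spec_i)
        frame.metadata["distance_increment"] = float(delta)
        frames.append(frame)
    return frames


def render_peak_shift_series(
    n_frames: int,
    centre_trajectory: Sequence[float],
    fwhm_trajectory: Sequence[float],
    amplitude: float = 1000.0,
    background: tuple[float, float] = (50.0, 5.0),
    axis_range: tuple[float, float] = (2.0, 8.0),
    n_points: int = 400,
    noise: str = "none",
    seed: int = 0,
):
    """Series of 1D profiles with a drifting Gaussian peak on a linear baseline.

    Returns ``(profiles, axis, truth)`` where ``profiles`` has shape
    ``(n_frames, n_points)`` and ``truth`` records the generating centre and
    FWHM trajectories.  ``FWHM = 2 sqrt(2 ln 2) sigma`` throughout.
    """
    centre = np.asarray(centre_trajectory, dtype=float)
    fwhm = np.asarray(fwhm_trajectory, dtype=float)
    if centre.size != n_frames or fwhm.size != n_frames:
        raise ValueError("trajectories must have length n_frames")
    axis = np.linspace(axis_range[0], axis_range[1], n_points)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    base = background[0] + background[1] * (axis - axis[0])
    profiles = base[None, :] + amplitude * np.exp(
        -((axis[None, :] - centre[:, None]) ** 2) / (2.0 * sigma[:, None] ** 2)
    )
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        profiles = rng.poisson(np.clip(profiles, 0, None)).astype(float)
    elif noise != "none":
        raise ValueError("noise must be 'none' or 'poisson'")
    truth = {"centre": centre, "fwhm": fwhm, "amplitude": amplitude}
    return profiles, axis, truth


@dataclass
class OrientedScanSpec:
    """Recipe for a 2D grid scan of frames with azimuthally oriented scatter.

    Per cell the in-band intensity follows
    ``I(chi) = iso + aniso * cos^2(chi - direction)``.
    """

    grid_shape: tuple[int, int]
    iso_amplitude: float = 200.0
    aniso_amplitude: float = 400.0
    direction_field: Optional[np.ndarray] = None  # degrees per cell
    q_band: tuple[float, float] = (1.0, 2.0)
    background: float = 5.0
    noise: str = "none"
    seed: int = 0

    def __post_init__(self):
        if self.iso_amplitude < 0 or self.aniso_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if not self.q_band[0] < self.q_band[1]:
            raise ValueError("require q_lo < q_hi")
        rows, cols = self.grid_shape
        if self.direction_field is None:
            rng = np.random.default_rng(self.seed)
            self.direction_field = rng.uniform(-90.0, 90.0, size=(rows, cols))
        else:
            self.direction_field = np.asarray(self.direction_field, dtype=float)
            if self.direction_field.shape != (rows, cols):
                raise ValueError("direction_field shape must match grid_shape")


def render_oriented_grid_scan(spec: OrientedScanSpec, geometry: DiffractionGeometry):
    """Rank-4 stack (rows, cols, slow, fast) of oriented-scatter frames.

    Returns ``(data, stage_axes, truth)``: the stack, two stage-axis
    coordinate arrays in mm, and the generating ground truth (direction field
    and the analytic degree of orientation ``aniso/2 / (iso + aniso/2)`` of
    the in-band signal).
    """
    rows, cols = spec.grid_shape
    qm = q_map(geometry)
    cm = np.deg2rad(chi_map(geometry))
    in_band = (qm >= spec.q_band[0]) & (qm <= spec.q_band[1])
    data = np.empty((rows, cols) + geometry.detector.shape)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(rows * cols)
    for r in range(rows):
        for c in range(cols):
            direction = np.deg2rad(spec.direction_field[r, c])
            cell = np.full(geometry.detector.shape, spec.background)
            cell = cell + in_band * (
                spec.iso_amplitude
                + spec.aniso_amplitude * np.cos(cm - direction) ** 2
            )
            if spec.noise == "poisson":
                rng = np.random.default_rng(children[r * cols + c])
                cell = rng.poisson(np.clip(cell, 0, None)).astype(float)
            data[r, c] = cell
    stage_y = np.arange(rows) * 0.1  # mm
    stage_x = np.arange(cols) * 0.1
    aniso_mean = spec.aniso_amplitude / 2.0
    truth = {
        "direction": spec.direction_field.copy(),
        "degree": aniso_mean / (spec.iso_amplitude + aniso_mean)
        if (spec.iso_amplitude + aniso_mean) > 0
        else 0.0,
        "q_band": spec.q_band,
    }
    return data, (stage_y, stage_x), truth
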