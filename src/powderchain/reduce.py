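"""Per-frame reduction operations.

Implements the individual processing steps applied to raw detector frames:
threshold masking, Poisson error inference, solid-angle and polarization
corrections, normalisation by a reference intensity, dynamic background
subtraction, cake remapping onto (azimuth, radial) axes and azimuthal
integration with pixel splitting and full error propagation.

Binning statistic is the weighted mean (flat fields stay flat); the per-bin
weight sums are retained in ``bin_counts``/``weights`` so that plain sums are
recoverable.  Pixel splitting ``"bbox"`` approximates a pixel's footprint by
its bounding interval in the radial (and, for cakes, azimuthal) coordinate
computed from the four pixel corners; empty bins are flagged with NaN, never
zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .errors import ReductionError
from .geometry import DiffractionGeometry, pixel_to_angles

RADIAL_UNITS = ("q", "2theta", "d")


@dataclass
class Frame:
    """A 2D detector image with optional error map, mask and metadata.

    ``mask`` is True for excluded pixels; masked pixels never contribute to
    any reduction.  ``metadata`` carries monitor readings and frame axes.
    """

    counts: np.ndarray
    errors: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("Frame counts must be 2D")
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape mismatch")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.counts.shape:
                raise ValueError("errors shape mismatch")
            if np.any(self.errors[~self.mask] < 0):
                raise ValueError("errors must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def copy(self) -> "Frame":
        return Frame(
            counts=self.counts.copy(),
            errors=None if self.errors is None else self.errors.copy(),
            mask=self.mask.copy(),
            metadata=dict(self.metadata),
        )


@dataclass
class RadialProfile:
    """1D reduced pattern: intensity vs a radial coordinate, with errors.

    ``bin_counts`` holds the total contributing weight per bin; empty bins
    carry NaN intensity and zero weight.
    """

    radial_unit: str
    bin_centres: np.ndarray
    intensity: np.ndarray
    errors: Optional[np.ndarray] = None
    bin_counts: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.radial_unit not in RADIAL_UNITS:
            raise ValueError(f"radial_unit must be one of {RADIAL_UNITS}")
        steps = np.diff(self.bin_centres)
        if steps.size and not (np.all(steps > 0) or np.all(steps < 0)):
            raise ValueError("bin_centres must be strictly monotone")

    @property
    def valid(self) -> np.ndarray:
        if self.bin_counts is not None:
            return self.bin_counts > 0
        return np.isfinite(self.intensity)

    def copy(self) -> "RadialProfile":
        return RadialProfile(
            radial_unit=self.radial_unit,
            bin_centres=self.bin_centres.copy(),
            intensity=self.intensity.copy(),
            errors=None if self.errors is None else self.errors.copy(),
            bin_counts=None if self.bin_counts is None else self.bin_counts.copy(),
            metadata=dict(self.metadata),
        )


@dataclass
class CakeGrid:
    """2D azimuth x radial regrid of a frame (weighted-mean statistic)."""

    azimuth_centres: np.ndarray  # degrees
    radial_centres: np.ndarray
    radial_unit: str
    intensity: np.ndarray  # (n_azimuthal, n_radial)
    errors: Optional[np.ndarray]
    weights: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        return self.weights > 0


# ---------------------------------------------------------------------------
# elementwise corrections
# ---------------------------------------------------------------------------


def threshold_mask(frame: Frame, low: float, high: float) -> Frame:
    """Mask pixels with counts below ``low`` or above ``high`` (hot/overexposed)."""
    if not low < high:
        raise ValueError("require low < high")
    out = frame.copy()
    bad = (out.counts < low) | (out.counts > high)
    out.mask |= bad
    if out.mask.all():
        raise ReductionError("threshold mask excluded every pixel")
    return out


def estimate_errors(frame: Frame, model: str = "poisson", gain: float = 1.0) -> Frame:
    """Infer per-pixel count errors; overwrites any existing error map.

    Poisson model with a one-photon floor: ``sigma = gain * sqrt(max(counts /
    gain, 1))``, i.e. counting statistics on the photon number for a detector
    with ``gain`` counts per photon.
    """
    if model != "poisson":
        raise ValueError(f"unknown error model {model!r}")
    if gain <= 0:
        raise ValueError("gain must be positive")
    out = frame.copy()
    unmasked = ~out.mask
    if np.any(out.counts[unmasked] < 0):
        raise ReductionError("negative counts on unmasked pixels; mask or offset first")
    photons = np.maximum(out.counts / gain, 1.0)
    out.errors = gain * np.sqrt(photons)
    return out


def solid_angle_factor(geom: DiffractionGeometry, detector_shape=None) -> np.ndarray:
    """Multiplicative solid-angle correction factor per pixel.

    Each pixel subtends Omega = A cos(alpha) / L^2 (alpha the ray-normal
    incidence angle, L the sample-pixel distance); the factor Omega_0 /
    Omega normalises to 1 at the beam-centre pixel.  For an untilted detector
    it reduces to 1 / cos^3(2theta).
    """
    shape = detector_shape or geom.detector.shape
    slow, fast = np.indices(shape, dtype=float)
    p = geom.lab_positions(fast, slow)
    normal = geom.rotation() @ np.array([0.0, 0.0, 1.0])
    l2 = (p * p).sum(axis=-1)
    cos_alpha = np.abs(p @ normal) / np.sqrt(l2)
    omega = cos_alpha / l2
    # beam-centre pixel: L = distance, cos(alpha) follows from the pose
    p0 = geom.lab_positions(geom.beam_centre_fast, geom.beam_centre_slow)
    l0sq = float(p0 @ p0)
    omega0 = abs(float(p0 @ normal)) / np.sqrt(l0sq) / l0sq
    return omega0 / omega


def correct_solid_angle(frame: Frame, geom: DiffractionGeometry) -> Frame:
    """Apply the solid-angle correction (counts and errors multiplied)."""
    factor = solid_angle_factor(geom, frame.shape)
    out = frame.copy()
    out.counts *= factor
    if out.errors is not None:
        out.errors *= factor
    return out


def kahn_polarization(two_theta_deg, chi_deg, polarization_fraction: float):
    """Kahn-convention polarization factor P(2theta, chi).

    ``P = 1/2 (1 + cos^2(2theta) - xi cos(2 chi) sin^2(2theta))`` with the
    polarization fraction xi in [-1, 1]; vectorized over angle arrays.
    """
    if not -1.0 <= polarization_fraction <= 1.0:
        raise ValueError("polarization fraction must be in [-1, 1]")
    tth = np.deg2rad(np.asarray(two_theta_deg, dtype=float))
    chi2 = np.deg2rad(2.0 * np.asarray(chi_deg, dtype=float))
    return 0.5 * (
        1.0 + np.cos(tth) ** 2 - polarization_fraction * np.cos(chi2) * np.sin(tth) ** 2
    )


def polarization_factor(
    geom: DiffractionGeometry, polarization_fraction: float, detector_shape=None
) -> np.ndarray:
    """Per-pixel Kahn polarization factor over the detector."""
    shape = detector_shape or geom.detector.shape
    slow, fast = np.indices(shape, dtype=float)
    ang = pixel_to_angles(geom, fast, slow)
    return kahn_polarization(ang.two_theta, ang.chi, polarization_fraction)


def correct_polarization(
    frame: Frame, geom: DiffractionGeometry, polarization_fraction: float = 0.0
) -> Frame:
    """Divide counts/errors by the polarization factor; mask singular pixels."""
    p = polarization_factor(geom, polarization_fraction, frame.shape)
    out = frame.copy()
    singular = p < 1e-10
    safe = np.where(singular, 1.0, p)
    out.counts /= safe
    if out.errors is not None:
        out.errors /= safe
    out.mask |= singular
    return out


def divide(frame: Frame, by: Union[float, str, Frame]) -> Frame:
    """Normalise by a scalar, a metadata key, or a reference frame.

    Frame-by-frame division propagates relative errors in quadrature when the
    reference carries its own error map.
    """
    out = frame.copy()
    if isinstance(by, Frame):
        if by.counts.shape != out.counts.shape:
            raise ValueError("reference frame shape mismatch")
        denom = by.counts
        unmasked = ~(out.mask | by.mask)
        if np.any(denom[unmasked] == 0):
            raise ReductionError("division by zero on unmasked reference pixels")
        safe = np.where(denom == 0, 1.0, denom)
        ratio = out.counts / safe
        if out.errors is not None or by.errors is not None:
            sa = out.errors if out.errors is not None else np.zeros_like(out.counts)
            sb = by.errors if by.errors is not None else np.zeros_like(out.counts)
            out.errors = np.sqrt((sa / safe) ** 2 + (out.counts * sb / safe**2) ** 2)
        out.counts = ratio
        out.mask |= by.mask
        return out
    if isinstance(by, str):
        if by not in out.metadata:
            raise ReductionError(f"metadata key {by!r} not present on frame")
        value = float(out.metadata[by])
    else:
        value = float(by)
    if value == 0:
        raise ReductionError("division by zero")
    out.counts = out.counts / value
    if out.errors is not None:
        out.errors = out.errors / abs(value)
    return out


# ---------------------------------------------------------------------------
# binning: azimuthal integration and cake remapping
# ---------------------------------------------------------------------------


def _radial_map(geom: DiffractionGeometry, shape, radial_unit: str, offset=0.0) -> np.ndarray:
    slow, fast = np.indices(shape, dtype=float)
    if np.ndim(offset):
        fast = fast + offset[0]
        slow = slow + offset[1]
    ang = pixel_to_angles(geom, fast, slow)
    if radial_unit == "q":
        return ang.q
    if radial_unit == "2theta":
        return ang.two_theta
    if radial_unit == "d":
        return ang.d
    raise ValueError(f"radial_unit must be one of {RADIAL_UNITS}")


_CORNER_OFFSETS = [(-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)]


def _corner_extrema(geom, shape, radial_unit):
    """Per-pixel min/max of the radial coordinate over the four pixel corners."""
    rmin = None
    rmax = None
    for off in _CORNER_OFFSETS:
        r = _radial_map(geom, shape, radial_unit, offset=np.array(off))
        rmin = r if rmin is None else np.minimum(rmin, r)
        rmax = r if rmax is None else np.maximum(rmax, r)
    return rmin, rmax


def _bin_index(values, lo, width, n_bins):
    # values are pre-filtered to [lo, hi]; the clip makes the top edge
    # inclusive and absorbs floating-point overshoot at the boundaries
    idx = np.floor((values - lo) / width).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def _accumulate_bbox_1d(lo_frac, hi_frac, values, sigmas, n_bins, sums, esums, wsums):
    """Distribute unit pixel weight over the bins its [lo, hi] footprint overlaps.

    ``lo_frac``/``hi_frac`` are fractional bin coordinates of the footprint
    bounds, already clipped to [0, n_bins]."""
    lo_i = np.floor(lo_frac).astype(np.int64)
    hi_i = np.ceil(hi_frac).astype(np.int64) - 1
    hi_i = np.maximum(hi_i, lo_i)
    span = hi_frac - lo_frac
    degenerate = span <= 0
    max_span = int(np.max(hi_i - lo_i)) if lo_i.size else 0
    for k in range(max_span + 1):
        b = lo_i + k
        active = b <= hi_i
        if not np.any(active):
            break
        seg_lo = np.maximum(lo_frac, b)
        seg_hi = np.minimum(hi_frac, b + 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(degenerate, 1.0, (seg_hi - seg_lo) / np.where(span > 0, span, 1.0))
        w = np.where(active, np.clip(w, 0.0, 1.0), 0.0)
        bb = np.clip(b, 0, n_bins - 1)
        np.add.at(sums, bb, w * values)
        np.add.at(wsums, bb, w)
        if esums is not None:
            np.add.at(esums, bb, (w * sigmas) ** 2)


def integrate_azimuthal(
    frame: Frame,
    geom: DiffractionGeometry,
    n_bins: int,
    radial_unit: str = "q",
    radial_range: Optional[tuple[float, float]] = None,
    azimuth_range: Optional[tuple[float, float]] = None,
    splitting: str = "none",
) -> RadialProfile:
    """Reduce a 2D frame to intensity vs a radial coordinate.

    Equal-width bins over ``radial_range`` (default: the detector's coverage;
    with bbox splitting the coverage of the pixel *corners* so that every
    footprint is fully binned).  ``splitting='none'`` assigns each unmasked
    pixel to the bin of its centre coordinate; ``'bbox'`` spreads each pixel's
    bounding radial interval proportionally over the bins it overlaps.
    Intensity is the weighted mean, errors propagate as
    ``sqrt(sum w^2 sigma^2) / sum w``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if splitting not in ("none", "bbox"):
        raise ValueError("splitting must be 'none' or 'bbox'")
    rmap = _radial_map(geom, frame.shape, radial_unit)
    select = ~frame.mask & np.isfinite(rmap)
    if azimuth_range is not None:
        cmap = _azimuth_map(geom, frame.shape)
        select &= _azimuth_in_range(cmap, azimuth_range)
    if not np.any(select):
        raise ReductionError("empty selection: all pixels masked or out of range")

    if splitting == "bbox":
        rlo_map, rhi_map = _corner_extrema(geom, frame.shape, radial_unit)
        finite = np.isfinite(rlo_map) & np.isfinite(rhi_map)
        select &= finite
        if radial_range is None:
            radial_range = (float(rlo_map[select].min()), float(rhi_map[select].max()))
    elif radial_range is None:
        radial_range = (float(rmap[select].min()), float(rmap[select].max()))
    lo, hi = map(float, radial_range)
    if not hi > lo:
        raise ValueError("radial_range must be increasing")
    width = (hi - lo) / n_bins

    values = frame.counts[select]
    sigmas = frame.errors[select] if frame.errors is not None else None
    sums = np.zeros(n_bins)
    wsums = np.zeros(n_bins)
    esums = np.zeros(n_bins) if sigmas is not None else None

    if splitting == "none":
        r = rmap[select]
        inside = (r >= lo) & (r <= hi)
        idx = _bin_index(r[inside], lo, width, n_bins)
        np.add.at(sums, idx, values[inside])
        np.add.at(wsums, idx, 1.0)
        if esums is not None:
            np.add.at(esums, idx, sigmas[inside] ** 2)
    else:
        lo_frac = np.clip((rlo_map[select] - lo) / width, 0.0, n_bins)
        hi_frac = np.clip((rhi_map[select] - lo) / width, 0.0, n_bins)
        keep = hi_frac > lo_frac
        keep |= (lo_frac == hi_frac) & (lo_frac < n_bins)
        _accumulate_bbox_1d(
            lo_frac[keep],
            hi_frac[keep],
            values[keep],
            sigmas[keep] if sigmas is not None else np.zeros(keep.sum()),
            n_bins,
            sums,
            esums,
            wsums,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(wsums > 0, sums / np.where(wsums > 0, wsums, 1.0), np.nan)
        if esums is not None:
            err = np.where(wsums > 0, np.sqrt(esums) / np.where(wsums > 0, wsums, 1.0), np.nan)
        else:
            err = None
    centres = lo + (np.arange(n_bins) + 0.5) * width
    return RadialProfile(
        radial_unit=radial_unit,
        bin_centres=centres,
        intensity=intensity,
        errors=err,
        bin_counts=wsums,
        metadata={"radial_range": (lo, hi), "splitting": splitting},
    )


def _azimuth_map(geom, shape):
    slow, fast = np.indices(shape, dtype=float)
    return pixel_to_angles(geom, fast, slow).chi


def _azimuth_in_range(chi, azimuth_range):
    lo, hi = azimuth_range
    c = (chi - lo) % 360.0
    return c <= (hi - lo) % 360.0 if (hi - lo) % 360.0 else np.ones_like(chi, bool)


def cake_remap(
    frame: Frame,
    geom: DiffractionGeometry,
    n_radial: int,
    n_azimuthal: int,
    splitting: str = "none",
    radial_unit: str = "q",
    radial_range: Optional[tuple[float, float]] = None,
    azimuth_range: Optional[tuple[float, float]] = None,
) -> CakeGrid:
    """Regrid a frame onto (azimuth, radial) axes by weighted-mean binning.

    Azimuth bins live on (-180, 180] by default; a requested range crossing
    the seam is handled by rotating the azimuth coordinate before binning.
    Collapsing the cake over azimuth with its weights reproduces
    :func:`integrate_azimuthal` for identical binning and splitting.
    """
    if n_radial < 2 or n_azimuthal < 1:
        raise ValueError("need n_radial >= 2 and n_azimuthal >= 1")
    if splitting not in ("none", "bbox"):
        raise ValueError("splitting must be 'none' or 'bbox'")
    rmap = _radial_map(geom, frame.shape, radial_unit)
    cmap = _azimuth_map(geom, frame.shape)
    select = ~frame.mask & np.isfinite(rmap)
    if not np.any(select):
        raise ReductionError("empty selection: all pixels masked")

    if azimuth_range is None:
        az_lo, az_hi = -180.0, 180.0
    else:
        az_lo, az_hi = map(float, azimuth_range)
    # rotate so the requested azimuth window is contiguous starting at az_lo
    shift = az_lo
    span = (az_hi - az_lo) if azimuth_range is not None else 360.0
    if azimuth_range is not None and span <= 0:
        span += 360.0
    crel = (cmap - shift) % 360.0
    az_width = span / n_azimuthal

    if splitting == "bbox":
        rlo_map, rhi_map = _corner_extrema(geom, frame.shape, radial_unit)
        select &= np.isfinite(rlo_map) & np.isfinite(rhi_map)
        if radial_range is None:
            radial_range = (float(rlo_map[select].min()), float(rhi_map[select].max()))
    elif radial_range is None:
        radial_range = (float(rmap[select].min()), float(rmap[select].max()))
    lo, hi = map(float, radial_range)
    width = (hi - lo) / n_radial

    sums = np.zeros((n_azimuthal, n_radial))
    wsums = np.zeros((n_azimuthal, n_radial))
    esums = np.zeros((n_azimuthal, n_radial)) if frame.errors is not None else None

    values = frame.counts[select]
    sigmas = frame.errors[select] if frame.errors is not None else None
    crel_sel = crel[select]
    in_az = crel_sel <= span  # pixels outside a partial window drop out
    if azimuth_range is None:
        in_az = np.ones_like(crel_sel, dtype=bool)

    if splitting == "none":
        r = rmap[select]
        inside = (r >= lo) & (r <= hi) & in_az
        ridx = _bin_index(r[inside], lo, width, n_radial)
        cidx = _bin_index(np.minimum(crel_sel[inside], span), 0.0, az_width, n_azimuthal)
        flat = cidx * n_radial + ridx
        np.add.at(sums.ravel(), flat, values[inside])
        np.add.at(wsums.ravel(), flat, 1.0)
        if esums is not None:
            np.add.at(esums.ravel(), flat, sigmas[inside] ** 2)
    else:
        _cake_bbox_accumulate(
            geom, frame, select, in_az, shift, span, lo, width, az_width,
            n_radial, n_azimuthal, rlo_map, rhi_map, sums, wsums, esums,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.where(wsums > 0, wsums, 1.0)
        intensity = np.where(wsums > 0, sums / safe, np.nan)
        err = np.where(wsums > 0, np.sqrt(esums) / safe, np.nan) if esums is not None else None
    radial_centres = lo + (np.arange(n_radial) + 0.5) * width
    azimuth_centres = shift + (np.arange(n_azimuthal) + 0.5) * az_width
    azimuth_centres = (azimuth_centres + 180.0) % 360.0 - 180.0
    return CakeGrid(
        azimuth_centres=azimuth_centres,
        radial_centres=radial_centres,
        radial_unit=radial_unit,
        intensity=intensity,
        errors=err,
        weights=wsums,
        metadata={"radial_range": (lo, hi), "splitting": splitting,
                  "azimuth_range": (az_lo, az_lo + span)},
    )


def _cake_bbox_accumulate(
    geom, frame, select, in_az, shift, span, lo, width, az_width,
    n_radial, n_azimuthal, rlo_map, rhi_map, sums, wsums, esums,
):
    """2D bbox splitting: outer product of radial and azimuthal overlap fractions."""
    shape = frame.shape
    clo = None
    chi_corners = []
    for off in _CORNER_OFFSETS:
        slow, fast = np.indices(shape, dtype=float)
        ang = pixel_to_angles(geom, fast + off[0], slow + off[1])
        chi_corners.append((ang.chi - shift) % 360.0)
    cc = np.stack(chi_corners)
    # footprints that straddle the wrap point of the rotated azimuth get
    # unwrapped by shifting low corners up by 360
    cmin = cc.min(axis=0)
    cmax = cc.max(axis=0)
    wrapped = (cmax - cmin) > 180.0
    cc_unwrapped = np.where(wrapped[None] & (cc < 180.0), cc + 360.0, cc)
    clo = np.where(wrapped, cc_unwrapped.min(axis=0), cmin)
    chi_hi = np.where(wrapped, cc_unwrapped.max(axis=0), cmax)

    sel = select & in_az_full(in_az, select)
    values = frame.counts[sel]
    sigmas = frame.errors[sel] if frame.errors is not None else np.zeros(values.shape)

    r_lo = np.clip((rlo_map[sel] - lo) / width, 0.0, n_radial)
    r_hi = np.clip((rhi_map[sel] - lo) / width, 0.0, n_radial)
    c_lo = clo[sel] / az_width
    c_hi = chi_hi[sel] / az_width

    r_lo_i = np.floor(r_lo).astype(np.int64)
    r_hi_i = np.maximum(np.ceil(r_hi).astype(np.int64) - 1, r_lo_i)
    c_lo_i = np.floor(c_lo).astype(np.int64)
    c_hi_i = np.maximum(np.ceil(c_hi).astype(np.int64) - 1, c_lo_i)
    r_span = r_hi - r_lo
    c_span = c_hi - c_lo
    max_r = int(np.max(r_hi_i - r_lo_i)) if r_lo_i.size else 0
    max_c = int(np.max(c_hi_i - c_lo_i)) if c_lo_i.size else 0
    for kc in range(max_c + 1):
        bc = c_lo_i + kc
        act_c = bc <= c_hi_i
        seg = np.minimum(c_hi, bc + 1.0) - np.maximum(c_lo, bc)
        with np.errstate(invalid="ignore", divide="ignore"):
            wc = np.where(c_span > 0, seg / np.where(c_span > 0, c_span, 1.0), 1.0)
        wc = np.where(act_c, np.clip(wc, 0.0, 1.0), 0.0)
        bc_mod = np.mod(bc, max(int(round(360.0 / az_width)), n_azimuthal))
        bc_idx = np.clip(bc_mod, 0, n_azimuthal - 1)
        drop = bc_mod > n_azimuthal - 1  # outside a partial azimuth window
        wc = np.where(drop, 0.0, wc)
        for kr in range(max_r + 1):
            br = r_lo_i + kr
            act_r = br <= r_hi_i
            seg_r = np.minimum(r_hi, br + 1.0) - np.maximum(r_lo, br)
            with np.errstate(invalid="ignore", divide="ignore"):
                wr = np.where(r_span > 0, seg_r / np.where(r_span > 0, r_span, 1.0), 1.0)
            wr = np.where(act_r, np.clip(wr, 0.0, 1.0), 0.0)
            w = wc * wr
            if not np.any(w > 0):
                continue
            br_idx = np.clip(br, 0, n_radial - 1)
            flat = bc_idx * n_radial + br_idx
            np.add.at(sums.ravel(), flat, w * values)
            np.add.at(wsums.ravel(), flat, w)
            if esums is not None:
                np.add.at(esums.ravel(), flat, (w * sigmas) ** 2)


def in_az_full(in_az, select):
    """Expand a selected-subset azimuth mask back to the full image shape."""
    full = np.zeros(select.shape, dtype=bool)
    full[select] = in_az
    return full


# ---------------------------------------------------------------------------
# dynamic background subtraction
# ---------------------------------------------------------------------------


def _clipped_envelope(y, err, iterations, clip_factor, window):
    """Iteratively clipped smooth lower envelope of a 1D profile."""
    from scipy.ndimage import uniform_filter1d

    work = y.copy()
    valid = np.isfinite(work)
    if not np.any(valid):
        return np.full_like(y, np.nan)
    # fill gaps by interpolation so smoothing does not propagate NaN
    idx = np.arange(y.size)
    work[~valid] = np.interp(idx[~valid], idx[valid], work[valid])
    local_err = err if err is not None else np.zeros_like(work)
    for _ in range(iterations):
        smooth = uniform_filter1d(work, size=window, mode="nearest")
        above = work > smooth + clip_factor * local_err
        work = np.where(above, smooth, work)
    return uniform_filter1d(work, size=window, mode="nearest")


def subtract_radial_background(
    obj,
    geom: Optional[DiffractionGeometry] = None,
    iterations: int = 30,
    clip_factor: float = 1.5,
    window: Optional[int] = None,
    n_bins: Optional[int] = None,
):
    """Dynamic background subtraction for profiles or frames.

    The background is the iteratively clipped smooth lower envelope of the
    (azimuthally integrated, for frames) radial profile: values above
    ``envelope + clip_factor * local_error`` are replaced by the envelope and
    the smoothing repeated ``iterations`` times.  For frames the 1D background
    is remapped to pixels through the radial coordinate before subtraction.
    Negative results are permitted and errors are left unchanged;
    ``iterations = 0`` is the identity.
    """
    if iterations == 0:
        return obj.copy()
    if isinstance(obj, RadialProfile):
        y = obj.intensity
        # the envelope window must exceed the widest peak to avoid tracking it
        win = window or max(5, y.size // 8)
        bg = _clipped_envelope(y, obj.errors, iterations, clip_factor, win)
        out = obj.copy()
        out.intensity = y - np.where(np.isfinite(y), bg, 0.0)
        return out
    if isinstance(obj, Frame):
        if geom is None:
            raise ValueError("frame background subtraction needs a geometry")
        nb = n_bins or max(min(obj.shape) // 2, 50)
        prof = integrate_azimuthal(obj, geom, n_bins=nb, radial_unit="q")
        win = window or max(5, nb // 8)
        bg = _clipped_envelope(prof.intensity, prof.errors, iterations, clip_factor, win)
        rmap = _radial_map(geom, obj.shape, "q")
        valid = np.isfinite(bg)
        bg_map = np.interp(rmap, prof.bin_centres[valid], bg[valid])
        out = obj.copy()
        out.counts = out.counts - bg_map
        return out
    raise TypeError("expected RadialProfile or Frame")
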