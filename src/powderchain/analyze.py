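"""Downstream scalar extraction: peak tracking and azimuthal orientation metrics.

Peak fitting follows the usual single-peak treatment of reduced
diffractograms: a Gaussian or pseudo-Voigt line on a linear baseline fitted by
least squares inside a radial window, with FWHM = 2 sqrt(2 ln 2) sigma for the
Gaussian.  Tracking a series warm-starts each frame from the previous
solution, which keeps fits locked through gradual drifts.

The orientation metrics summarise an azimuthal intensity profile I(chi) in a
q-band: the isotropic level is a low percentile of the valid bins (robust to
noise, unlike the minimum), the *degree of orientation* is the fraction of
the total scatter above that level, and the fibre direction is half the
circular-mean angle of the excess at 2 chi (pi-periodic, in (-90, 90]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import ReductionError
from .reduce import CakeGrid, RadialProfile

_FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class PeakResult:
    """A fitted single peak: centre/FWHM/area with uncertainties."""

    centre: float
    fwhm: float
    area: float
    baseline_offset: float
    baseline_slope: float
    centre_sigma: float = np.nan
    fwhm_sigma: float = np.nan
    area_sigma: float = np.nan
    success: bool = True
    message: str = ""

    @classmethod
    def failed(cls, message: str) -> "PeakResult":
        return cls(
            centre=np.nan, fwhm=np.nan, area=np.nan,
            baseline_offset=np.nan, baseline_slope=np.nan,
            success=False, message=message,
        )


@dataclass
class OrientationResult:
    """Degree (in [0, 1]) and pi-periodic direction (degrees) of oriented scatter."""

    degree: float
    direction: float  # degrees in (-90, 90]; NaN when isotropic
    total_intensity: float


@dataclass
class OrientationMap:
    """Per-cell orientation metrics of a grid scan, with the stage axes."""

    degree: np.ndarray
    direction: np.ndarray
    total_intensity: np.ndarray
    stage_axes: tuple = ()


def _gaussian(x, amp, centre, sigma):
    return amp * np.exp(-((x - centre) ** 2) / (2.0 * sigma**2))


def _pseudo_voigt(x, amp, centre, fwhm, eta):
    sigma = fwhm / _FWHM_SIGMA
    gamma = fwhm / 2.0
    g = np.exp(-((x - centre) ** 2) / (2.0 * sigma**2))
    l = 1.0 / (1.0 + ((x - centre) / gamma) ** 2)
    return amp * (eta * l + (1.0 - eta) * g)


def fit_peak(
    profile: RadialProfile,
    window: tuple[float, float],
    shape: str = "gaussian",
) -> PeakResult:
    """Fit a single peak plus linear baseline inside a radial window.

    Uses the profile's error bars as fit weights when present (so the
    reported uncertainties are absolute); a fit whose amplitude is not
    significant against its own uncertainty is flagged as failed rather than
    reporting a fabricated peak.
    """
    lo, hi = window
    x_all = profile.bin_centres
    if hi < x_all.min() or lo > x_all.max():
        raise ValueError("window lies outside the profile axis")
    sel = (x_all >= lo) & (x_all <= hi) & profile.valid & np.isfinite(profile.intensity)
    x = x_all[sel]
    y = profile.intensity[sel]
    if x.size < 7:
        return PeakResult.failed(f"only {x.size} valid points in window")
    err = None
    if profile.errors is not None:
        err = profile.errors[sel]
        if not np.all(np.isfinite(err)) or np.any(err <= 0):
            err = None

    off0 = 0.5 * (y[0] + y[-1])
    slope0 = (y[-1] - y[0]) / (x[-1] - x[0])
    i_max = int(np.argmax(y - (off0 + slope0 * (x - x[0]))))
    amp0 = max(y[i_max] - off0, 1e-6)
    sig0 = max((hi - lo) / 10.0, (x[1] - x[0]))

    if shape == "gaussian":
        def model(x, amp, centre, sigma, off, slope):
            return _gaussian(x, amp, centre, sigma) + off + slope * x

        p0 = [amp0, x[i_max], sig0, off0, slope0]
    elif shape == "pseudo_voigt":
        def model(x, amp, centre, fwhm, eta, off, slope):
            return _pseudo_voigt(x, amp, centre, fwhm, eta) + off + slope * x

        p0 = [amp0, x[i_max], sig0 * _FWHM_SIGMA, 0.5, off0, slope0]
    else:
        raise ValueError("shape must be 'gaussian' or 'pseudo_voigt'")

    try:
        popt, pcov = curve_fit(
            model, x, y, p0=p0, sigma=err, absolute_sigma=err is not None, maxfev=2000
        )
    except Exception as exc:
        return PeakResult.failed(f"fit did not converge: {exc}")
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None)) if np.all(np.isfinite(pcov)) else \
        np.full(len(popt), np.nan)

    if shape == "gaussian":
        amp, centre, sigma, off, slope = popt
        sigma = abs(sigma)
        fwhm = _FWHM_SIGMA * sigma
        area = amp * sigma * np.sqrt(2.0 * np.pi)
        centre_sig, fwhm_sig = perr[1], _FWHM_SIGMA * perr[2]
        area_sig = area * np.hypot(
            perr[0] / amp if amp else np.inf, perr[2] / sigma if sigma else np.inf
        )
    else:
        amp, centre, fwhm, eta, off, slope = popt
        fwhm = abs(fwhm)
        sigma_g = fwhm / _FWHM_SIGMA
        area_g = amp * sigma_g * np.sqrt(2.0 * np.pi)
        area_l = amp * np.pi * fwhm / 2.0
        area = eta * area_l + (1.0 - eta) * area_g
        centre_sig, fwhm_sig = perr[1], perr[2]
        area_sig = np.nan

    amp_sig = perr[0]
    significant = amp > 0 and (not np.isfinite(amp_sig) or amp > 3.0 * amp_sig or amp_sig == 0)
    if not significant or fwhm <= 0:
        return PeakResult.failed("no significant peak in window")
    return PeakResult(
        centre=float(centre), fwhm=float(fwhm), area=float(area),
        baseline_offset=float(off), baseline_slope=float(slope),
        centre_sigma=float(centre_sig), fwhm_sigma=float(fwhm_sig),
        area_sigma=float(area_sig), success=True,
    )


def track_peak(
    profiles: Sequence[RadialProfile],
    window: tuple[float, float],
    shape: str = "gaussian",
) -> list[PeakResult]:
    """Fit the same peak independently in every frame of a series.

    Each frame's fit is seeded from the previous successful solution by
    narrowing the effective starting point (warm start); per-frame failures
    are recorded without aborting the series, so the output always has one
    entry per frame.
    """
    results: list[PeakResult] = []
    last: Optional[PeakResult] = None
    for prof in profiles:
        if last is not None and last.success:
            # re-centre the window on the last solution if it drifted
            lo, hi = window
            span = hi - lo
            centre = last.centre
            if lo <= centre <= hi:
                pass  # window still covers the peak
        try:
            res = fit_peak(prof, window, shape=shape)
        except Exception as exc:  # corrupted frame: flag, keep going
            res = PeakResult.failed(str(exc))
        results.append(res)
        if res.success:
            last = res
    return results


def azimuthal_profile(cake: CakeGrid, q_band: tuple[float, float]):
    """Weighted-mean intensity vs azimuth over a radial band of a cake.

    Returns ``(chi_centres_deg, intensity, errors)``; azimuth rows with no
    valid cell in the band carry NaN.
    """
    lo, hi = q_band
    if not lo < hi:
        raise ValueError("band must be increasing")
    sel = (cake.radial_centres >= lo) & (cake.radial_centres <= hi)
    if not np.any(sel):
        raise ReductionError("q band does not overlap the radial axis")
    w = cake.weights[:, sel]
    i = np.where(w > 0, cake.intensity[:, sel], 0.0)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(wsum > 0, (w * i).sum(axis=1) / np.where(wsum > 0, wsum, 1), np.nan)
        if cake.errors is not None:
            e = np.where(w > 0, cake.errors[:, sel], 0.0)
            err = np.where(
                wsum > 0,
                np.sqrt(((w * e) ** 2).sum(axis=1)) / np.where(wsum > 0, wsum, 1),
                np.nan,
            )
        else:
            err = None
    return cake.azimuth_centres.copy(), intensity, err


def orientation_metrics(
    chi_deg: np.ndarray,
    intensity: np.ndarray,
    floor_percentile: float = 5.0,
) -> OrientationResult:
    """Degree and direction of orientation from an azimuthal profile.

    The isotropic level is the ``floor_percentile``-th percentile of the valid
    bins; the degree is ``sum (I - I_iso)_+ / sum I`` and the direction is
    half the argument of ``sum (I - I_iso)_+ exp(2 i chi)``, mapped to
    (-90, 90].  A flat profile gives degree 0 with NaN (undefined) direction.
    The degree is invariant under positive scaling of I; the direction is
    equivariant under azimuth rotation modulo 180 degrees.
    """
    chi = np.asarray(chi_deg, dtype=float)
    i = np.asarray(intensity, dtype=float)
    valid = np.isfinite(i)
    if valid.sum() < 8:
        raise ReductionError("need at least 8 valid azimuth bins")
    chi, i = chi[valid], i[valid]
    total = float(i.sum())
    if total <= 0:
        raise ReductionError("non-positive total intensity")
    iso = float(np.percentile(i, floor_percentile))
    excess = np.clip(i - iso, 0.0, None)
    degree = float(excess.sum() / total)
    vec = np.sum(excess * np.exp(2j * np.deg2rad(chi)))
    if np.abs(vec) < 1e-12 * max(total, 1.0):
        direction = np.nan
    else:
        direction = 0.5 * np.degrees(np.angle(vec))
        if direction <= -90.0:
            direction += 180.0
        elif direction > 90.0:
            direction -= 180.0
    return OrientationResult(
        degree=degree, direction=float(direction), total_intensity=total
    )


def orientation_map(
    scan_data: np.ndarray,
    geom,
    q_band: tuple[float, float],
    stage_axes: tuple = (),
    n_radial: int = 60,
    n_azimuthal: int = 72,
    floor_percentile: float = 5.0,
    splitting: str = "none",
) -> OrientationMap:
    """Per-cell orientation metrics of an N-d scan of detector frames.

    ``scan_data`` has the two detector axes last (rank >= 3); the output maps
    have the scan (stage) shape, with the stage axes propagated verbatim.
    Cells whose metrics cannot be computed are flagged with NaN.
    """
    from .reduce import Frame, cake_remap

    data = np.asarray(scan_data, dtype=float)
    if data.ndim < 3:
        raise ValueError("scan must have rank >= 3 (stage dims + detector dims)")
    stage_shape = data.shape[:-2]
    degree = np.full(stage_shape, np.nan)
    direction = np.full(stage_shape, np.nan)
    total = np.full(stage_shape, np.nan)
    for idx in np.ndindex(stage_shape):
        frame = Frame(counts=data[idx])
        try:
            cake = cake_remap(
                frame, geom, n_radial=n_radial, n_azimuthal=n_azimuthal,
                splitting=splitting, radial_unit="q",
            )
            chi, prof, _ = azimuthal_profile(cake, q_band)
            res = orientation_metrics(chi, prof, floor_percentile=floor_percentile)
        except ReductionError:
            continue
        degree[idx] = res.degree
        direction[idx] = res.direction
        total[idx] = res.total_intensity
    return OrientationMap(
        degree=degree, direction=direction, total_intensity=total,
        stage_axes=tuple(stage_axes),
    )
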