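"""NeXus/HDF5, TIFF and ASCII input/output.

Processed-output layout (versioned; self-consistent rather than claimed
byte-compatible with any other package):

* ``/entry`` (NXentry)
* ``/entry/result`` (NXdata): signal ``data``, ``errors`` dataset, axis
  datasets with an ``axes`` attribute naming them
* ``/entry/intermediate/<n>-<step_name>`` (NXdata) per saved intermediate
* ``/entry/process`` (NXprocess): ``program``, ``version``, ``date``, the
  verbatim chain JSON, the input reference and one sequenced NXnote per step
  holding that step's verbatim parameter serialization

Calibration files store ``/entry/calibration`` with distance (mm),
beam_centre_fast/slow (pixels), tilt_pitch/tilt_yaw (deg), wavelength (A),
uncertainties, calibrant and routine, plus the detector description.

ASCII export: '#'-prefixed header (axis name/unit, provenance one-liner),
then 2 or 3 columns (radial, intensity[, error]); one file per frame with a
zero-padded frame suffix.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional, Sequence

import h5py
import numpy as np

from .errors import FileFormatError

FILE_FORMAT_VERSION = "1"


@dataclass
class Axis:
    """A named per-dimension coordinate array."""

    name: str
    values: np.ndarray
    unit: str = ""


@dataclass
class ScanDataset:
    """An N-d stack of frames, detector axes last.

    ``detector_ndim`` identifies how many trailing dimensions form one frame
    (2 for images, 1 for stored profiles); the leading dimensions are the
    scan (stage) dimensions whose axes propagate onto every output.
    """

    data: np.ndarray
    axes: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    detector_ndim: int = 2

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim < self.detector_ndim:
            raise ValueError("dataset rank smaller than detector_ndim")
        if self.axes and len(self.axes) != self.data.ndim:
            raise ValueError("need one axis per dimension (or none)")
        for ax, n in zip(self.axes, self.data.shape):
            if len(np.asarray(ax.values)) != n:
                raise ValueError(f"axis {ax.name!r} length mismatch")

    @property
    def scan_shape(self) -> tuple:
        return self.data.shape[: self.data.ndim - self.detector_ndim]


def _nx_group(parent, name, nx_class):
    group = parent.create_group(name)
    group.attrs["NX_class"] = nx_class
    return group


def _write_nxdata(entry, name, payload):
    """Write one assembled result dict as an NXdata group."""
    group = _nx_group(entry, name, "NXdata")
    axes = payload.get("axes", [])
    if payload["kind"] == "scalars":
        names = sorted(payload["data"])
        group.attrs["signal"] = names[0] if names else "data"
        for key in names:
            group.create_dataset(key, data=np.asarray(payload["data"][key]))
    else:
        group.attrs["signal"] = "data"
        group.create_dataset("data", data=np.asarray(payload["data"]))
        if payload.get("errors") is not None:
            group.create_dataset("errors", data=np.asarray(payload["errors"]))
        if payload.get("weights") is not None:
            group.create_dataset("weights", data=np.asarray(payload["weights"]))
    axis_names = []
    for ax_name, unit, values in axes:
        safe = ax_name.replace("/", "_")
        ds = group.create_dataset(safe, data=np.asarray(values))
        ds.attrs["units"] = unit
        axis_names.append(safe)
    if axis_names:
        group.attrs["axes"] = axis_names
    group.attrs["kind"] = payload["kind"]
    return group


def write_processed(path: str, result: dict, intermediates: dict, provenance: dict):
    """Write a processed result, saved intermediates and provenance to NeXus."""
    with h5py.File(path, "w") as fh:
        fh.attrs["default"] = "entry"
        entry = _nx_group(fh, "entry", "NXentry")
        entry.attrs["default"] = "result"
        entry.create_dataset("format_version", data=FILE_FORMAT_VERSION)
        _write_nxdata(entry, "result", result)
        if intermediates:
            inter = _nx_group(entry, "intermediate", "NXcollection")
            for key, payload in intermediates.items():
                _write_nxdata(inter, key.replace("/", "_"), payload)
        process = _nx_group(entry, "process", "NXprocess")
        process.create_dataset("program", data=provenance.get("program", "powderchain"))
        process.create_dataset("version", data=provenance.get("version", ""))
        process.create_dataset("date", data=provenance.get(
            "finished", datetime.now(timezone.utc).isoformat()))
        process.create_dataset("chain", data=provenance.get("chain_json", ""))
        process.create_dataset("input", data=str(provenance.get("input", "")))
        process.create_dataset(
            "input_dataset", data=str(provenance.get("input_dataset", ""))
        )
        process.create_dataset(
            "calibration", data=str(provenance.get("calibration", ""))
        )
        if provenance.get("frame_errors"):
            process.create_dataset(
                "frame_errors", data=json.dumps(provenance["frame_errors"])
            )
        for i, step in enumerate(provenance.get("steps", [])):
            note = _nx_group(process, f"{i}_{step['step_name']}".replace("/", "_"),
                             "NXnote")
            note.create_dataset("type", data="application/json")
            note.create_dataset("data", data=json.dumps(step, sort_keys=True))
            note.create_dataset("sequence_index", data=i)


def extract_chain(processed_path: str):
    """Reload the processing chain from a processed output file."""
    from .chain import parse_chain

    with h5py.File(processed_path, "r") as fh:
        try:
            text = fh["entry/process/chain"][()]
        except KeyError as exc:
            raise FileFormatError(
                f"{processed_path}: no chain record at /entry/process/chain"
            ) from exc
    if isinstance(text, bytes):
        text = text.decode()
    return parse_chain(text)


# ---------------------------------------------------------------------------
# dataset reading / writing
# ---------------------------------------------------------------------------


def _find_nxdata(fh) -> Optional[str]:
    found = []

    def visitor(name, obj):
        if isinstance(obj, h5py.Group) and "signal" in obj.attrs:
            found.append(name)

    fh.visititems(visitor)
    # prefer a group literally named data/result over intermediates
    for name in found:
        if name.endswith("result") or name.endswith("data"):
            return name
    return found[0] if found else None


def read_dataset(path: str, dataset_path: Optional[str] = None,
                 detector_ndim: int = 2) -> ScanDataset:
    """Read an HDF5/NeXus (signal + axes attributes honoured) or TIFF stack."""
    lower = path.lower()
    if lower.endswith((".tif", ".tiff")):
        import tifffile

        data = np.asarray(tifffile.imread(path))
        if data.ndim not in (2, 3):
            raise FileFormatError(f"{path}: TIFF rank {data.ndim} unsupported")
        axes = [Axis(f"dim_{i}", np.arange(n), "pixel") for i, n in enumerate(data.shape)]
        return ScanDataset(data=data, axes=axes,
                           metadata={"source_path": path}, detector_ndim=2)
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise FileFormatError(f"{path}: unknown or unreadable format: {exc}") from exc
    with fh:
        if dataset_path is not None:
            node = fh.get(dataset_path)
            if node is None:
                raise FileFormatError(f"{path}: no dataset at {dataset_path!r}")
            if isinstance(node, h5py.Dataset):
                data = node[()]
                axes = [Axis(f"dim_{i}", np.arange(n), "")
                        for i, n in enumerate(data.shape)]
                return ScanDataset(
                    data=data, axes=axes,
                    metadata={"source_path": path, "source_dataset": dataset_path},
                    detector_ndim=detector_ndim,
                )
            group_name = dataset_path
        else:
            group_name = _find_nxdata(fh)
            if group_name is None:
                raise FileFormatError(f"{path}: no NXdata group with a signal found")
        group = fh[group_name]
        signal = group.attrs.get("signal")
        if isinstance(signal, bytes):
            signal = signal.decode()
        if signal is None or signal not in group:
            raise FileFormatError(f"{path}: missing signal dataset in {group_name!r}")
        data = group[signal][()]
        axes = []
        axis_names = group.attrs.get("axes")
        if axis_names is not None:
            for i, ax_name in enumerate(np.atleast_1d(axis_names)):
                if isinstance(ax_name, bytes):
                    ax_name = ax_name.decode()
                if ax_name in group:
                    values = group[ax_name][()]
                    if values.ndim != 1 or (values.size > 1 and
                                            not _monotone(values)):
                        raise FileFormatError(
                            f"{path}: axis {ax_name!r} is not monotone 1D")
                    unit = group[ax_name].attrs.get("units", "")
                    if isinstance(unit, bytes):
                        unit = unit.decode()
                    axes.append(Axis(ax_name, values, unit))
                else:
                    axes.append(Axis(str(ax_name), np.arange(data.shape[i]), ""))
        if len(axes) != data.ndim:
            axes = [Axis(f"dim_{i}", np.arange(n), "")
                    for i, n in enumerate(data.shape)]
        det_nd = int(group.attrs.get("detector_ndim", detector_ndim))
        metadata = {"source_path": path, "source_dataset": group_name}
        # sibling scalar datasets (e.g. monitor readings) become metadata
        for key, node in group.items():
            if key == signal or any(ax.name == key for ax in axes):
                continue
            if isinstance(node, h5py.Dataset) and node.ndim <= len(
                    data.shape) - det_nd:
                metadata[key] = node[()]
        return ScanDataset(data=data, axes=axes, metadata=metadata,
                           detector_ndim=det_nd)


def _monotone(values) -> bool:
    diffs = np.diff(values)
    return bool(np.all(diffs > 0) or np.all(diffs < 0))


def write_dataset(path: str, dataset: ScanDataset):
    """Write a ScanDataset as a minimal NXentry/NXdata file (simulate output)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["default"] = "entry"
        entry = _nx_group(fh, "entry", "NXentry")
        entry.attrs["default"] = "data"
        group = _nx_group(entry, "data", "NXdata")
        group.attrs["signal"] = "data"
        group.attrs["detector_ndim"] = dataset.detector_ndim
        group.create_dataset("data", data=dataset.data)
        names = []
        for ax in dataset.axes:
            ds = group.create_dataset(ax.name, data=np.asarray(ax.values))
            ds.attrs["units"] = ax.unit
            names.append(ax.name)
        if names:
            group.attrs["axes"] = names
        for key, value in dataset.metadata.items():
            if key.startswith("source_"):
                continue
            try:
                group.create_dataset(key, data=value)
            except TypeError:
                group.create_dataset(key, data=str(value))


# ---------------------------------------------------------------------------
# calibration files
# ---------------------------------------------------------------------------

_CAL_FIELDS = (
    "distance",
    "beam_centre_fast",
    "beam_centre_slow",
    "tilt_pitch",
    "tilt_yaw",
    "wavelength",
)

_CAL_UNITS = {
    "distance": "mm",
    "beam_centre_fast": "pixel",
    "beam_centre_slow": "pixel",
    "tilt_pitch": "degrees",
    "tilt_yaw": "degrees",
    "wavelength": "angstrom",
}


def write_calibration(result, path: str):
    """Persist a CalibrationResult with its provenance as a NeXus file."""
    geom = result.geometry
    det = geom.detector
    with h5py.File(path, "w") as fh:
        fh.attrs["default"] = "entry"
        entry = _nx_group(fh, "entry", "NXentry")
        entry.create_dataset("format_version", data=FILE_FORMAT_VERSION)
        cal = _nx_group(entry, "calibration", "NXcollection")
        for name in _CAL_FIELDS:
            ds = cal.create_dataset(name, data=float(getattr(geom, name)))
            ds.attrs["units"] = _CAL_UNITS[name]
        unc = _nx_group(cal, "uncertainties", "NXcollection")
        for name, value in result.uncertainties.items():
            unc.create_dataset(name, data=float(value))
        cal.create_dataset("fixed_parameters",
                           data=json.dumps(list(result.fixed_parameters)))
        cal.create_dataset("residual_rms_q", data=float(result.residual_rms_q))
        cal.create_dataset("n_points", data=int(result.n_points))
        cal.create_dataset("n_rings", data=int(result.n_rings))
        cal.create_dataset("routine", data=result.routine)
        cal.create_dataset("calibrant", data=result.calibrant_name)
        cal.create_dataset("details", data=json.dumps(result.details, default=str))
        detg = _nx_group(cal, "detector", "NXdetector")
        detg.create_dataset("n_slow", data=det.n_slow)
        detg.create_dataset("n_fast", data=det.n_fast)
        detg.create_dataset("pixel_size_slow", data=det.pixel_size_slow)
        detg.create_dataset("pixel_size_fast", data=det.pixel_size_fast)
        detg.create_dataset("saturation", data=det.saturation)
        if det.static_mask is not None:
            detg.create_dataset("static_mask", data=det.static_mask.astype(np.uint8))


def read_calibration(path: str):
    """Load a calibration file written by :func:`write_calibration`."""
    from .calibrate import CalibrationResult
    from .geometry import DetectorSpec, DiffractionGeometry

    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise FileFormatError(f"{path}: not a readable HDF5 file: {exc}") from exc
    with fh:
        if "entry/calibration" not in fh:
            raise FileFormatError(f"{path}: missing /entry/calibration group")
        version = fh["entry/format_version"][()] if "entry/format_version" in fh else b"?"
        if isinstance(version, bytes):
            version = version.decode()
        if version != FILE_FORMAT_VERSION:
            raise FileFormatError(
                f"{path}: format version {version!r} != {FILE_FORMAT_VERSION!r}"
            )
        cal = fh["entry/calibration"]
        values = {}
        for name in _CAL_FIELDS:
            if name not in cal:
                raise FileFormatError(f"{path}: missing field {name!r}")
            values[name] = float(cal[name][()])
        detg = cal["detector"]
        mask = detg["static_mask"][()].astype(bool) if "static_mask" in detg else None
        det = DetectorSpec(
            n_slow=int(detg["n_slow"][()]),
            n_fast=int(detg["n_fast"][()]),
            pixel_size_slow=float(detg["pixel_size_slow"][()]),
            pixel_size_fast=float(detg["pixel_size_fast"][()]),
            static_mask=mask,
            saturation=float(detg["saturation"][()]),
        )
        geom = DiffractionGeometry(detector=det, **values)
        unc = {
            name: float(cal["uncertainties"][name][()])
            for name in cal["uncertainties"]
        }
        fixed = tuple(json.loads(_text(cal["fixed_parameters"][()])))
        return CalibrationResult(
            geometry=geom,
            uncertainties=unc,
            fixed_parameters=fixed,
            residual_rms_q=float(cal["residual_rms_q"][()]),
            n_points=int(cal["n_points"][()]),
            n_rings=int(cal["n_rings"][()]),
            routine=_text(cal["routine"][()]),
            calibrant_name=_text(cal["calibrant"][()]),
            details=json.loads(_text(cal["details"][()])),
        )


def _text(value) -> str:
    return value.decode() if isinstance(value, bytes) else str(value)


# ---------------------------------------------------------------------------
# ASCII export
# ---------------------------------------------------------------------------


def export_ascii(
    radial: np.ndarray,
    intensity: np.ndarray,
    errors: Optional[np.ndarray],
    path: str,
    axis_name: str = "q",
    axis_unit: str = "1/angstrom",
    provenance_line: str = "",
):
    """Write stacked profiles as text, one file per frame.

    ``intensity`` may be 1D (single profile, written to ``path``) or N-d with
    the radial axis last (one file per leading index, zero-padded suffix).
    """
    intensity = np.asarray(intensity)
    if intensity.ndim == 1:
        _write_xy(path, radial, intensity, errors, axis_name, axis_unit,
                  provenance_line)
        return [path]
    base, ext = os.path.splitext(path)
    ext = ext or ".dat"
    lead_shape = intensity.shape[:-1]
    n = int(np.prod(lead_shape))
    pad = max(4, len(str(n - 1)))
    written = []
    for k, idx in enumerate(np.ndindex(lead_shape)):
        fname = f"{base}_{k:0{pad}d}{ext}"
        err_k = None if errors is None else np.asarray(errors)[idx]
        _write_xy(fname, radial, intensity[idx], err_k, axis_name, axis_unit,
                  provenance_line)
        written.append(fname)
    return written


def export_frame_ascii(profile, prefix: str, idx, scan_shape,
                       provenance_line: str = ""):
    """Export a single frame's profile during chain execution."""
    if scan_shape:
        flat = int(np.ravel_multi_index(idx, scan_shape))
        n = int(np.prod(scan_shape))
        pad = max(4, len(str(n - 1)))
        path = f"{prefix}_{flat:0{pad}d}.dat"
    else:
        path = f"{prefix}.dat"
    _write_xy(
        path, profile.bin_centres, profile.intensity, profile.errors,
        profile.radial_unit,
        {"q": "1/angstrom", "2theta": "degrees", "d": "angstrom"}[profile.radial_unit],
        provenance_line,
    )
    return path


def _write_xy(path, x, y, err, axis_name, axis_unit, provenance_line):
    with open(path, "w") as fh:
        fh.write(f"# {axis_name} ({axis_unit})  intensity"
                 + ("  error" if err is not None else "") + "\n")
        if provenance_line:
            fh.write(f"# {provenance_line}\n")
        for i in range(len(x)):
            if err is not None:
                fh.write(f"{x[i]:.10g} {y[i]:.10g} {err[i]:.10g}\n")
            else:
                fh.write(f"{x[i]:.10g} {y[i]:.10g}\n")
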