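"""The processing-chain engine.

A chain is an ordered list of registered steps, each split into the operation
(the algorithm) and its parameter record (validated against the step's
declared schema — the schema also drives the CLI help text).  Chains execute
over N-dimensional scans frame by frame, preserving the scan rank: a step
producing 1D output turns a (rows, cols, slow, fast) grid scan into a
(rows, cols, n_bins) stack, scalars into (rows, cols) maps.  Steps can save
their output into the result file and either forward it or pass the *input*
through unchanged to the next step (save & pass-through semantics), so e.g. a
cake remap can be archived while the azimuthal integration still consumes the
uncorrupted frame.  Serial and parallel execution produce identical, ordered
results; every run records a provenance block sufficient to re-execute it.

Chain serialization is a versioned JSON document: diff-able provenance and a
hand-editable configuration format.
"""

from __future__ import annotations

import json
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ChainError
from .reduce import CakeGrid, Frame, RadialProfile

CHAIN_FORMAT_VERSION = "1"

#: data kinds flowing between steps
KINDS = ("image", "profile", "azprofile", "cake", "scalars")


@dataclass
class StepDefinition:
    name: str
    function: Callable
    schema: dict
    input_kind: str
    output_kind: str
    needs_geometry: bool = False


_REGISTRY: dict[str, StepDefinition] = {}


def register_step(
    name: str,
    parameter_schema: dict,
    function: Callable,
    input_kind: str,
    output_kind: str,
    needs_geometry: bool = False,
) -> None:
    """Register a processing step; the schema drives parameter validation."""
    if name in _REGISTRY:
        raise ChainError(f"step {name!r} already registered")
    for kind in (input_kind, output_kind):
        if kind not in KINDS:
            raise ChainError(f"unknown data kind {kind!r}")
    for pname, spec in parameter_schema.items():
        if "type" not in spec:
            raise ChainError(f"schema for {name!r}/{pname}: missing 'type'")
    _REGISTRY[name] = StepDefinition(
        name, function, parameter_schema, input_kind, output_kind, needs_geometry
    )


def step_registry() -> dict[str, StepDefinition]:
    return dict(_REGISTRY)


_TYPES = {"float": float, "int": int, "str": str, "bool": bool}


def validate_parameters(step_name: str, schema: dict, params: dict) -> dict:
    """Check parameters against a schema, fill defaults; errors name the key."""
    out = {}
    for key in params:
        if key not in schema:
            raise ChainError(f"{step_name}: unknown parameter {key!r}")
    for key, spec in schema.items():
        if key in params:
            value = params[key]
            typ = _TYPES[spec["type"]]
            if value is None and spec.get("optional"):
                out[key] = None
                continue
            if spec["type"] == "float" and isinstance(value, int):
                value = float(value)
            if not isinstance(value, typ) or (typ is not bool and isinstance(value, bool)):
                raise ChainError(
                    f"{step_name}.{key}: expected {spec['type']}, got {value!r}"
                )
            if "choices" in spec and value not in spec["choices"]:
                raise ChainError(
                    f"{step_name}.{key}: {value!r} not in {spec['choices']}"
                )
            if "min" in spec and value < spec["min"]:
                raise ChainError(f"{step_name}.{key}: {value!r} < min {spec['min']}")
            if "max" in spec and value > spec["max"]:
                raise ChainError(f"{step_name}.{key}: {value!r} > max {spec['max']}")
            out[key] = value
        elif "default" in spec:
            out[key] = spec["default"]
        elif spec.get("optional"):
            out[key] = None
        else:
            raise ChainError(f"{step_name}: missing required parameter {key!r}")
    return out


@dataclass
class ChainStep:
    """One configured step: registered name, parameter record, save flags."""

    step_name: str
    parameters: dict = field(default_factory=dict)
    save_output: bool = False
    pass_through: bool = False


@dataclass
class Chain:
    """An ordered sequence of configured steps."""

    steps: list
    format_version: str = CHAIN_FORMAT_VERSION

    def validated(self) -> "Chain":
        validate_chain(self)
        return self


def validate_chain(chain: Chain, input_kind: str = "image") -> str:
    """Validate step names, parameters and data-kind compatibility.

    Returns the output kind of the chain.  A step consuming kind X cannot
    follow a forwarding step that produces a different kind.
    """
    if chain.format_version != CHAIN_FORMAT_VERSION:
        raise ChainError(
            f"chain format version {chain.format_version!r} != {CHAIN_FORMAT_VERSION!r}"
        )
    current = input_kind
    for i, step in enumerate(chain.steps):
        if step.step_name not in _REGISTRY:
            raise ChainError(f"step {i}: unknown step {step.step_name!r}")
        definition = _REGISTRY[step.step_name]
        validate_parameters(step.step_name, definition.schema, step.parameters)
        if definition.input_kind != current:
            raise ChainError(
                f"step {i} ({step.step_name!r}) consumes {definition.input_kind!r} "
                f"but receives {current!r}"
            )
        if not step.pass_through:
            current = definition.output_kind
    return current


def serialize_chain(chain: Chain) -> str:
    """Chain -> versioned JSON text (the on-disk and in-provenance format)."""
    doc = {
        "format_version": chain.format_version,
        "steps": [
            {
                "step_name": s.step_name,
                "parameters": s.parameters,
                "save_output": s.save_output,
                "pass_through": s.pass_through,
            }
            for s in chain.steps
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def parse_chain(text: str) -> Chain:
    """JSON text -> validated Chain; errors carry the path of the offence."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ChainError(f"chain is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "steps" not in doc:
        raise ChainError("chain document must be an object with a 'steps' list")
    steps = []
    for i, item in enumerate(doc["steps"]):
        for key in item:
            if key not in ("step_name", "parameters", "save_output", "pass_through"):
                raise ChainError(f"steps[{i}].{key}: unknown field")
        if "step_name" not in item:
            raise ChainError(f"steps[{i}]: missing step_name")
        steps.append(
            ChainStep(
                step_name=item["step_name"],
                parameters=dict(item.get("parameters", {})),
                save_output=bool(item.get("save_output", False)),
                pass_through=bool(item.get("pass_through", False)),
            )
        )
    chain = Chain(steps=steps, format_version=str(doc.get("format_version", "?")))
    validate_chain(chain)
    return chain


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------


@dataclass
class StepContext:
    """Per-frame context handed to step functions."""

    geometry: object = None
    frame_metadata: dict = field(default_factory=dict)


def _frame_kind(detector_ndim: int) -> str:
    return "image" if detector_ndim == 2 else "profile"


def chain_needs_geometry(chain: Chain) -> Optional[str]:
    """Name of the first step requiring a calibration geometry, if any."""
    for step in chain.steps:
        if _REGISTRY[step.step_name].needs_geometry:
            return step.step_name
    return None


def _run_frame(chain, obj, ctx):
    """Run one frame through the chain; returns (final, saved, export_requests)."""
    saved = {}
    exports = []
    for i, step in enumerate(chain.steps):
        definition = _REGISTRY[step.step_name]
        params = validate_parameters(step.step_name, definition.schema, step.parameters)
        out = definition.function(obj, params, ctx)
        if step.step_name == "Export Text":
            exports.append((i, params, obj))
        if step.save_output or step.pass_through:
            saved[f"{i}-{step.step_name}"] = out
        if not step.pass_through:
            obj = out
    return obj, saved, exports


def run_chain(
    chain: Chain,
    dataset,
    calibration=None,
    output_path: Optional[str] = None,
    execution: str = "serial",
    n_workers: Optional[int] = None,
) -> dict:
    """Execute a chain over every frame of a ScanDataset.

    Each innermost detector frame is processed independently; the outputs are
    reassembled so the scan rank is preserved and the stage axes propagate
    verbatim.  ``calibration`` may be a CalibrationResult, a
    DiffractionGeometry, or a path to a saved calibration file; a chain
    containing a ``Detector Calibration`` import step loads it from that
    step's parameter instead.  Per-frame failures are recorded with their
    frame index and flagged as NaN gaps; only structural errors abort the
    run.  ``execution='parallel'`` yields results identical to serial, in
    frame order.  When ``output_path`` is given the result, saved
    intermediates and the provenance record are written as a NeXus file.
    """
    from .calibrate import CalibrationResult
    from .geometry import DiffractionGeometry
    from . import nexus

    if execution not in ("serial", "parallel"):
        raise ChainError("execution must be 'serial' or 'parallel'")
    validate_chain(chain, input_kind=_frame_kind(dataset.detector_ndim))

    calibration_ref = ""
    geometry = None
    for step in chain.steps:
        if step.step_name == "Detector Calibration":
            path = step.parameters.get("calibration_file")
            if path:
                from .calibrate import load_calibration

                loaded = load_calibration(path)
                geometry = loaded.geometry
                calibration_ref = str(path)
    if geometry is None and calibration is not None:
        if isinstance(calibration, str):
            from .calibrate import load_calibration

            geometry = load_calibration(calibration).geometry
            calibration_ref = calibration
        elif isinstance(calibration, CalibrationResult):
            geometry = calibration.geometry
            calibration_ref = "<in-memory CalibrationResult>"
        elif isinstance(calibration, DiffractionGeometry):
            geometry = calibration
            calibration_ref = "<in-memory DiffractionGeometry>"
        else:
            raise ChainError(f"unsupported calibration object {type(calibration)}")
    needed_by = chain_needs_geometry(chain)
    if needed_by and geometry is None:
        raise ChainError(
            f"step {needed_by!r} requires a calibration geometry but none was provided"
        )

    data = np.asarray(dataset.data, dtype=float)
    det_ndim = dataset.detector_ndim
    scan_shape = data.shape[: data.ndim - det_ndim]
    indices = list(np.ndindex(scan_shape)) if scan_shape else [()]
    started = datetime.now(timezone.utc).isoformat()

    def metadata_for(idx):
        md = {}
        for key, value in dataset.metadata.items():
            arr = np.asarray(value)
            if arr.shape == scan_shape and scan_shape:
                md[key] = arr[idx]
            else:
                md[key] = value
        return md

    def task(idx):
        frame_data = data[idx] if idx else data
        if det_ndim == 2:
            obj = Frame(counts=frame_data, metadata=metadata_for(idx))
        else:
            axis = dataset.axes[-1].values if dataset.axes else np.arange(frame_data.size)
            obj = RadialProfile(
                radial_unit="q",
                bin_centres=np.asarray(axis, dtype=float),
                intensity=np.asarray(frame_data, dtype=float),
                metadata=metadata_for(idx),
            )
        ctx = StepContext(geometry=geometry, frame_metadata=metadata_for(idx))
        try:
            return idx, _run_frame(chain, obj, ctx), None
        except Exception as exc:
            return idx, None, f"frame {idx}: {type(exc).__name__}: {exc}"

    if execution == "parallel":
        with ThreadPoolExecutor(max_workers=n_workers or 4) as pool:
            raw = list(pool.map(task, indices))
    else:
        raw = [task(idx) for idx in indices]

    frame_errors = [msg for _, _, msg in raw if msg]
    per_frame_final = {idx: payload[0] if payload else None for idx, payload, _ in raw}
    per_frame_saved = {idx: payload[1] if payload else {} for idx, payload, _ in raw}
    per_frame_exports = [
        (idx, payload[2]) for idx, payload, _ in raw if payload and payload[2]
    ]

    result = _assemble(per_frame_final, scan_shape, dataset)
    intermediates = {}
    saved_keys = set()
    for saved in per_frame_saved.values():
        saved_keys |= set(saved)
    for key in sorted(saved_keys):
        intermediates[key] = _assemble(
            {idx: per_frame_saved[idx].get(key) for idx in per_frame_saved},
            scan_shape,
            dataset,
        )

    provenance = {
        "input": dataset.metadata.get("source_path", "<in-memory>"),
        "input_dataset": dataset.metadata.get("source_dataset", ""),
        "chain_json": serialize_chain(chain),
        "steps": [
            {"step_name": s.step_name, "parameters": s.parameters}
            for s in chain.steps
        ],
        "calibration": calibration_ref,
        "program": "powderchain",
        "version": _package_version(),
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "frame_errors": frame_errors,
    }
    output = {
        "result": result,
        "intermediates": intermediates,
        "provenance": provenance,
        "frame_errors": frame_errors,
    }
    if per_frame_exports and output_path:
        import os

        outdir = os.path.dirname(os.path.abspath(output_path))
        for idx, requests in per_frame_exports:
            for step_i, params, obj in requests:
                prefix = params.get("prefix") or "profile"
                nexus.export_frame_ascii(
                    obj, os.path.join(outdir, prefix), idx, scan_shape,
                    provenance_line=f"powderchain {_package_version()}",
                )
    if output_path:
        nexus.write_processed(output_path, result, intermediates, provenance)
    return output


def _package_version() -> str:
    from . import __version__

    return __version__


def _assemble(per_frame: dict, scan_shape, dataset) -> dict:
    """Stack per-frame outputs into scan-rank-preserving arrays with axes."""
    example = next((v for v in per_frame.values() if v is not None), None)
    if example is None:
        raise ChainError("every frame failed; nothing to assemble")
    stage_axes = [
        (ax.name, ax.unit, np.asarray(ax.values))
        for ax in dataset.axes[: len(scan_shape)]
    ]
    if len(stage_axes) < len(scan_shape):
        stage_axes = [
            (f"dim_{i}", "", np.arange(n)) for i, n in enumerate(scan_shape)
        ]

    def stack(get, shape, fill=np.nan):
        out = np.full(scan_shape + shape, fill)
        for idx, obj in per_frame.items():
            if obj is not None:
                out[idx] = get(obj)
        return out

    if isinstance(example, Frame):
        data = stack(lambda o: o.counts, example.counts.shape)
        errors = (
            stack(lambda o: o.errors, example.counts.shape)
            if example.errors is not None
            else None
        )
        axes = stage_axes + [
            ("slow", "pixel", np.arange(example.counts.shape[0])),
            ("fast", "pixel", np.arange(example.counts.shape[1])),
        ]
        return {"kind": "image", "data": data, "errors": errors, "axes": axes}
    if isinstance(example, RadialProfile):
        data = stack(lambda o: o.intensity, example.intensity.shape)
        errors = (
            stack(lambda o: o.errors, example.intensity.shape)
            if example.errors is not None
            else None
        )
        axes = stage_axes + [
            (example.radial_unit, _radial_unit_label(example.radial_unit),
             example.bin_centres)
        ]
        return {"kind": "profile", "data": data, "errors": errors, "axes": axes}
    if isinstance(example, CakeGrid):
        data = stack(lambda o: o.intensity, example.intensity.shape)
        errors = (
            stack(lambda o: o.errors, example.intensity.shape)
            if example.errors is not None
            else None
        )
        weights = stack(lambda o: o.weights, example.weights.shape, fill=0.0)
        axes = stage_axes + [
            ("azimuth", "degrees", example.azimuth_centres),
            (example.radial_unit, _radial_unit_label(example.radial_unit),
             example.radial_centres),
        ]
        return {
            "kind": "cake", "data": data, "errors": errors, "axes": axes,
            "weights": weights,
        }
    if isinstance(example, tuple) and len(example) == 3:  # azimuthal profile
        chi, intensity, err = example
        data = stack(lambda o: o[1], intensity.shape)
        errors = stack(lambda o: o[2], intensity.shape) if err is not None else None
        axes = stage_axes + [("azimuth", "degrees", chi)]
        return {"kind": "azprofile", "data": data, "errors": errors, "axes": axes}
    if isinstance(example, dict):  # scalars
        out = {}
        for key in example:
            out[key] = stack(lambda o, k=key: o.get(k, np.nan), ())
        return {"kind": "scalars", "data": out, "errors": None, "axes": stage_axes}
    raise ChainError(f"cannot assemble output of type {type(example)}")


def _radial_unit_label(unit: str) -> str:
    return {"q": "1/angstrom", "2theta": "degrees", "d": "angstrom"}[unit]


# ---------------------------------------------------------------------------
# built-in steps
# ---------------------------------------------------------------------------


def _register_builtin_steps():
    from . import analyze, reduce

    register_step(
        "Detector Calibration",
        {"calibration_file": {"type": "str", "optional": True}},
        lambda obj, params, ctx: obj,
        input_kind="image",
        output_kind="image",
    )
    register_step(
        "Threshold Mask",
        {
            "low": {"type": "float", "default": 0.0},
            "high": {"type": "float", "default": 1e9},
        },
        lambda obj, params, ctx: reduce.threshold_mask(obj, params["low"], params["high"]),
        input_kind="image",
        output_kind="image",
    )
    register_step(
        "General Detector Error",
        {"gain": {"type": "float", "default": 1.0, "min": 1e-12}},
        lambda obj, params, ctx: reduce.estimate_errors(obj, gain=params["gain"]),
        input_kind="image",
        output_kind="image",
    )

    def _corrections(obj, params, ctx):
        out = obj
        if params["solid_angle"]:
            out = reduce.correct_solid_angle(out, ctx.geometry)
        if params["polarization"]:
            out = reduce.correct_polarization(
                out, ctx.geometry, params["polarization_fraction"]
            )
        return out

    register_step(
        "Powder Diffraction Intensity Corrections",
        {
            "solid_angle": {"type": "bool", "default": True},
            "polarization": {"type": "bool", "default": True},
            "polarization_fraction": {"type": "float", "default": 0.0,
                                      "min": -1.0, "max": 1.0},
        },
        _corrections,
        input_kind="image",
        output_kind="image",
        needs_geometry=True,
    )

    def _divide(obj, params, ctx):
        if params["metadata_key"]:
            return reduce.divide(obj, params["metadata_key"])
        if params["value"] is None:
            raise ChainError("Divide: set either 'value' or 'metadata_key'")
        return reduce.divide(obj, params["value"])

    register_step(
        "Divide",
        {
            "value": {"type": "float", "optional": True},
            "metadata_key": {"type": "str", "optional": True},
        },
        _divide,
        input_kind="image",
        output_kind="image",
    )
    register_step(
        "Dynamic Background Subtraction",
        {
            "iterations": {"type": "int", "default": 30, "min": 0},
            "clip_factor": {"type": "float", "default": 1.5, "min": 0.0},
        },
        lambda obj, params, ctx: reduce.subtract_radial_background(
            obj, ctx.geometry, iterations=params["iterations"],
            clip_factor=params["clip_factor"],
        ),
        input_kind="image",
        output_kind="image",
        needs_geometry=True,
    )
    register_step(
        "Cake Remapping",
        {
            "n_radial": {"type": "int", "default": 100, "min": 2},
            "n_azimuthal": {"type": "int", "default": 36, "min": 1},
            "splitting": {"type": "str", "default": "none", "choices": ["none", "bbox"]},
            "radial_unit": {"type": "str", "default": "q", "choices": ["q", "2theta", "d"]},
        },
        lambda obj, params, ctx: reduce.cake_remap(
            obj, ctx.geometry, n_radial=params["n_radial"],
            n_azimuthal=params["n_azimuthal"], splitting=params["splitting"],
            radial_unit=params["radial_unit"],
        ),
        input_kind="image",
        output_kind="cake",
        needs_geometry=True,
    )

    def _integrate(obj, params, ctx):
        rr = None
        if params["radial_lo"] is not None and params["radial_hi"] is not None:
            rr = (params["radial_lo"], params["radial_hi"])
        return reduce.integrate_azimuthal(
            obj, ctx.geometry, n_bins=params["n_bins"],
            radial_unit=params["radial_unit"], radial_range=rr,
            splitting=params["splitting"],
        )

    register_step(
        "Azimuthal Integration",
        {
            "n_bins": {"type": "int", "default": 1000, "min": 2},
            "radial_unit": {"type": "str", "default": "q", "choices": ["q", "2theta", "d"]},
            "splitting": {"type": "str", "default": "none", "choices": ["none", "bbox"]},
            "radial_lo": {"type": "float", "optional": True},
            "radial_hi": {"type": "float", "optional": True},
        },
        _integrate,
        input_kind="image",
        output_kind="profile",
        needs_geometry=True,
    )

    def _peak_fit(obj, params, ctx):
        res = analyze.fit_peak(
            obj, (params["window_lo"], params["window_hi"]), shape=params["shape"]
        )
        return {
            "centre": res.centre, "fwhm": res.fwhm, "area": res.area,
            "centre_sigma": res.centre_sigma, "fwhm_sigma": res.fwhm_sigma,
            "success": float(res.success),
        }

    register_step(
        "Peak Fit",
        {
            "window_lo": {"type": "float"},
            "window_hi": {"type": "float"},
            "shape": {"type": "str", "default": "gaussian",
                      "choices": ["gaussian", "pseudo_voigt"]},
        },
        _peak_fit,
        input_kind="profile",
        output_kind="scalars",
    )
    register_step(
        "Azimuthal Profile",
        {"q_lo": {"type": "float"}, "q_hi": {"type": "float"}},
        lambda obj, params, ctx: analyze.azimuthal_profile(
            obj, (params["q_lo"], params["q_hi"])
        ),
        input_kind="cake",
        output_kind="azprofile",
    )

    def _orientation(obj, params, ctx):
        chi, intensity, _ = obj
        res = analyze.orientation_metrics(
            chi, intensity, floor_percentile=params["floor_percentile"]
        )
        return {
            "degree": res.degree, "direction": res.direction,
            "total_intensity": res.total_intensity,
        }

    register_step(
        "Orientation Metrics",
        {"floor_percentile": {"type": "float", "default": 5.0, "min": 0.0, "max": 50.0}},
        _orientation,
        input_kind="azprofile",
        output_kind="scalars",
    )
    register_step(
        "Export Text",
        {"prefix": {"type": "str", "default": "profile"}},
        lambda obj, params, ctx: obj,
        input_kind="profile",
        output_kind="profile",
    )


_register_builtin_steps()
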