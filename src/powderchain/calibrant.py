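"""Calibration-standard line lists and d/q/2theta conversion.

Built-in calibrants are generated from published cubic lattice parameters and
reflection conditions rather than stored as literal d-spacing tables, so the
provenance of every reference number is the lattice constant itself:

* ``CeO2_SRM674b`` — ceria, fluorite structure (face-centred cubic),
  certified lattice parameter a = 5.411651 A (NIST SRM 674b certificate).
  F-centring allows reflections with h, k, l all even or all odd.
* ``Si_SRM640c`` — silicon, diamond cubic, certified lattice parameter
  a = 5.4311946 A (NIST SRM 640c certificate).  Diamond-glide extinctions
  allow h, k, l all odd, or all even with h + k + l divisible by 4.

External line lists are plain text: ``#`` comments, one d-spacing (Angstrom)
per line, optional second column with an hkl label.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import CalibrantError

#: Maximum number of rings emitted for a built-in calibrant.
MAX_BUILTIN_RINGS = 50

_CUBIC_BUILTINS = {
    # name -> (lattice parameter a in Angstrom, reflection-condition key)
    "CeO2_SRM674b": (5.411651, "fcc"),
    "Si_SRM640c": (5.4311946, "diamond"),
}


def _allowed_fcc(h, k, l):
    parities = {h % 2, k % 2, l % 2}
    return len(parities) == 1


def _allowed_diamond(h, k, l):
    if not _allowed_fcc(h, k, l):
        return False
    if h % 2 == 1:  # all odd
        return True
    return (h + k + l) % 4 == 0


_CONDITIONS = {"fcc": _allowed_fcc, "diamond": _allowed_diamond}


@dataclass(frozen=True)
class Calibrant:
    """A named list of certified d-spacings, strictly decreasing, in Angstrom."""

    name: str
    d_spacings: np.ndarray
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        d = np.asarray(self.d_spacings, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise CalibrantError("d_spacings must be a non-empty 1D sequence")
        if np.any(d <= 0):
            raise CalibrantError("d-spacings must be positive")
        if np.any(np.diff(d) >= 0):
            raise CalibrantError("d-spacings must be strictly decreasing")
        if d.size > 1 and np.min(-np.diff(d)) < 1e-6:
            raise CalibrantError("duplicate d-spacings (within 1e-6 A)")
        if self.labels is not None and len(self.labels) != d.size:
            raise CalibrantError("labels length must match d_spacings")
        object.__setattr__(self, "d_spacings", d)

    def __len__(self) -> int:
        return self.d_spacings.size


def cubic_d_spacings(a: float, condition: str, max_rings: int = MAX_BUILTIN_RINGS):
    """d = a / sqrt(h^2 + k^2 + l^2) for allowed cubic reflections, descending.

    Returns (d_spacings, labels); symmetry-equivalent reflections are merged
    onto the representative with h >= k >= l.
    """
    allowed = _CONDITIONS[condition]
    seen: dict[int, tuple[int, int, int]] = {}
    hmax = 12
    for h in range(hmax + 1):
        for k in range(h + 1):
            for l in range(k + 1):
                if h == k == l == 0:
                    continue
                if not allowed(h, k, l):
                    continue
                s = h * h + k * k + l * l
                if s not in seen:
                    seen[s] = (h, k, l)
    order = sorted(seen)  # ascending h^2+k^2+l^2 => descending d
    order = order[:max_rings]
    d = np.array([a / np.sqrt(s) for s in order])
    labels = tuple("{}{}{}".format(*seen[s]) for s in order)
    return d, labels


def load_calibrant(name_or_path: str) -> Calibrant:
    """Load a built-in calibrant by name or a d-spacing line list from a file."""
    if name_or_path in _CUBIC_BUILTINS:
        a, condition = _CUBIC_BUILTINS[name_or_path]
        d, labels = cubic_d_spacings(a, condition)
        return Calibrant(name=name_or_path, d_spacings=d, labels=labels)
    if os.path.exists(name_or_path):
        return _read_line_list(name_or_path)
    raise CalibrantError(
        f"unknown calibrant {name_or_path!r}; built-ins: {sorted(_CUBIC_BUILTINS)}"
    )


def _read_line_list(path: str) -> Calibrant:
    d_values: list[float] = []
    labels: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            try:
                d_values.append(float(parts[0]))
            except ValueError as exc:
                raise CalibrantError(f"{path}:{lineno}: not a d-spacing: {parts[0]!r}") from exc
            labels.append(parts[1] if len(parts) > 1 else "")
    if not d_values:
        raise CalibrantError(f"{path}: no d-spacings found")
    name = os.path.splitext(os.path.basename(path))[0]
    lab = tuple(labels) if any(labels) else None
    return Calibrant(name=name, d_spacings=np.array(d_values), labels=lab)


def ring_positions(
    cal: Calibrant, wavelength: float, two_theta_max: float = 180.0
) -> list[tuple[float, float, float]]:
    """Reachable reflections as (d, q, 2theta) tuples, q strictly increasing.

    Only reflections with ``lambda < 2 d`` (Bragg condition satisfiable) and
    ``2theta <= two_theta_max`` (degrees) are emitted; q = 2 pi / d and
    2theta = 2 arcsin(lambda / 2 d).
    """
    if wavelength <= 0:
        raise CalibrantError("wavelength must be positive")
    out = []
    for d in cal.d_spacings:
        if wavelength >= 2.0 * d:
            continue
        tth = np.degrees(2.0 * np.arcsin(wavelength / (2.0 * d)))
        if tth > two_theta_max:
            continue
        out.append((float(d), float(2.0 * np.pi / d), float(tth)))
    return out
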