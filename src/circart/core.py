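"""Angle arithmetic on the circle.

Angles are held internally in radians on the half-open interval ``[0, 2π)``;
degrees exist only at the I/O boundary.  The geodesic (shortest-arc) distance
defined here is the building block of the angular randomisation test.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = [
    "TWO_PI",
    "wrap_angle",
    "to_radians",
    "geodesic_distance",
    "AngleSample",
    "as_angle_sample",
]


def _check_finite(x: np.ndarray | float, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite, got {x!r}")


def wrap_angle(x):
    """Reduce an angle (radians) into ``[0, 2π)``.

    Exact multiples of 2π map to 0 (half-open convention).  Accepts scalars
    or arrays; idempotent.

    Raises
    ------
    ValueError
        If any input is NaN or infinite.
    """
    x = np.asarray(x, dtype=float)
    _check_finite(x, "angle")
    out = np.mod(x, TWO_PI)
    # np.mod can return 2π itself when x is a tiny negative number, due to
    # rounding; fold that edge case back to 0 to keep the interval half-open.
    out = np.where(out >= TWO_PI, 0.0, out)
    return float(out) if out.ndim == 0 else out


def to_radians(x):
    """Convert degrees to radians wrapped into ``[0, 2π)``."""
    x = np.asarray(x, dtype=float)
    _check_finite(x, "angle (degrees)")
    return wrap_angle(np.deg2rad(x))


def geodesic_distance(a, b):
    """Shortest angular (geodesic) distance between two points on the circle.

    Returns ``min(Δ, 2π − Δ)`` with ``Δ = |a − b| mod 2π``; the result lies in
    ``[0, π]``.  Symmetric in its arguments and invariant under a common
    rotation.  Broadcasts like a numpy ufunc.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_finite(a, "a")
    _check_finite(b, "b")
    # reduce |a - b| so the result is exactly symmetric in (a, b)
    delta = np.mod(np.abs(a - b), TWO_PI)
    out = np.minimum(delta, TWO_PI - delta)
    return float(out) if out.ndim == 0 else out


class AngleSample:
    """An ordered sample of angles, wrapped to radians on ``[0, 2π)``.

    Parameters
    ----------
    angles : sequence of float
        Angles; wrapped on construction.
    unit : {"radians", "degrees"}
        Unit of the *input* values.  Stored values are always radians.
    """

    __slots__ = ("angles", "unit")

    def __init__(self, angles: Iterable[float] | Sequence[float], unit: str = "radians"):
        arr = np.atleast_1d(np.asarray(list(angles) if not isinstance(angles, np.ndarray) else angles, dtype=float))
        if arr.ndim != 1:
            raise ValueError("angles must be one-dimensional")
        if arr.size < 1:
            raise ValueError("an AngleSample needs at least one angle")
        if unit not in ("radians", "degrees"):
            raise ValueError(f"unit must be 'radians' or 'degrees', got {unit!r}")
        wrapped = to_radians(arr) if unit == "degrees" else wrap_angle(arr)
        wrapped = np.atleast_1d(wrapped)
        wrapped.setflags(write=False)
        self.angles = wrapped
        self.unit = unit

    def __repr__(self) -> str:
        return f"AngleSample(n={self.size})"

    @property
    def size(self) -> int:
        return int(self.angles.size)

    def __len__(self) -> int:
        return self.size

    def __iter__(self):
        return iter(self.angles)

    def rotated(self, c: float) -> "AngleSample":
        """Return a copy rotated by ``c`` radians (wrapped)."""
        return AngleSample(self.angles + c)

    def __eq__(self, other) -> bool:
        return isinstance(other, AngleSample) and np.array_equal(self.angles, other.angles)


def as_angle_sample(x, unit: str = "radians") -> AngleSample:
    """Coerce an array-like or AngleSample to an AngleSample."""
    if isinstance(x, AngleSample):
        return x
    return AngleSample(x, unit=unit)
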