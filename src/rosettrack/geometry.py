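"""Circular (angle) arithmetic helpers.

All angles are degrees. The image frame has rows increasing downward;
everything user-facing is reported in a mathematical y-up frame, so the
conversion from (row, col) displacements to angles flips the sign of the
row component exactly once, here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_deg",
    "circular_distance",
    "circular_mean",
    "angle_from_displacement",
]


def wrap_deg(angle):
    """Wrap an angle (or array) into (-180, 180]."""
    wrapped = np.asarray(angle, dtype=float) % 360.0
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def circular_distance(a, b):
    """Absolute circular distance |a - b| in [0, 180]."""
    d = wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    out = np.abs(d)
    if np.ndim(out) == 0:
        return float(out)
    return out


def circular_mean(angles) -> float:
    """Mean direction of a set of angles, in [0, 360)."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circular_mean of empty set")
    rad = np.deg2rad(angles)
    mean = float(np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0)
    return mean if mean < 360.0 else 0.0


def angle_from_displacement(drow: float, dcol: float) -> float:
    """Angle of a (row, col) displacement in the y-up frame, in [0, 360).

    A displacement toward larger columns is 0 deg; toward smaller rows
    (visually "up") is 90 deg.
    """
    return float(np.rad2deg(np.arctan2(-drow, dcol)) % 360.0)
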