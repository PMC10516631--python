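"""Circular-quantity helpers shared across the package.

Angles are radians throughout, measured counter-clockwise from the +x axis
and wrapped to the half-open interval (-pi, pi].
"""
from __future__ import annotations

import numpy as np


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = np.mod(a + np.pi, 2.0 * np.pi) - np.pi
    # mod maps exact multiples of 2*pi offset to -pi; the convention here is +pi
    w = np.where(w == -np.pi, np.pi, w)
    return w if w.ndim else float(w)


def circular_mean(a) -> float:
    """Direction of the resultant of unit vectors, in (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    return float(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))))


def circular_std(a) -> float:
    """sqrt(-2 ln Rbar), the standard circular dispersion measure."""
    a = np.asarray(a, dtype=float)
    rbar = np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a)))
    rbar = min(rbar, 1.0)
    if rbar <= 0.0:
        return float(np.inf)
    return float(np.sqrt(-2.0 * np.log(rbar)))


def circular_distance(a, b):
    """Absolute angular separation in [0, pi]."""
    return np.abs(wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))
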