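"""Circular-track geometry helpers.

All positions live on a belt of length ``L`` treated as the half-open
interval ``[0, L)``. Distances between two positions are either the
*arc distance* ``min(d, L - d)`` (unsigned, in ``[0, L/2]``) or the
*forward distance* measured along the running direction (in ``[0, L)``).
"""

from __future__ import annotations

import numpy as np


def wrap(x, belt_length: float):
    """Map positions onto ``[0, belt_length)``."""
    return np.mod(x, belt_length)


def forward_distance(a, b, belt_length: float):
    """Distance from ``a`` to ``b`` travelling in the running direction."""
    return np.mod(np.asarray(b, dtype=float) - np.asarray(a, dtype=float), belt_length)


def arc_distance(a, b, belt_length: float):
    """Shortest unsigned distance between positions on the belt."""
    d = forward_distance(a, b, belt_length)
    return np.minimum(d, belt_length - d)


def circular_com(values, positions, belt_length: float) -> float:
    """Center of mass of nonnegative weights at circular positions.

    Uses the angular-mean construction so the result does not depend on
    where the belt coordinate wraps.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    total = values.sum()
    if total <= 0:
        return float("nan")
    ang = positions * (2.0 * np.pi / belt_length)
    c = float(np.sum(values * np.cos(ang)))
    s = float(np.sum(values * np.sin(ang)))
    if c == 0.0 and s == 0.0:
        return float("nan")
    com = np.arctan2(s, c) * belt_length / (2.0 * np.pi)
    return float(np.mod(com, belt_length))


def gaussian_smooth_circular(x: np.ndarray, sigma_bins: float) -> np.ndarray:
    """Gaussian smoothing with circular (wrap-around) boundary handling."""
    from scipy.ndimage import gaussian_filter1d

    return gaussian_filter1d(np.asarray(x, dtype=float), sigma_bins, mode="wrap")
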