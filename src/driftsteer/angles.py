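"""Circular arithmetic on the 180°-periodic orientation circle.

Orientations (as opposed to directions of motion) are defined modulo 180°:
a grating drifting at 30° and one at 210° have the same orientation.  All
public functions here accept scalars or arrays of degrees and return the
same shape.  The canonical interval for an orientation is [-90°, 90°).

The standard trick throughout is angle doubling: mapping an orientation
``theta`` to the point ``exp(2i·theta)`` on the unit circle turns the
180°-periodic problem into an ordinary 360°-periodic one, where resultant
vectors, circular means and percentiles are well defined.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_orientation",
    "orientation_distance",
    "signed_orientation_diff",
    "circular_mean_orientation",
]


def wrap_orientation(theta):
    """Wrap orientation(s) in degrees to the canonical interval [-90, 90)."""
    return (np.asarray(theta, dtype=float) + 90.0) % 180.0 - 90.0


def orientation_distance(a, b):
    """Minimal distance between two orientations, in degrees.

    The result lives in [0, 90]: two orientations can never be further
    apart than perpendicular.  This is the |ΔPO| drift-magnitude metric
    and also the |rPO| distance from an experienced orientation.
    """
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def signed_orientation_diff(a, b):
    """Signed circular difference ``a - b`` wrapped to (-90, 90] degrees.

    Positive means ``a`` lies counter-clockwise of ``b`` along the shorter
    arc.  A half-turn difference is reported as +90 by convention.
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    return np.where(d > 90.0, d - 180.0, d)[()]


def circular_mean_orientation(theta, weights=None, axis=None):
    """Circular mean of orientations via angle doubling.

    Parameters
    ----------
    theta : array_like
        Orientations in degrees (any wrapping).
    weights : array_like, optional
        Non-negative weights, broadcast against ``theta``.
    axis : int, optional
        Axis to reduce; default reduces everything.

    Returns
    -------
    float or ndarray
        Mean orientation in [-90, 90).
    """
    beta = np.deg2rad(2.0 * np.asarray(theta, dtype=float))
    c, s = np.cos(beta), np.sin(beta)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        c, s = c * w, s * w
    return wrap_orientation(np.rad2deg(np.arctan2(np.sum(s, axis=axis), np.sum(c, axis=axis))) / 2.0)
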