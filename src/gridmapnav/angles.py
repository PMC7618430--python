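"""Project-wide angle convention and circular helpers.

All headings and directions are compass-like angles: measured from the +y
axis, increasing clockwise, in [0, 2*pi).  The direction sweep used to lay
out training locations follows the same orientation.  Every conversion
between vectors and angles goes through this module so the convention can
be changed in exactly one place.

Signed angular differences are wrapped to (-pi, pi]; absolute differences
live in [0, pi].
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def angle_of(vx, vy):
    """Angle of the vector (vx, vy) in the compass convention.

    (0, 1) -> 0, (1, 0) -> pi/2, (0, -1) -> pi, (-1, 0) -> 3*pi/2.
    """
    return np.mod(np.arctan2(vx, vy), TWO_PI)


def unit_vector(theta):
    """Unit vector (x, y) pointing along compass angle ``theta``."""
    theta = np.asarray(theta, dtype=float)
    return np.stack([np.sin(theta), np.cos(theta)], axis=-1)


def wrap_signed(delta):
    """Wrap an angular difference (radians) to (-pi, pi]."""
    delta = np.asarray(delta, dtype=float)
    wrapped = np.mod(delta + np.pi, TWO_PI) - np.pi
    # np.mod maps to [-pi, pi); move the single excluded endpoint to +pi
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def abs_diff(a, b):
    """Absolute circular difference |wrap(a - b)| in [0, pi]."""
    return np.abs(wrap_signed(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def circular_mean_signed(errors, axis=0):
    """Circular mean of signed angular errors, returned in (-pi, pi].

    Computed as the angle of the mean unit vector; for tightly clustered
    errors this agrees with the arithmetic mean.
    """
    import warnings

    errors = np.asarray(errors, dtype=float)
    with warnings.catch_warnings():
        # all-NaN slices (e.g. the goal gridpoint) yield NaN, silently
        warnings.simplefilter("ignore", RuntimeWarning)
        s = np.nanmean(np.sin(errors), axis=axis)
        c = np.nanmean(np.cos(errors), axis=axis)
    return wrap_signed(np.arctan2(s, c))
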