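"""Small circular-statistics helpers shared by the metric modules."""

from __future__ import annotations

import numpy as np


def wrap_angle(theta):
    """Wrap angles into (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.remainder(theta + np.pi, 2.0 * np.pi) - np.pi
    # remainder maps exact odd multiples of pi to -pi; the convention here
    # is the half-open interval (-pi, pi]
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def resultant_length(angles) -> float:
    """Mean resultant length R of a sample of angles (R in [0, 1])."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        return float("nan")
    c = np.cos(angles).mean()
    s = np.sin(angles).mean()
    return float(np.hypot(c, s))


def circular_mean(angles) -> float:
    """Circular mean angle, in (-pi, pi]."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        return float("nan")
    return wrap_angle(np.arctan2(np.sin(angles).sum(), np.cos(angles).sum()))
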