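"""Circular helpers for 180-degree-periodic orientation variables.

Orientation is a circular feature with period 180 deg (a line through the
origin has no direction).  All public statistics in this package therefore
live on the "doubled" circle: an orientation theta is embedded as the angle
2*theta on the full circle, averaged there, and halved back.  Signed
differences are wrapped to the half-open interval (-period/2, period/2].
"""

from __future__ import annotations

import numpy as np

ORIENTATION_PERIOD_DEG = 180.0


def wrap_orientation(theta_deg, period: float = ORIENTATION_PERIOD_DEG):
    """Wrap orientations into [0, period)."""
    w = np.mod(theta_deg, period)
    # np.mod can round a tiny negative input up to the period itself
    return np.where(w >= period, w - period, w) if np.ndim(w) else (w - period if w >= period else w)


def signed_circ_diff(a_deg, b_deg, period: float = ORIENTATION_PERIOD_DEG):
    """Signed circular difference a - b wrapped to (-period/2, period/2]."""
    d = np.mod(np.asarray(a_deg, dtype=float) - b_deg, period)
    half = period / 2.0
    return np.where(d > half, d - period, d)


def circ_mean_orientation(theta_deg, axis=None, period: float = ORIENTATION_PERIOD_DEG):
    """Circular mean of orientations via angle doubling, in [0, period)."""
    ang = np.asarray(theta_deg, dtype=float) * (2.0 * np.pi / period)
    z = np.exp(1j * ang).mean(axis=axis)
    mean = np.angle(z) * (period / (2.0 * np.pi))
    return np.mod(mean, period)


def circ_std_orientation(theta_deg, axis=None, period: float = ORIENTATION_PERIOD_DEG):
    """Circular standard deviation of orientations, in degrees.

    Computed as sqrt(-2 ln R) on the doubled circle and mapped back to the
    orientation scale; for tightly concentrated samples this coincides with
    the linear standard deviation.
    """
    ang = np.asarray(theta_deg, dtype=float) * (2.0 * np.pi / period)
    r = np.abs(np.exp(1j * ang).mean(axis=axis))
    r = np.minimum(r, 1.0)
    with np.errstate(divide="ignore"):
        s = np.sqrt(np.maximum(-2.0 * np.log(r), 0.0))
    return s * (period / (2.0 * np.pi))


def wrap_index_angle(dpsi_rad, period: float = np.pi):
    """Wrap neuron index-angle differences to (-period/2, period/2] (radians)."""
    d = np.mod(dpsi_rad, period)
    half = period / 2.0
    return np.where(d > half, d - period, d)
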