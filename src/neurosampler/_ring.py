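"""Circular (ring) arithmetic helpers shared across modules.

Stimulus values live on the ring (−L/2, L/2] with L = 360° by default.
"""

from __future__ import annotations

import numpy as np

DEFAULT_L = 360.0


def wrap(x, L: float = DEFAULT_L):
    """Wrap angles (degrees) onto (−L/2, L/2]."""
    w = np.mod(np.asarray(x, dtype=float) + L / 2.0, L) - L / 2.0
    # np.mod maps the boundary to −L/2; the convention here is half-open at −L/2
    w = np.where(w == -L / 2.0, L / 2.0, w)
    if np.ndim(x) == 0:
        return float(w)
    return w


def circ_mean(angles, weights=None, L: float = DEFAULT_L) -> float:
    """Resultant-vector mean of angles in degrees on a ring of length L."""
    ang = np.asarray(angles, dtype=float) * (2.0 * np.pi / L)
    if weights is None:
        z = np.exp(1j * ang).mean()
    else:
        w = np.asarray(weights, dtype=float)
        z = np.sum(w * np.exp(1j * ang)) / np.sum(w)
    return wrap(np.angle(z) * L / (2.0 * np.pi), L)


def linear_popvec(angles, weights, L: float = DEFAULT_L, n_iter: int = 3) -> float:
    """Wrap-safe linear weighted mean of angles.

    The plain weighted mean sum(w*theta)/sum(w) is the exact mean of a
    Gaussian likelihood decoded from log-linear population activity, but it
    is wrap-sensitive.  Starting from the circular resultant mean, iterate
    the weighted mean of wrapped deviations to a fixed point; this equals
    the plain formula whenever the activity stays away from the wrap point.
    """
    w = np.asarray(weights, dtype=float)
    c = circ_mean(angles, weights=w, L=L)
    th = np.asarray(angles, dtype=float)
    for _ in range(n_iter):
        c = wrap(c + np.sum(w * wrap(th - c, L)) / np.sum(w), L)
    return float(c)


def circ_dist(a, b, L: float = DEFAULT_L):
    """Minimal-arc signed difference a − b on the ring."""
    return wrap(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), L)
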