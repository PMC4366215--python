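"""Toroidal geometry and the correlated-random-walk (CRW) movement kernel.

All mobile agents (prospecting birds, wild boars, red foxes) share one
movement primitive: at each time step the heading is perturbed by a normal
turn (mean 0 deg, configurable SD) and the agent advances a fixed step
length along the new heading on an ``L x L`` torus.

Conventions
-----------
* Positions are continuous; the discrete grid cell of a position is obtained
  by flooring each coordinate.  One cell corresponds to 10 m at the default
  parameterisation of the model.
* Headings are compass-like: 0 deg points along +y and angles increase
  clockwise, so a step of length ``s`` displaces by ``(s*sin(h), s*cos(h))``.
* Turn draws are added unreduced (an SD of 360 deg may wind the heading
  through several full turns, producing a very tight, convoluted path); only
  the resulting heading is reduced modulo 360.

All functions broadcast over leading axes so that whole populations can be
stepped in one call.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap",
    "torus_delta",
    "torus_distance",
    "pairwise_torus_distance",
    "crw_step",
]

_DEG2RAD = np.pi / 180.0


def wrap(p, side):
    """Reduce coordinates into ``[0, side)`` on the torus.

    Idempotent.  Raises ``ValueError`` for non-finite coordinates or a
    non-positive side length.
    """
    if side <= 0:
        raise ValueError(f"side length must be positive, got {side}")
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite coordinates cannot be wrapped")
    out = np.mod(p, side)
    # np.mod of a tiny negative value may round up to exactly `side`
    out = np.where(out >= side, out - side, out)
    return out


def torus_delta(a, b, side):
    """Signed component-wise difference ``a - b`` under minimum image."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return d - side * np.round(d / side)


def torus_distance(a, b, side):
    """Euclidean distance between positions under the minimum-image convention.

    Symmetric, zero iff the (wrapped) points coincide, and bounded above by
    ``side * sqrt(2) / 2``.
    """
    d = torus_delta(a, b, side)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite coordinates in distance computation")
    return np.sqrt(np.sum(d * d, axis=-1))


def pairwise_torus_distance(a, b, side):
    """Distance matrix between row sets ``a`` (m, 2) and ``b`` (n, 2)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    return torus_distance(a[:, None, :], b[None, :, :], side)


def crw_step(pos, heading, sd, step, rng, side):
    """One correlated-random-walk step.

    Parameters
    ----------
    pos : array-like, shape (..., 2)
        Current (wrapped) positions.
    heading : array-like, shape (...)
        Current headings in degrees.
    sd : float or array-like
        SD of the normal turning-angle distribution, degrees (``sd >= 0``).
        May broadcast against ``heading`` to give per-agent turning.
    step : float
        Step length in cells (``> 0``); every agent in the model uses 1.
    rng : numpy.random.Generator
    side : float
        Torus side length.

    Returns
    -------
    (new_pos, new_heading)
        New positions wrapped into the torus and new headings reduced
        modulo 360.
    """
    if np.any(np.asarray(sd) < 0):
        raise ValueError("turning SD must be non-negative")
    if step <= 0:
        raise ValueError("step length must be positive")
    heading = np.asarray(heading, dtype=float)
    turn = rng.normal(0.0, 1.0, size=heading.shape) * sd
    new_heading = heading + turn
    rad = new_heading * _DEG2RAD
    delta = step * np.stack([np.sin(rad), np.cos(rad)], axis=-1)
    new_pos = wrap(np.asarray(pos, dtype=float) + delta, side)
    return new_pos, np.mod(new_heading, 360.0)
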