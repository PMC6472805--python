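"""Periodic geometry primitives shared by the discrete-network modules.

The simulation box is periodic in x and y and bounded in z, so every pairwise
vector goes through :func:`minimum_image` before any distance or direction is
computed.  Segment rest lengths are well below half the box edge, which makes
the minimum-image convention unambiguous for all intra-segment geometry.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "minimum_image",
    "wrap_xy",
    "segment_closest_points",
    "midpoint_cell_pairs",
]


def minimum_image(delta: np.ndarray, l_xy: float) -> np.ndarray:
    """Map displacement vectors to their periodic minimum image in x and y.

    Parameters
    ----------
    delta : (..., 3) array
        Raw displacement vectors ``r_b - r_a``.
    l_xy : float
        Periodic box edge in x and y (μm).  z is untouched.
    """
    out = np.array(delta, dtype=float, copy=True)
    out[..., 0] -= l_xy * np.round(out[..., 0] / l_xy)
    out[..., 1] -= l_xy * np.round(out[..., 1] / l_xy)
    return out


def wrap_xy(positions: np.ndarray, l_xy: float) -> np.ndarray:
    """Wrap x,y coordinates into [0, l_xy); idempotent."""
    out = np.array(positions, dtype=float, copy=True)
    for k in (0, 1):
        out[..., k] %= l_xy
        # float modulo of a tiny negative value returns exactly l_xy
        out[..., k] = np.where(out[..., k] >= l_xy, 0.0, out[..., k])
    return out


def segment_closest_points(
    p1: np.ndarray,
    d1: np.ndarray,
    p2: np.ndarray,
    d2: np.ndarray,
    l_xy: float,
):
    """Closest approach between segment pairs ``p1 + t*d1`` and ``p2 + s*d2``.

    Vectorized version of the standard clamped quadratic minimization
    (Ericson, *Real-Time Collision Detection*, §5.1.9) with the x/y periodic
    minimum image applied to the inter-segment offset.

    Returns
    -------
    dist : (n,) array
        Minimum distance between the segments.
    t, s : (n,) arrays
        Arc coordinates in [0, 1] of the closest points on segments 1 and 2.
    sep : (n, 3) array
        Vector from the closest point on segment 1 to the one on segment 2
        (minimum image).
    """
    p1 = np.atleast_2d(p1)
    d1 = np.atleast_2d(d1)
    p2 = np.atleast_2d(p2)
    d2 = np.atleast_2d(d2)
    r = minimum_image(p1 - p2, l_xy)

    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    b = np.einsum("ij,ij->i", d1, d2)
    c = np.einsum("ij,ij->i", d1, r)
    f = np.einsum("ij,ij->i", d2, r)

    eps = 1e-14
    denom = a * e - b * b
    # Initial t on segment 1 for infinite lines; parallel pairs fall back to 0.
    t = np.where(denom > eps, np.clip((b * f - c * e) / np.where(denom > eps, denom, 1.0), 0.0, 1.0), 0.0)
    # s given t, clamped; then recompute t given clamped s, clamp again.
    s = np.clip((b * t + f) / np.where(e > eps, e, 1.0), 0.0, 1.0)
    t = np.clip((b * s - c) / np.where(a > eps, a, 1.0), 0.0, 1.0)
    # One more s refinement keeps corner cases (both clamps active) exact.
    s = np.clip((b * t + f) / np.where(e > eps, e, 1.0), 0.0, 1.0)

    c1 = p1 + t[:, None] * d1
    c2 = p2 + s[:, None] * d2
    sep = minimum_image(c2 - c1, l_xy)
    dist = np.linalg.norm(sep, axis=1)
    return dist, t, s, sep


def midpoint_cell_pairs(midpoints: np.ndarray, cutoff: float, l_xy: float, l_z: float):
    """Candidate index pairs whose midpoints are within ``cutoff`` (periodic x/y).

    Backed by a k-d tree with a periodic box: x,y wrap at l_xy while the z
    period is padded far beyond the data so it never engages.  Returns an
    (m, 2) int array with i < j and no duplicates.
    """
    n = len(midpoints)
    if n < 2:
        return np.empty((0, 2), dtype=np.intp)
    pts = np.array(midpoints, dtype=float)
    pts[:, 0] %= l_xy
    pts[:, 1] %= l_xy
    z_pad = 2.0 * l_z + 4.0 * cutoff
    pts[:, 2] = np.clip(pts[:, 2], 0.0, z_pad - 1e-9)
    tree = cKDTree(pts, boxsize=[l_xy, l_xy, z_pad])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.intp)
    lo = np.minimum(pairs[:, 0], pairs[:, 1])
    hi = np.maximum(pairs[:, 0], pairs[:, 1])
    order = np.lexsort((hi, lo))
    return np.stack([lo[order], hi[order]], axis=1).astype(np.intp)
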