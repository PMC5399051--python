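"""Planar shape-geometry primitives shared across the package.

Everything here operates on bare ``(k, 2)`` float arrays.  Higher-level
modules wrap these functions with metadata-carrying types; keeping the
arithmetic in one place lets the I/O layer (bilateral merging) and the
superimposition layer share a single rotation/centering implementation
without circular imports.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "DegenerateConfigurationError",
    "as_points",
    "centroid",
    "centroid_size",
    "preshape",
    "rotation_onto",
    "procrustes_distance",
]


class DegenerateConfigurationError(ValueError):
    """Raised when a landmark configuration has no usable geometry.

    A configuration with all landmarks coincident has centroid size zero and
    cannot be scaled; a rank-deficient (collinear) configuration leaves the
    optimal rotation underdetermined.
    """


def as_points(points) -> np.ndarray:
    """Coerce to a ``(k, 2)`` float array, validating shape and finiteness."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected a (k, 2) coordinate array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("landmark coordinates must all be finite")
    return arr


def centroid(points) -> np.ndarray:
    return as_points(points).mean(axis=0)


def centroid_size(points) -> float:
    """Square root of the summed squared distances of landmarks from their centroid."""
    pts = as_points(points)
    centred = pts - pts.mean(axis=0)
    size = float(np.sqrt((centred**2).sum()))
    if size == 0.0:
        raise DegenerateConfigurationError(
            "all landmarks coincide; centroid size 0 cannot be normalized"
        )
    return size


def preshape(points) -> np.ndarray:
    """Center at the origin and scale to unit centroid size."""
    pts = as_points(points)
    centred = pts - pts.mean(axis=0)
    size = float(np.sqrt((centred**2).sum()))
    if size == 0.0:
        raise DegenerateConfigurationError(
            "all landmarks coincide; centroid size 0 cannot be normalized"
        )
    return centred / size


def rotation_onto(source, target) -> tuple[np.ndarray, float]:
    """Proper rotation of ``source`` onto ``target`` minimizing summed squared distance.

    Returns ``(R, rss)`` where ``source @ R.T`` is the rotated configuration and
    ``rss`` the minimized residual sum of squares.  Reflections are never
    produced (``det R = +1``); mirroring is an explicit I/O-level operation.
    """
    src = as_points(source)
    tgt = as_points(target)
    if src.shape != tgt.shape:
        raise ValueError(f"landmark counts differ: {src.shape[0]} vs {tgt.shape[0]}")
    a = float(np.sum(src * tgt))
    b = float(np.sum(src[:, 0] * tgt[:, 1] - src[:, 1] * tgt[:, 0]))
    norm = math.hypot(a, b)
    if norm == 0.0:
        # orthogonal shapes: every rotation is equally (un)good; fix identity
        rot = np.eye(2)
    else:
        c, s = a / norm, b / norm
        rot = np.array([[c, -s], [s, c]])
    rss = float(((src @ rot.T - tgt) ** 2).sum())
    return rot, rss


def procrustes_distance(p, q) -> float:
    """Partial Procrustes distance between the shapes of two configurations.

    Both inputs are reduced to preshape (centred, unit centroid size) and one
    is optimally rotated onto the other; the distance is the root of the
    residual sum of squares.  Zero iff the configurations are similar
    (translation + scaling + rotation).
    """
    zp = preshape(p)
    zq = preshape(q)
    _, rss = rotation_onto(zp, zq)
    return math.sqrt(max(rss, 0.0))
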