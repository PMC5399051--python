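"""Ordinary and generalized Procrustes superimposition.

The generalized fit follows the orthogonal least-squares scheme standard in
geometric morphometrics: every configuration is centred and scaled to unit
centroid size (a *partial* fit — no further rescaling against the consensus),
then iteratively rotated onto a consensus that is re-estimated as the
landmark-wise mean, re-centred and re-normalized, until the summed squared
deviation stops decreasing.  Only shape is retained; centroid size is kept as
metadata and never enters the downstream statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import landmarks_io
from ._geometry import (
    DegenerateConfigurationError,
    as_points,
    preshape,
    procrustes_distance,
    rotation_onto,
)
from ._geometry import centroid_size as _centroid_size_arr

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedShape",
    "GpaResult",
    "centroid_size",
    "optimal_rotation",
    "gpa",
    "project_tangent",
    "procrustes_distance",
    "write_aligned_table",
]


@dataclass(frozen=True)
class AlignedShape:
    """Procrustes shape coordinates of one wing.

    ``coords`` are dimensionless: centred at the origin and at unit centroid
    size, rotated into the consensus frame.  ``centroid_size`` preserves the
    size of the raw configuration in input length units as metadata.
    """

    coords: np.ndarray
    centroid_size: float
    specimen_id: str = ""
    taxon: str | None = None

    def __post_init__(self):
        coords = as_points(self.coords)
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        c = coords.mean(axis=0)
        if np.abs(c).max() > 1e-9:
            raise ValueError("aligned coordinates must be centred at the origin")
        if abs(float(np.sqrt((coords**2).sum())) - 1.0) > 1e-9:
            raise ValueError("aligned coordinates must have unit centroid size")

    @property
    def flat(self) -> np.ndarray:
        """Coordinates flattened to a ``(2k,)`` vector (x1, y1, x2, y2, ...)."""
        return self.coords.reshape(-1)


@dataclass
class GpaResult:
    """Outcome of a generalized Procrustes fit."""

    shapes: list[AlignedShape]
    consensus: np.ndarray
    objective: float
    n_iterations: int
    converged: bool

    def coordinate_matrix(self) -> np.ndarray:
        """``(n, 2k)`` matrix of flattened aligned coordinates, input order."""
        return np.array([s.flat for s in self.shapes])

    def labels(self) -> list[str | None]:
        return [s.taxon for s in self.shapes]


def _points_of(config) -> np.ndarray:
    return as_points(getattr(config, "points", config))


def centroid_size(config) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    return _centroid_size_arr(_points_of(config))


def optimal_rotation(source, target) -> tuple[np.ndarray, float]:
    """Least-squares proper rotation of ``source`` onto ``target``.

    Both configurations should already be centred and at unit centroid size;
    returns ``(R, rss)`` with ``det R = +1`` and ``rss`` the squared partial
    Procrustes distance.  Reflections are never introduced here — chirality
    is handled only by :func:`wingid.landmarks_io.reflect`.
    """
    src = _points_of(source)
    tgt = _points_of(target)
    for name, arr in (("source", src), ("target", tgt)):
        svals = np.linalg.svd(arr - arr.mean(axis=0), compute_uv=False)
        if svals[0] == 0.0:
            raise DegenerateConfigurationError(f"{name} configuration is degenerate (rank 0)")
    return rotation_onto(src, tgt)


def gpa(configs, tol: float = 1e-10, max_iter: int = 100) -> GpaResult:
    """Generalized Procrustes alignment of two or more configurations.

    Each configuration is centred and scaled to unit centroid size; the
    consensus is initialized as the first configuration and then the scheme
    alternates rotating every configuration onto the consensus with
    re-estimating the consensus as the re-centred, re-normalized landmark-wise
    mean, until the decrease of the summed squared deviation falls below
    ``tol`` or ``max_iter`` is reached.  The objective is non-increasing by
    construction and asserted so every iteration.

    Output order matches input order.  If ``max_iter`` is exhausted the
    result is returned with ``converged=False`` and a warning, never silently.
    """
    configs = list(configs)
    if len(configs) < 2:
        raise ValueError(f"GPA needs at least 2 configurations, got {len(configs)}")
    points = [_points_of(c) for c in configs]
    k = points[0].shape[0]
    for idx, pts in enumerate(points):
        if pts.shape[0] != k:
            raise ValueError(
                f"configuration {idx} has {pts.shape[0]} landmarks, expected {k}"
            )
    sizes = [_centroid_size_arr(pts) for pts in points]
    shapes = np.array([preshape(pts) for pts in points])
    n = len(shapes)

    consensus = shapes[0].copy()
    prev_objective = np.inf
    objective = np.inf
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        for i in range(n):
            rot, _ = rotation_onto(shapes[i], consensus)
            shapes[i] = shapes[i] @ rot.T
        mean = shapes.mean(axis=0)
        mean -= mean.mean(axis=0)
        norm = float(np.sqrt((mean**2).sum()))
        if norm == 0.0:
            raise DegenerateConfigurationError("consensus degenerated to a point during GPA")
        consensus = mean / norm
        objective = float(((shapes - consensus) ** 2).sum())
        # least-squares steps can only lower the objective; anything else is a bug
        assert objective <= prev_objective + 1e-12 * (1.0 + abs(objective)), (
            f"GPA objective increased from {prev_objective} to {objective}"
        )
        if prev_objective - objective < tol:
            converged = True
            break
        prev_objective = objective
    if not converged:
        warnings.warn(
            f"GPA did not converge within {max_iter} iterations "
            f"(last objective decrease {prev_objective - objective:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )

    aligned = [
        AlignedShape(
            coords=shapes[i],
            centroid_size=sizes[i],
            specimen_id=getattr(configs[i], "specimen_id", f"specimen_{i}"),
            taxon=getattr(configs[i], "taxon", None),
        )
        for i in range(n)
    ]
    return GpaResult(
        shapes=aligned,
        consensus=consensus,
        objective=objective,
        n_iterations=iteration,
        converged=converged,
    )


def project_tangent(gpa_result: GpaResult) -> np.ndarray:
    """Orthogonal projection of aligned coordinates onto the tangent space.

    The shape space of unit-size configurations is curved; for linear
    multivariate statistics the aligned shapes can be projected onto the
    tangent plane at the consensus.  With flattened unit vectors ``x`` and
    consensus ``c`` the projection is ``x - (x·c - 1) c``: the component of
    the deviation along ``c`` is removed.  The consensus maps to itself and
    for shapes close to the consensus the change is second order, which is
    why the pipeline leaves the projection off by default.

    Returns an ``(n, 2k)`` matrix in the input order of the fit.
    """
    c = gpa_result.consensus.reshape(-1)
    X = gpa_result.coordinate_matrix()
    return X - np.outer(X @ c - 1.0, c)


def tangent_project_vector(x: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Project a single flattened unit-size shape vector onto the tangent plane."""
    c = consensus.reshape(-1)
    return x - (float(x @ c) - 1.0) * c


def write_aligned_table(gpa_result: GpaResult, stream) -> None:
    """Export aligned shapes in the delimited-table dialect, flagged aligned."""
    configs = [
        landmarks_io.LandmarkConfiguration(
            points=s.coords, specimen_id=s.specimen_id, taxon=s.taxon, side="merged"
        )
        for s in gpa_result.shapes
    ]
    landmarks_io.write_table(configs, stream, aligned=True)
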