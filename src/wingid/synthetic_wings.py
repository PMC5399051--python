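"""Synthetic wing-landmark datasets with the statistical structure the
identification pipeline assumes.

The generator emulates a multi-taxon landmark study: per-taxon mean shapes
displaced from a common wing template, isotropic (or full-covariance)
Gaussian shape variation in the tangent space at the taxon mean, nuisance
similarity transforms (rotation, translation, scale) applied to the raw
coordinates, per-landmark digitization noise, and optional mirrored
left/right wing pairs per specimen.

All geometry is parameterized on the *preshape* scale (unit centroid size),
so ``within_sd`` and ``separation`` are in Procrustes shape units and the
physical size of the template only affects raw coordinates.  Every source of
randomness flows from one seeded generator, so identical spec + seed produce
byte-identical output files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from ._geometry import preshape
from .landmarks_io import LandmarkConfiguration, SpecimenRecord

__all__ = [
    "BASE_WING",
    "STUDY_TAXA",
    "SyntheticSpec",
    "shape_subspace",
    "make_taxon_means",
    "sample_dataset",
]

#: Stylized 15-landmark fly-wing template (coordinates in cm, wing length
#: ~0.9 cm).  Only the topology matters to the statistics: 15 well-spread,
#: non-collinear points laid out like the vein junctions and termini of a
#: muscid wing (costal/radial arc, crossveins, medial and cubital field).
BASE_WING = np.array(
    [
        (0.05, 0.05),
        (0.12, 0.10),
        (0.30, 0.16),
        (0.55, 0.18),
        (0.80, 0.14),
        (0.90, 0.05),
        (0.62, 0.05),
        (0.70, -0.02),
        (0.84, -0.01),
        (0.45, 0.02),
        (0.50, -0.08),
        (0.60, -0.12),
        (0.28, -0.06),
        (0.30, -0.14),
        (0.12, -0.08),
    ],
    dtype=float,
)

#: Default study design: 13 taxa with the class sizes of the genus-level
#: reference study this package reproduces (790 specimens in total).
STUDY_TAXA: tuple[tuple[str, int], ...] = (
    ("Azelia", 14),
    ("Eudasyphora", 40),
    ("Graphomya", 17),
    ("Helina", 35),
    ("Hydrotaea", 318),
    ("Musca", 46),
    ("Muscina", 163),
    ("Mydaea", 14),
    ("Neomyia", 30),
    ("Phaonia", 45),
    ("Polietes", 8),
    ("Stomoxys", 32),
    ("Thricops", 28),
)


@dataclass
class SyntheticSpec:
    """Full parameterization of a simulated landmark study.

    Parameters
    ----------
    taxa
        ``(label, n_specimens)`` pairs; every taxon needs at least 2 specimens.
    base_shape
        ``(k, 2)`` wing template shared by all taxa.
    separation
        Magnitude of each taxon's mean shift from the template, in units of
        the within-taxon shape standard deviation (``within_sd``); either one
        value for all taxa or a per-taxon sequence (taxa given small values
        form closely related clusters).
    within_sd
        Isotropic per-dimension SD of shape variation in the tangent space at
        the taxon mean, in Procrustes units.
    within_cov
        Optional full ``(2k-4, 2k-4)`` covariance in tangent coordinates;
        overrides the isotropic ``within_sd`` for sampling (``within_sd``
        still sets the separation unit).
    rotation_range, translation_range, scale_range
        Uniform ranges of the nuisance similarity transform applied to each
        raw wing (degrees; length units; dimensionless factor).
    digitization_sd
        SD of iid Gaussian noise added to every raw coordinate, in length
        units (landmark click error).
    bilateral
        Emit a mirrored left wing with independent digitization noise and its
        own nuisance transform for every specimen.
    orthogonal_means
        Orthogonalize the taxon mean-shift directions across taxa.
    seed
        Seed of the single random generator all sampling flows from.
    """

    taxa: tuple[tuple[str, int], ...] = STUDY_TAXA
    base_shape: np.ndarray = field(default_factory=lambda: BASE_WING.copy())
    separation: float | tuple[float, ...] = 6.0
    within_sd: float = 0.003
    within_cov: np.ndarray | None = None
    rotation_range: tuple[float, float] = (-180.0, 180.0)
    translation_range: tuple[float, float] = (-0.5, 0.5)
    scale_range: tuple[float, float] = (0.9, 1.1)
    digitization_sd: float = 0.0004
    bilateral: bool = True
    orthogonal_means: bool = False
    seed: int = 0

    def __post_init__(self):
        self.taxa = tuple((str(lab), int(n)) for lab, n in self.taxa)
        if not self.taxa:
            raise ValueError("at least one taxon is required")
        for lab, n in self.taxa:
            if n < 2:
                raise ValueError(f"taxon '{lab}': need at least 2 specimens, got {n}")
        if np.isscalar(self.separation):
            self.separation = (float(self.separation),) * len(self.taxa)
        else:
            self.separation = tuple(float(s) for s in self.separation)
            if len(self.separation) != len(self.taxa):
                raise ValueError(
                    f"separation has {len(self.separation)} entries for {len(self.taxa)} taxa"
                )
        if min(self.separation) < 0:
            raise ValueError("separation must be non-negative")
        if self.within_sd < 0 or self.digitization_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.scale_range[0] <= 0 or self.scale_range[1] < self.scale_range[0]:
            raise ValueError("scale range must be positive and ordered")
        self.base_shape = np.asarray(self.base_shape, dtype=float)
        # template must itself be a valid configuration
        LandmarkConfiguration(points=self.base_shape, specimen_id="template")

    @property
    def n_landmarks(self) -> int:
        return self.base_shape.shape[0]

    @property
    def shape_dim(self) -> int:
        return 2 * self.n_landmarks - 4


def shape_subspace(mean: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the shape tangent space at a configuration.

    Shape space has ``2k - 4`` dimensions: from the ``2k`` raw coordinates,
    two translation directions, the scaling direction (the configuration
    itself, once centred) and the infinitesimal-rotation direction (each
    landmark moved perpendicular to its position vector) are removed.
    Returns a ``(2k, 2k-4)`` matrix with orthonormal columns spanning the
    complement of those four directions at ``mean``.
    """
    pts = preshape(mean)
    k = pts.shape[0]
    tx = np.zeros(2 * k)
    tx[0::2] = 1.0
    ty = np.zeros(2 * k)
    ty[1::2] = 1.0
    scale_dir = pts.reshape(-1)
    rot_dir = np.column_stack([-pts[:, 1], pts[:, 0]]).reshape(-1)
    nuisance = np.vstack([tx, ty, scale_dir, rot_dir])
    basis = null_space(nuisance)
    if basis.shape[1] != 2 * k - 4:
        raise ValueError("degenerate configuration: nuisance directions are not independent")
    return basis


def make_taxon_means(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
    """Per-taxon mean configurations: template plus a tangent-space shift.

    Each taxon mean is ``base + separation * within_sd * u`` on the preshape
    scale, with ``u`` a random unit direction in the ``2k-4``-dimensional
    shape subspace at the template (orthogonalized across taxa when
    ``spec.orthogonal_means``), then mapped back to the template's physical
    size and centroid.  Deterministic under ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    base = spec.base_shape
    base_centroid = base.mean(axis=0)
    base_size = float(np.sqrt(((base - base_centroid) ** 2).sum()))
    base_pre = preshape(base)
    basis = shape_subspace(base)
    d = basis.shape[1]
    g = len(spec.taxa)
    directions = rng.standard_normal((d, g))
    if spec.orthogonal_means:
        if g > d:
            raise ValueError(f"cannot orthogonalize {g} mean directions in {d} dimensions")
        directions, _ = np.linalg.qr(directions)
    directions /= np.linalg.norm(directions, axis=0, keepdims=True)

    base_min_dist = _min_pairwise_distance(base_pre)
    means: dict[str, np.ndarray] = {}
    for (label, _), sep, u in zip(spec.taxa, spec.separation, directions.T):
        shift_norm = sep * spec.within_sd
        shift = (basis @ u).reshape(-1, 2) * shift_norm
        mean_pre = base_pre + shift
        # crossing heuristic: the shift rivals the closest landmark spacing, or
        # two landmarks of the (renormalized) mean have drifted onto each other
        crossing_risk = shift_norm > base_min_dist or (
            _min_pairwise_distance(preshape(mean_pre)) < 0.5 * base_min_dist
        )
        if crossing_risk:
            warnings.warn(
                f"taxon '{label}': mean shift {sep} x {spec.within_sd} brings "
                "landmarks close to crossing; the wing outline may self-intersect",
                RuntimeWarning,
                stacklevel=2,
            )
        means[label] = mean_pre * base_size + base_centroid
    return means


def _min_pairwise_distance(points: np.ndarray) -> float:
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    return float(dist[np.triu_indices(points.shape[0], k=1)].min())


def _similarity_transform(points: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    theta = np.deg2rad(rng.uniform(*spec.rotation_range))
    s = rng.uniform(*spec.scale_range)
    t = rng.uniform(spec.translation_range[0], spec.translation_range[1], size=2)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return s * points @ rot.T + t


def sample_dataset(spec: SyntheticSpec) -> list[SpecimenRecord]:
    """Draw a full labelled dataset of specimen records from ``spec``.

    Each specimen's true shape is its taxon mean plus Gaussian tangent-space
    noise; the raw right wing is that shape under a random similarity
    transform plus digitization noise, and (when ``spec.bilateral``) the left
    wing is the mirrored true shape under an independent transform and noise.
    The records are ready for :func:`wingid.landmarks_io.merge_sides` /
    serialization through ``landmarks_io``.
    """
    rng = np.random.default_rng(spec.seed)
    means = make_taxon_means(spec, rng)
    base_centroid = spec.base_shape.mean(axis=0)
    base_size = float(np.sqrt(((spec.base_shape - base_centroid) ** 2).sum()))
    d = spec.shape_dim
    chol = None
    if spec.within_cov is not None:
        cov = np.asarray(spec.within_cov, dtype=float)
        if cov.shape != (d, d):
            raise ValueError(f"within_cov must be ({d}, {d}), got {cov.shape}")
        chol = np.linalg.cholesky(cov)

    records: list[SpecimenRecord] = []
    for label, n in spec.taxa:
        mean = means[label]
        mean_pre = preshape(mean)
        basis = shape_subspace(mean)
        for i in range(n):
            z = rng.standard_normal(d)
            z = chol @ z if chol is not None else spec.within_sd * z
            true_pre = mean_pre + (basis @ z).reshape(-1, 2)
            true_raw = true_pre * base_size + base_centroid
            specimen_id = f"{label}_{i:03d}"

            right_pts = _similarity_transform(true_raw, spec, rng)
            right_pts = right_pts + spec.digitization_sd * rng.standard_normal(right_pts.shape)
            right = LandmarkConfiguration(
                points=right_pts, specimen_id=specimen_id, taxon=label, side="right"
            )
            left = None
            if spec.bilateral:
                mirrored = np.column_stack([-true_raw[:, 0], true_raw[:, 1]])
                left_pts = _similarity_transform(mirrored, spec, rng)
                left_pts = left_pts + spec.digitization_sd * rng.standard_normal(left_pts.shape)
                left = LandmarkConfiguration(
                    points=left_pts, specimen_id=specimen_id, taxon=label, side="left"
                )
            records.append(
                SpecimenRecord(specimen_id=specimen_id, taxon=label, left=left, right=right)
            )
    return records
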