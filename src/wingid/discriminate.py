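"""Group discrimination in shape space.

Implements the multivariate core of landmark-based identification:

* Wilks' lambda MANOVA with Rao's F approximation (exact for two groups or a
  single variable),
* canonical variate analysis (CVA) on the pooled within-group principal
  subspace,
* Mahalanobis nearest-mean classification (equivalent to a linear
  discriminant with equal priors), and
* chi-square typicality probabilities flagging specimens that resemble no
  training taxon, or more than one.

Aligned Procrustes coordinates of k 2-D landmarks carry at most 2k-4 true
shape dimensions and the pooled covariance is therefore singular in the raw
coordinate space.  All statistics are computed on the principal subspace of
the pooled within-group covariance: components with relative eigenvalue above
``rel_tol`` are kept, capped at ``max_rank`` (``min(n-g, 2k-4)`` for shape
coordinates; pipeline callers pass the cap explicitly).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._geometry import preshape, rotation_onto
from .superimposition import AlignedShape, tangent_project_vector

logger = logging.getLogger(__name__)

__all__ = [
    "ManovaResult",
    "CvaModel",
    "ClassificationResult",
    "wilks_manova",
    "fit_cva",
    "classify",
    "typicality",
    "save_reference_set",
    "load_reference_set",
]

REFERENCE_FORMAT = "wingid-reference-1"


@dataclass(frozen=True)
class ManovaResult:
    """Wilks' lambda test of equal group mean shapes."""

    wilks_lambda: float
    log_wilks_lambda: float
    f_stat: float
    df1: float
    df2: float
    p_value: float
    n_variables: int
    n_groups: int


@dataclass
class CvaModel:
    """Trained canonical-variate / Mahalanobis classifier.

    ``basis`` holds the orthonormal principal axes of the pooled within-group
    covariance (the subspace in which that covariance is inverted);
    ``within_eigvals`` the corresponding pooled variances, so the covariance
    is diagonal in basis coordinates.  ``canonical_axes`` are scaled so
    training scores have unit pooled within-group variance per axis, and
    ``eigenvalues`` are the between/within generalized eigenvalues on the
    cross-product scale (so Wilks' lambda factorizes as prod 1/(1+l_i)).
    """

    class_labels: list[str]
    grand_mean: np.ndarray  # (p,)
    basis: np.ndarray  # (p, r), orthonormal columns
    within_eigvals: np.ndarray  # (r,), pooled covariance eigenvalues
    canonical_axes: np.ndarray  # (p, r'), ambient-space axis vectors
    eigenvalues: np.ndarray  # (r',), descending
    class_means: np.ndarray  # (g, p), ambient-space class means
    class_means_cv: np.ndarray  # (g, r'), class means in canonical space
    pooled_cov_rank: int
    n_per_class: list[int]
    consensus: np.ndarray | None = None  # (k, 2) training consensus shape
    tangent: bool = False

    @property
    def n_landmarks(self) -> int | None:
        return None if self.consensus is None else self.consensus.shape[0]


@dataclass(frozen=True)
class ClassificationResult:
    """Per-specimen identification output."""

    specimen_id: str
    predicted: str
    distances: dict[str, float]  # squared Mahalanobis distance per class
    typicality: dict[str, float]  # chi-square upper-tail probability per class
    ambiguous: bool


def _group_stats(X: np.ndarray, labels) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Class labels in order of first appearance, class means, W and B cross-products."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D data matrix (specimens x variables)")
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("number of labels must match number of rows")
    class_labels: list[str] = []
    for lab in labels:
        if lab is None:
            raise ValueError("every training specimen needs a taxon label")
        if lab not in class_labels:
            class_labels.append(lab)
    if len(class_labels) < 2:
        raise ValueError("need at least 2 classes")
    groups = [np.flatnonzero([l == lab for l in labels]) for lab in class_labels]
    for lab, idx in zip(class_labels, groups):
        if idx.size < 2:
            raise ValueError(f"class '{lab}' has {idx.size} specimen(s); at least 2 required")
    means = np.array([X[idx].mean(axis=0) for idx in groups])
    grand = X.mean(axis=0)
    p = X.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for mean, idx in zip(means, groups):
        dev = X[idx] - mean
        W += dev.T @ dev
        B += idx.size * np.outer(mean - grand, mean - grand)
    return class_labels, means, W, B


def _coordinate_matrix(shapes) -> tuple[np.ndarray, list, int | None]:
    """Accept an array, a GpaResult, or a list of AlignedShape."""
    if hasattr(shapes, "coordinate_matrix"):  # GpaResult
        return shapes.coordinate_matrix(), shapes.labels(), shapes.consensus.shape[0]
    if len(shapes) and isinstance(shapes[0], AlignedShape):
        X = np.array([s.flat for s in shapes])
        return X, [s.taxon for s in shapes], shapes[0].coords.shape[0]
    return np.asarray(shapes, dtype=float), None, None


def _within_subspace(
    W: np.ndarray, n: int, g: int, max_rank: int | None, rel_tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Principal subspace of the pooled within-group covariance.

    Returns orthonormal ``basis (p, r)`` and pooled covariance eigenvalues
    ``(r,)`` (descending), keeping eigenvalues above ``rel_tol`` times the
    largest and at most ``max_rank`` components.
    """
    cov = W / (n - g)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[0] <= 0.0:
        raise ValueError("pooled within-group covariance is zero; no within-group variation")
    cap = min(n - g, W.shape[0])
    if max_rank is not None:
        cap = min(cap, max_rank)
    keep = int(np.sum(evals > rel_tol * evals[0]))
    r = max(1, min(keep, cap))
    return evecs[:, :r], evals[:r]


def wilks_manova(shapes, labels=None, *, max_rank: int | None = None, rel_tol: float = 1e-10) -> ManovaResult:
    """Wilks' lambda MANOVA of group mean differences in shape space.

    ``shapes`` may be a GpaResult, a list of AlignedShape (labels taken from
    their taxa unless given), or a bare ``(n, p)`` matrix with ``labels``.
    Variables are reduced to the pooled within-group principal subspace (the
    same reduction CVA uses) so the total scatter is nonsingular; there
    ``lambda = det(W) / det(W + B)``, computed stably through the generalized
    between/within eigenvalues, with Rao's F approximation (exact for two
    groups or one variable).
    """
    X, inferred_labels, k = _coordinate_matrix(shapes)
    if labels is None:
        labels = inferred_labels
    if labels is None:
        raise ValueError("labels are required with a bare coordinate matrix")
    if max_rank is None and k is not None:
        max_rank = 2 * k - 4
    class_labels, _, W, B = _group_stats(X, labels)
    n, g = X.shape[0], len(class_labels)
    basis, w_evals = _within_subspace(W, n, g, max_rank, rel_tol)
    lam = _between_within_eigvals(W, B, basis, w_evals, n, g)[0]
    p_red = basis.shape[1]
    log_lambda = -float(np.sum(np.log1p(lam)))
    return _rao_f(log_lambda, p_red, g, n)


def _between_within_eigvals(W, B, basis, w_evals, n, g):
    """Generalized eigenvalues/vectors of B v = l W v inside the basis subspace.

    ``basis`` diagonalizes the pooled covariance, so the within cross-product
    matrix restricted to the subspace is diagonal and the problem reduces to
    an ordinary symmetric eigenproblem after whitening.  Returns descending
    eigenvalues (cross-product scale) and subspace eigenvectors ``v`` with
    ``v^T (W/(n-g)) v = I`` (unit pooled within-group variance of scores).
    """
    scale = 1.0 / np.sqrt((n - g) * w_evals)
    Bw = (basis * scale).T @ B @ (basis * scale)
    Bw = 0.5 * (Bw + Bw.T)
    lam, U = np.linalg.eigh(Bw)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    V = (U[:, order].T * scale).T  # v = diag(scale) u, columns
    V = V * math.sqrt(n - g)  # unit pooled within-group *covariance* of scores
    return lam, V


def _rao_f(log_lambda: float, p: int, g: int, n: int) -> ManovaResult:
    """Rao's F transformation of Wilks' lambda."""
    df1 = p * (g - 1)
    denom = p**2 + (g - 1) ** 2 - 5
    t = math.sqrt((p**2 * (g - 1) ** 2 - 4) / denom) if denom > 0 else 1.0
    m = n - 1 - (p + g) / 2.0
    df2 = m * t - df1 / 2.0 + 1.0
    if df2 <= 0:
        raise ValueError(
            f"too few specimens (n={n}) for {p} variables and {g} groups: Rao df2 <= 0"
        )
    l_root = math.exp(log_lambda / t)
    f_stat = (1.0 - l_root) / l_root * df2 / df1
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return ManovaResult(
        wilks_lambda=math.exp(log_lambda),
        log_wilks_lambda=log_lambda,
        f_stat=f_stat,
        df1=df1,
        df2=df2,
        p_value=p_value,
        n_variables=p,
        n_groups=g,
    )


def fit_cva(
    shapes,
    labels=None,
    *,
    consensus: np.ndarray | None = None,
    tangent: bool = False,
    max_rank: int | None = None,
    rel_tol: float = 1e-10,
) -> CvaModel:
    """Fit a canonical variate / Mahalanobis model to labelled shapes.

    Steps: pooled within-group covariance of the coordinates; restriction to
    its principal subspace (eigenvalue > ``rel_tol`` x largest, at most
    ``max_rank`` components, never more than ``n - g``); generalized
    between/within eigenproblem in that subspace; axes scaled to unit pooled
    within-group variance of training scores; class means stored both in
    ambient coordinates and in canonical space.
    """
    X, inferred_labels, k = _coordinate_matrix(shapes)
    if labels is None:
        labels = inferred_labels
    if labels is None:
        raise ValueError("labels are required with a bare coordinate matrix")
    if consensus is None and hasattr(shapes, "consensus"):
        consensus = shapes.consensus
    if max_rank is None and k is not None:
        max_rank = 2 * k - 4
    class_labels, means, W, B = _group_stats(X, labels)
    n, g = X.shape[0], len(class_labels)
    if n - g < 2:
        raise ValueError(f"need n - g >= 2 residual degrees of freedom, got {n - g}")
    basis, w_evals = _within_subspace(W, n, g, max_rank, rel_tol)
    lam, V = _between_within_eigvals(W, B, basis, w_evals, n, g)
    n_axes = min(g - 1, basis.shape[1])
    lam = lam[:n_axes]
    V = V[:, :n_axes]
    if lam.size and lam[0] < 1e-8:
        logger.warning("all class means coincide: leading canonical eigenvalue %.3e", lam[0])
    grand_mean = X.mean(axis=0)
    axes_ambient = basis @ V  # (p, r')
    class_means_cv = (means - grand_mean) @ axes_ambient
    # C-contiguous copies: a JSON save/load round trip then reproduces every
    # classification bit-for-bit (summation order depends on memory layout)
    return CvaModel(
        class_labels=class_labels,
        grand_mean=np.ascontiguousarray(grand_mean),
        basis=np.ascontiguousarray(basis),
        within_eigvals=np.ascontiguousarray(w_evals),
        canonical_axes=np.ascontiguousarray(axes_ambient),
        eigenvalues=np.ascontiguousarray(lam),
        class_means=np.ascontiguousarray(means),
        class_means_cv=np.ascontiguousarray(class_means_cv),
        pooled_cov_rank=basis.shape[1],
        n_per_class=[int(sum(1 for l in labels if l == lab)) for lab in class_labels],
        consensus=None if consensus is None else np.asarray(consensus, dtype=float),
        tangent=tangent,
    )


def _to_model_frame(model: CvaModel, shape) -> tuple[str, np.ndarray]:
    """Bring a query into the model's aligned coordinate frame.

    Raw configurations (``LandmarkConfiguration`` or a ``(k, 2)`` array) are
    centred, scaled to unit centroid size, and rotated onto the training
    consensus; already-aligned shapes are re-rotated (a near no-op) for
    safety.  A flat ``(p,)`` vector is taken to be in the model frame
    already.
    """
    if shape is None:
        raise TypeError("query shape is None (was the specimen record merged?)")
    specimen_id = getattr(shape, "specimen_id", "")
    pts = getattr(shape, "coords", None)
    if pts is None:
        pts = getattr(shape, "points", shape)
    arr = np.asarray(pts, dtype=float)
    if arr.ndim not in (1, 2):
        raise ValueError(f"query must be a (k, 2) configuration or flat vector, got shape {arr.shape}")
    if arr.ndim == 1:
        if arr.shape[0] != model.grand_mean.shape[0]:
            raise ValueError(
                f"flat query has {arr.shape[0]} variables, model expects {model.grand_mean.shape[0]}"
            )
        return specimen_id, arr
    if model.consensus is None:
        raise ValueError(
            "model was fitted without a consensus shape; pass a flat aligned vector instead"
        )
    if arr.shape != model.consensus.shape:
        raise ValueError(
            f"query has {arr.shape[0]} landmarks, model expects {model.consensus.shape[0]}"
        )
    z = preshape(arr)
    rot, _ = rotation_onto(z, model.consensus)
    x = (z @ rot.T).reshape(-1)
    if model.tangent:
        x = tangent_project_vector(x, model.consensus)
    return specimen_id, x


def _mahalanobis_sq(model: CvaModel, x: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of ``x`` to each class mean.

    The pooled within-group covariance is diagonal in basis coordinates, so
    the distance restricted to the retained subspace is a scaled Euclidean
    norm there.
    """
    z = (x - model.grand_mean) @ model.basis
    zc = (model.class_means - model.grand_mean) @ model.basis
    diff = z - zc
    return (diff**2 / model.within_eigvals).sum(axis=1)


def classify(
    model: CvaModel,
    shape,
    *,
    typicality_low: float = 0.01,
    typicality_high: float = 0.05,
) -> ClassificationResult:
    """Assign a specimen to the nearest class mean in Mahalanobis distance.

    Equal priors: with a pooled covariance this is the standard linear
    discriminant assignment.  Ties go to the first class in training label
    order and are logged.  Typicality probabilities and the ambiguity flag
    follow :func:`typicality`.
    """
    specimen_id, x = _to_model_frame(model, shape)
    d2 = _mahalanobis_sq(model, x)
    best = int(np.argmin(d2))
    if np.sum(d2 == d2[best]) > 1:
        logger.info(
            "specimen '%s': tied Mahalanobis distances; keeping first class '%s'",
            specimen_id,
            model.class_labels[best],
        )
    probs = stats.chi2.sf(d2, df=model.pooled_cov_rank)
    ambiguous = bool(probs.max() < typicality_low or np.sum(probs > typicality_high) >= 2)
    return ClassificationResult(
        specimen_id=specimen_id,
        predicted=model.class_labels[best],
        distances={lab: float(v) for lab, v in zip(model.class_labels, d2)},
        typicality={lab: float(v) for lab, v in zip(model.class_labels, probs)},
        ambiguous=ambiguous,
    )


def typicality(
    model: CvaModel,
    shape,
    *,
    low: float = 0.01,
    high: float = 0.05,
) -> tuple[dict[str, float], bool]:
    """Chi-square typicality probability of a specimen for every class.

    For each class the upper-tail probability of a chi-square with
    ``df = pooled_cov_rank`` at the specimen's squared Mahalanobis distance.
    The specimen is flagged ambiguous when it shows low similarity to all
    taxa (max p < ``low``) or high similarity to more than one taxon
    (p > ``high`` for two or more classes) — such outliers should be checked
    against conventional identification keys.
    """
    result = classify(model, shape, typicality_low=low, typicality_high=high)
    return result.typicality, result.ambiguous


# ---------------------------------------------------------------------------
# Reference-set serialization
# ---------------------------------------------------------------------------


def save_reference_set(model: CvaModel, path) -> None:
    """Write a trained model as a versioned JSON document.

    Floats are serialized with full ``repr`` precision, so a load/save round
    trip preserves classification outputs exactly.
    """
    doc = {
        "format": REFERENCE_FORMAT,
        "class_labels": model.class_labels,
        "grand_mean": model.grand_mean.tolist(),
        "basis": model.basis.tolist(),
        "within_eigvals": model.within_eigvals.tolist(),
        "canonical_axes": model.canonical_axes.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "class_means": model.class_means.tolist(),
        "class_means_cv": model.class_means_cv.tolist(),
        "pooled_cov_rank": model.pooled_cov_rank,
        "n_per_class": model.n_per_class,
        "consensus": None if model.consensus is None else model.consensus.tolist(),
        "tangent": model.tangent,
    }
    fh = open(path, "w") if not hasattr(path, "write") else path
    try:
        json.dump(doc, fh, indent=1)
    finally:
        if fh is not path:
            fh.close()


def load_reference_set(path) -> CvaModel:
    fh = open(path) if not hasattr(path, "read") else path
    try:
        doc = json.load(fh)
    finally:
        if fh is not path:
            fh.close()
    if doc.get("format") != REFERENCE_FORMAT:
        raise ValueError(f"unsupported reference-set format: {doc.get('format')!r}")
    return CvaModel(
        class_labels=list(doc["class_labels"]),
        grand_mean=np.array(doc["grand_mean"], dtype=float),
        basis=np.array(doc["basis"], dtype=float),
        within_eigvals=np.array(doc["within_eigvals"], dtype=float),
        canonical_axes=np.array(doc["canonical_axes"], dtype=float),
        eigenvalues=np.array(doc["eigenvalues"], dtype=float),
        class_means=np.array(doc["class_means"], dtype=float),
        class_means_cv=np.array(doc["class_means_cv"], dtype=float),
        pooled_cov_rank=int(doc["pooled_cov_rank"]),
        n_per_class=[int(v) for v in doc["n_per_class"]],
        consensus=None if doc["consensus"] is None else np.array(doc["consensus"], dtype=float),
        tangent=bool(doc["tangent"]),
    )
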