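"""Leave-one-out cross-validation and confusion-matrix summaries.

The confusion-matrix convention follows the published reference tables this
package reproduces: rows are the true taxon, columns the predicted taxon,
correct identifications on the diagonal.  Percentages are reported to one
decimal place, rounding halves away from zero.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np

from .discriminate import classify, fit_cva
from .superimposition import gpa, project_tangent

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "ConfusionSummary",
    "loo_cv",
    "summarize",
    "round_half_away",
    "load_reference_table",
    "REFERENCE_TABLES",
]

#: published leave-one-out confusion tables shipped as CSV fixtures
REFERENCE_TABLES = ("genus", "hydrotaea", "muscina")


@dataclass
class ConfusionMatrix:
    """Class-by-class leave-one-out counts (rows true, columns predicted)."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError(
                f"counts shape {counts.shape} does not match {len(self.labels)} labels"
            )
        if np.any(counts < 0):
            raise ValueError("confusion counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("confusion counts must be integers")
            counts = counts.astype(int)
        self.counts = counts

    @property
    def totals(self) -> np.ndarray:
        """Row sums: number of specimens per true class."""
        return self.counts.sum(axis=1)

    def to_csv(self, stream) -> None:
        fh = open(stream, "w") if not hasattr(stream, "write") else stream
        try:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["label", *self.labels])
            for lab, row in zip(self.labels, self.counts):
                writer.writerow([lab, *row.tolist()])
        finally:
            if fh is not stream:
                fh.close()

    @classmethod
    def from_csv(cls, stream) -> "ConfusionMatrix":
        fh = open(stream) if not hasattr(stream, "read") else stream
        try:
            rows = [r for r in csv.reader(fh) if r and not r[0].lstrip().startswith("#")]
        finally:
            if fh is not stream:
                fh.close()
        if not rows or rows[0][0].strip().lower() != "label":
            raise ValueError("confusion CSV must start with a 'label,<classes...>' header")
        labels = [lab.strip() for lab in rows[0][1:]]
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        if len(rows) - 1 != len(labels):
            raise ValueError(
                f"confusion CSV has {len(rows) - 1} data rows for {len(labels)} classes"
            )
        for i, row in enumerate(rows[1:]):
            if len(row) != len(labels) + 1:
                raise ValueError(f"confusion CSV row {i + 2}: wrong number of fields")
            if row[0].strip() != labels[i]:
                raise ValueError(
                    f"confusion CSV row {i + 2}: row label {row[0]!r} does not match "
                    f"column order {labels[i]!r}"
                )
            counts[i] = [int(v) for v in row[1:]]
        return cls(labels=labels, counts=counts)


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round with halves away from zero (the convention of the reference tables)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionSummary:
    """Percent summaries of a confusion matrix, rounded to one decimal."""

    labels: list[str]
    per_class_percent: dict[str, float]
    per_class_misidentified_percent: dict[str, float]
    misidentification_percent: dict[tuple[str, str], float]
    overall_percent: float
    correct_count: int
    total_count: int
    per_class_percent_raw: dict[str, float] = field(repr=False, default_factory=dict)
    overall_percent_raw: float = field(repr=False, default=0.0)


def summarize(confusion: ConfusionMatrix) -> ConfusionSummary:
    """Per-class percent correct, per-cell misidentification percents, overall percent.

    Per-class percent is ``100 x diagonal / row total``; each off-diagonal
    cell is reported as ``100 x cell / row total``; the overall percent is
    ``100 x trace / grand total``.  The overall percent equals the
    class-size-weighted mean of the per-class percents (verified before
    rounding).
    """
    counts = confusion.counts
    totals = confusion.totals
    if np.any(totals == 0):
        empty = confusion.labels[int(np.argmin(totals))]
        raise ValueError(f"class '{empty}' has zero specimens; percentages undefined")
    diag = np.diag(counts)
    per_class_raw = {
        lab: 100.0 * d / t for lab, d, t in zip(confusion.labels, diag, totals)
    }
    overall_raw = 100.0 * diag.sum() / totals.sum()
    weighted = sum(per_class_raw[lab] * t for lab, t in zip(confusion.labels, totals))
    assert abs(weighted / totals.sum() - overall_raw) < 1e-9
    misid = {}
    for i, true_lab in enumerate(confusion.labels):
        for j, pred_lab in enumerate(confusion.labels):
            if i != j and counts[i, j]:
                misid[(true_lab, pred_lab)] = round_half_away(
                    100.0 * counts[i, j] / totals[i]
                )
    return ConfusionSummary(
        labels=list(confusion.labels),
        per_class_percent={lab: round_half_away(v) for lab, v in per_class_raw.items()},
        per_class_misidentified_percent={
            lab: round_half_away(100.0 * (t - d) / t)
            for lab, d, t in zip(confusion.labels, diag, totals)
        },
        misidentification_percent=misid,
        overall_percent=round_half_away(overall_raw),
        correct_count=int(diag.sum()),
        total_count=int(totals.sum()),
        per_class_percent_raw=per_class_raw,
        overall_percent_raw=overall_raw,
    )


def loo_cv(dataset, pipeline_config=None) -> ConfusionMatrix:
    """Leave-one-out cross-validation of the shape-identification pipeline.

    ``dataset`` is a sequence of labelled merged-wing configurations (or
    specimen records, in which case their ``merged`` shapes are used).  By
    default the Procrustes superimposition is computed once on the full
    sample and each fold refits only the canonical-variate model on the
    remaining specimens; with ``pipeline_config.loo_resuperimpose`` the
    superimposition itself is redone per fold and the held-out specimen is
    aligned onto the fold consensus before classification.

    Counts accumulate in the order classes first appear in the input.
    """
    from .pipeline import PipelineConfig  # deferred: avoids a module cycle

    from .landmarks_io import SpecimenRecord, merge_sides

    cfg = pipeline_config or PipelineConfig()
    configs = []
    for item in dataset:
        if isinstance(item, SpecimenRecord):
            configs.append(item.merged if item.merged is not None else merge_sides(item))
        else:
            configs.append(item)
    labels = [c.taxon for c in configs]
    class_labels: list[str] = []
    for lab in labels:
        if lab is None:
            raise ValueError("every specimen needs a taxon label for cross-validation")
        if lab not in class_labels:
            class_labels.append(lab)
    for lab in class_labels:
        if labels.count(lab) < 2:
            raise ValueError(
                f"class '{lab}' has a single specimen and cannot be held out and trained on"
            )
    n = len(configs)
    fit = gpa(configs)
    if not fit.converged:
        raise RuntimeError("generalized Procrustes alignment did not converge; aborting LOO")
    k = fit.consensus.shape[0]
    max_rank = 2 * k - 4
    X = project_tangent(fit) if cfg.tangent_projection else fit.coordinate_matrix()

    index = {lab: i for i, lab in enumerate(class_labels)}
    counts = np.zeros((len(class_labels), len(class_labels)), dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        if cfg.loo_resuperimpose:
            fold_fit = gpa([configs[j] for j in range(n) if mask[j]])
            if not fold_fit.converged:
                raise RuntimeError(
                    f"per-fold superimposition failed to converge holding out specimen {i}"
                )
            fold_X = (
                project_tangent(fold_fit)
                if cfg.tangent_projection
                else fold_fit.coordinate_matrix()
            )
            model = fit_cva(
                fold_X,
                [labels[j] for j in range(n) if mask[j]],
                consensus=fold_fit.consensus,
                tangent=cfg.tangent_projection,
                max_rank=max_rank,
            )
            query = configs[i]
        else:
            model = fit_cva(
                X[mask],
                [labels[j] for j in range(n) if mask[j]],
                consensus=fit.consensus,
                tangent=cfg.tangent_projection,
                max_rank=max_rank,
            )
            query = X[i]
        pred = classify(
            model,
            query,
            typicality_low=cfg.typicality_low,
            typicality_high=cfg.typicality_high,
        ).predicted
        counts[index[labels[i]], index[pred]] += 1
        mask[i] = True
    return ConfusionMatrix(labels=class_labels, counts=counts)


def load_reference_table(name: str) -> ConfusionMatrix:
    """Load one of the shipped published leave-one-out confusion tables.

    ``name`` is one of ``"genus"`` (13 carrion-visiting muscid genera, 790
    specimens), ``"hydrotaea"`` (8 Hydrotaea species, 318 specimens) or
    ``"muscina"`` (4 Muscina species, 163 specimens).
    """
    if name not in REFERENCE_TABLES:
        raise ValueError(f"unknown reference table {name!r}; choose from {REFERENCE_TABLES}")
    path = resources.files("wingid").joinpath(f"data/tables/{name}.csv")
    with path.open() as fh:
        return ConfusionMatrix.from_csv(fh)
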