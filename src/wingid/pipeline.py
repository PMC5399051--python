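"""Pipeline configuration and high-level orchestration.

Thin glue over the library modules: validated run configuration, training a
reference set from labelled wings, and classifying query wings against one.
The command-line interface in :mod:`wingid.cli` wraps these functions.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

from .discriminate import ClassificationResult, CvaModel, classify, fit_cva
from .landmarks_io import LandmarkConfiguration, SpecimenRecord, build_records
from .superimposition import GpaResult, gpa, project_tangent

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "train_model", "classify_configs", "merged_configs"]

_LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


@dataclass
class PipelineConfig:
    """Validated run configuration, echoed into every report for reproducibility."""

    tangent_projection: bool = False
    loo_resuperimpose: bool = False
    typicality_low: float = 0.01
    typicality_high: float = 0.05
    percent_rounding: str = "half_away"
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"
    flip_y: bool = False

    def __post_init__(self):
        if not (0.0 < self.typicality_low < 1.0 and 0.0 < self.typicality_high < 1.0):
            raise ValueError("typicality thresholds must lie in (0, 1)")
        if self.typicality_low > self.typicality_high:
            raise ValueError("typicality_low must not exceed typicality_high")
        if self.percent_rounding != "half_away":
            raise ValueError("the only supported percent rounding mode is 'half_away'")
        if self.log_level.upper() not in _LOG_LEVELS:
            raise ValueError(f"log_level must be one of {_LOG_LEVELS}")
        self.log_level = self.log_level.upper()
        self.seed = int(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)


def merged_configs(items) -> list[LandmarkConfiguration]:
    """Reduce raw wings or specimen records to one merged configuration each."""
    if items and isinstance(items[0], LandmarkConfiguration):
        records = build_records(items)
    else:
        records = list(items)
    out = []
    for rec in records:
        if isinstance(rec, SpecimenRecord):
            from .landmarks_io import merge_sides

            out.append(rec.merged if rec.merged is not None else merge_sides(rec))
        else:
            out.append(rec)
    return out


def train_model(items, config: PipelineConfig | None = None) -> tuple[CvaModel, GpaResult]:
    """Superimpose labelled wings and fit the canonical-variate classifier."""
    cfg = config or PipelineConfig()
    configs = merged_configs(items)
    fit = gpa(configs)
    if not fit.converged:
        raise RuntimeError("generalized Procrustes alignment did not converge")
    k = fit.consensus.shape[0]
    X = project_tangent(fit) if cfg.tangent_projection else fit.coordinate_matrix()
    model = fit_cva(
        X,
        fit.labels(),
        consensus=fit.consensus,
        tangent=cfg.tangent_projection,
        max_rank=2 * k - 4,
    )
    return model, fit


def classify_configs(
    model: CvaModel, items, config: PipelineConfig | None = None
) -> list[ClassificationResult]:
    """Classify query wings (merged per specimen) against a trained model."""
    cfg = config or PipelineConfig()
    return [
        classify(
            model,
            c,
            typicality_low=cfg.typicality_low,
            typicality_high=cfg.typicality_high,
        )
        for c in merged_configs(items)
    ]
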