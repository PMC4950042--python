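"""End-to-end convenience wrappers over the stage modules."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import MarkerPanel, RocSummary, loocv_roc, select_panel
from .features import FeatureMatrix, bin_features, frequency_filter
from .io import SampleManifest, SpotPeakList
from .quantify import QuantifyParams, quantify_cohort
from .stats import group_summaries

__all__ = ["PipelineResult", "run_pipeline", "build_feature_matrix"]


@dataclass
class PipelineResult:
    matrix: FeatureMatrix
    stats: pd.DataFrame
    panel: MarkerPanel
    roc: RocSummary


def build_feature_matrix(
    spots: list[SpotPeakList],
    manifest: SampleManifest,
    quant_params: QuantifyParams | None = None,
    bin_tol: float = 0.1,
    overall_min: float = 0.10,
    group_min: float = 0.25,
) -> FeatureMatrix:
    """Quantify every sample, bin into consensus features, apply filters."""
    quants = quantify_cohort(spots, manifest, quant_params)
    matrix = bin_features(quants, bin_tol, groups=manifest.sample_groups())
    return frequency_filter(matrix, overall_min, group_min)


def run_pipeline(
    spots: list[SpotPeakList],
    manifest: SampleManifest,
    quant_params: QuantifyParams | None = None,
    alpha: float = 0.05,
    include_pools: bool = True,
) -> PipelineResult:
    """Quantification -> feature matrix -> marker stats -> panel -> LOOCV ROC.

    Panel selection runs on the full cohort before cross-validation, as in
    the original study design; the resulting LOOCV AUC therefore carries
    selection optimism (see the package methods note).
    """
    matrix = build_feature_matrix(spots, manifest, quant_params)
    stats = group_summaries(matrix)
    dense = matrix.dense()
    panel = select_panel(stats, dense, matrix.groups, alpha=alpha)
    roc = loocv_roc(dense, matrix.groups, panel, include_pools=include_pools)
    return PipelineResult(matrix, stats, panel, roc)
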