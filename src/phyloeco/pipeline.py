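"""End-to-end orchestration: proteomes -> features -> subset -> clusters.

One call runs the whole phyloecological analysis: featurize every
proteome, decorrelate the features at the chosen threshold, z-normalize
the surviving subset, scan all metric x linkage trees, cut the best one
at the cut height, and (optionally) cross-check with correlation-distance
k-means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cluster as cl
from .features import FeatureDefinition, ProteomeRecord, default_feature_definitions
from .features import build_feature_matrix
from .selection import SelectionAudit, select_uncorrelated


@dataclass(frozen=True)
class PipelineResult:
    """Everything the pipeline computed, for inspection or export."""

    features: pd.DataFrame
    audit: SelectionAudit
    subset: pd.DataFrame
    normalized: pd.DataFrame = field(hash=False)
    tree_scores: list[cl.TreeScore] = field(hash=False)
    assignment: cl.ClusterAssignment = field(hash=False)
    kmeans_assignment: cl.ClusterAssignment | None = None
    kmeans_mean_silhouette: float | None = None

    @property
    def best(self) -> cl.TreeScore:
        return self.tree_scores[0]


def run_pipeline(
    proteomes: list[ProteomeRecord] | None = None,
    feature_matrix: pd.DataFrame | None = None,
    defs: list[FeatureDefinition] | None = None,
    scales=None,
    threshold: float = 0.5,
    cut_height: float = 1.0,
    k: int | None = 3,
    kmeans_replicates: int = 8,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full analysis; supply either proteomes or a ready matrix.

    Defaults mirror the reference analysis: decorrelation threshold 0.5,
    representative tree chosen by cophenetic coefficient over 4 metrics
    x 2 linkages, cut height 1.0, k-means at k = 3 with 8 replicates.
    Pass ``k=None`` to skip the k-means cross-check.
    """
    if (proteomes is None) == (feature_matrix is None):
        raise ValueError("supply exactly one of proteomes / feature_matrix")
    if feature_matrix is None:
        if defs is None:
            defs, scales = default_feature_definitions()
        feature_matrix = build_feature_matrix(proteomes, defs, scales)
    audit = select_uncorrelated(feature_matrix, threshold)
    subset = feature_matrix[list(audit.final_subset)]
    normalized = cl.zscore_columns(subset)
    scores = cl.select_best_tree(normalized)
    assignment = cl.cut_tree(scores[0].tree, cut_height)
    km_assignment = None
    km_sil = None
    if k is not None:
        km_assignment, km_sil, _ = cl.kmeans_correlation(
            normalized, k=k, replicates=kmeans_replicates, seed=seed
        )
    return PipelineResult(
        features=feature_matrix,
        audit=audit,
        subset=subset,
        normalized=normalized,
        tree_scores=scores,
        assignment=assignment,
        kmeans_assignment=km_assignment,
        kmeans_mean_silhouette=km_sil,
    )
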