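"""Cluster validity checks and ecological interpretation.

Four instruments: (1) a within-feature permutation control that destroys
species structure while preserving each feature's marginal distribution,
(2) phenotype-abundance tables summarizing how habitat categories
distribute over clusters, (3) two-sample feature tests (Mann-Whitney,
Kolmogorov-Smirnov) between habitat subsets, and (4) label transfer for
new species by re-clustering the combined dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, mannwhitneyu, pearsonr, spearmanr

from .cluster import (
    ClusterAssignment,
    cut_tree,
    linkage_tree,
    pairwise_distances,
    zscore_columns,
)

#: Habitat axes every phenotype table must annotate.
PHENOTYPE_AXES = ("temperature", "salt", "pH", "O2", "metabolism", "pressure")


class ValidationError(ValueError):
    """Raised on invalid validation inputs."""


def permute_within_features(m: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """Independently permute each feature column over species.

    Column multisets (hence all marginal distributions) are preserved;
    the joint association between features and species is destroyed.
    """
    rng = np.random.default_rng(seed)
    values = m.to_numpy(dtype=float).copy()
    for j in range(values.shape[1]):
        values[:, j] = rng.permutation(values[:, j])
    return pd.DataFrame(values, index=m.index, columns=m.columns)


class PermutationRepeat(NamedTuple):
    rho: float
    p_rho: float
    r: float
    p_r: float


def permutation_validation(
    m: pd.DataFrame,
    metric: str = "correlation",
    repeats: int = 10,
    seed: int | None = None,
) -> list[PermutationRepeat]:
    """Correlate permuted-data distances against the original distances.

    For each repeat the (already normalized) matrix is column-permuted,
    pairwise distances recomputed, and the condensed distance vectors
    correlated (Spearman and Pearson, naive two-sided p) against the
    unpermuted distances.  Structured data should give non-significant
    correlations in every repeat.
    """
    original = pairwise_distances(m, metric).condensed()
    out = []
    for i in range(repeats):
        perm = permute_within_features(m, None if seed is None else seed + i)
        d = pairwise_distances(perm, metric).condensed()
        rho, p_rho = spearmanr(original, d)
        r, p_r = pearsonr(original, d)
        out.append(PermutationRepeat(float(rho), float(p_rho), float(r), float(p_r)))
    return out


def phenotype_abundance(
    a: ClusterAssignment, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """Fraction of each phenotype category falling into each cluster.

    ``phenotypes`` has species as index and one column per habitat axis.
    The output rows are (axis, category) pairs over the categories
    actually present; columns are cluster labels; each row sums to 1.
    Unknown/other is a category of its own wherever it appears.
    """
    species_a = set(a.labels)
    species_p = set(phenotypes.index)
    if species_a != species_p:
        raise ValidationError(
            "species mismatch: only in clustering "
            f"{sorted(species_a - species_p)}, only in phenotypes "
            f"{sorted(species_p - species_a)}"
        )
    missing_axes = [ax for ax in PHENOTYPE_AXES if ax not in phenotypes.columns]
    if missing_axes:
        raise ValidationError(f"phenotype table missing axes: {missing_axes}")
    clusters = sorted(set(a.labels.values()))
    rows = {}
    for axis in PHENOTYPE_AXES:
        for category, members in phenotypes.groupby(axis).groups.items():
            counts = np.array(
                [sum(a.labels[s] == c for s in members) for c in clusters], dtype=float
            )
            rows[(axis, str(category))] = counts / counts.sum()
    table = pd.DataFrame.from_dict(rows, orient="index", columns=clusters)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["axis", "category"])
    return table


def habitat_subset_tests(
    m: pd.DataFrame,
    group_a: set[str] | list[str],
    group_b: set[str] | list[str],
    holm: bool = False,
) -> pd.DataFrame:
    """Per-feature two-sample tests between two species groups.

    For every feature column, a two-sided Mann-Whitney U test (location)
    and a two-sample Kolmogorov-Smirnov test (distribution) compare the
    two groups.  Returns a DataFrame indexed by feature with columns
    ``U``, ``p_mw``, ``D``, ``p_ks`` (and Holm-adjusted columns when
    ``holm=True``; by default raw p-values are reported).
    """
    ga, gb = set(group_a), set(group_b)
    if ga & gb:
        raise ValidationError(f"groups overlap: {sorted(ga & gb)}")
    if len(ga) < 3 or len(gb) < 3:
        raise ValidationError("each group needs at least 3 species")
    missing = (ga | gb) - set(m.index)
    if missing:
        raise ValidationError(f"species not in feature matrix: {sorted(missing)}")
    xa = m.loc[sorted(ga)].to_numpy(dtype=float)
    xb = m.loc[sorted(gb)].to_numpy(dtype=float)
    rows = []
    for j, feature in enumerate(m.columns):
        u, p_mw = mannwhitneyu(xa[:, j], xb[:, j], alternative="two-sided")
        ks = ks_2samp(xa[:, j], xb[:, j])
        rows.append((feature, float(u), float(p_mw), float(ks.statistic), float(ks.pvalue)))
    out = pd.DataFrame(rows, columns=["feature", "U", "p_mw", "D", "p_ks"])
    out = out.set_index("feature")
    if holm:
        from statsmodels.stats.multitest import multipletests

        for col in ("p_mw", "p_ks"):
            out[f"{col}_holm"] = multipletests(out[col], method="holm")[1]
    return out


@dataclass(frozen=True)
class NewSpeciesReport:
    """Outcome of label transfer onto newly added species."""

    new_labels: dict[str, int]
    combined: ClusterAssignment
    cluster_mapping: dict[int, int]  # combined-cluster label -> reference label


def assign_new_species(
    reference: pd.DataFrame,
    assignment: ClusterAssignment,
    new_features: pd.DataFrame,
    metric: str = "correlation",
    linkage: str = "upgma",
    cut_height: float = 1.0,
) -> NewSpeciesReport:
    """Place new species by re-clustering the combined feature matrix.

    ``reference`` and ``new_features`` are *unnormalized* matrices over
    the identical feature subset.  The combined matrix is re-z-scored
    and re-clustered with the reference parameters; each combined
    cluster inherits the reference label held by the majority of its
    reference species.  A combined cluster whose majority is tied (or
    that contains no reference species) raises with diagnostics.
    """
    if list(reference.columns) != list(new_features.columns) and len(new_features):
        raise ValidationError("new species featurized over different feature set")
    overlap = set(reference.index) & set(new_features.index)
    if overlap:
        raise ValidationError(f"new species already in reference: {sorted(overlap)}")
    if set(reference.index) != set(assignment.labels):
        raise ValidationError("reference assignment does not cover reference matrix")
    if len(new_features) == 0:
        return NewSpeciesReport({}, assignment, {c: c for c in set(assignment.labels.values())})

    combined = pd.concat([reference, new_features], axis=0)
    z = zscore_columns(combined)
    tree = linkage_tree(pairwise_distances(z, metric), linkage)
    comb_assign = cut_tree(tree, cut_height)

    mapping: dict[int, int] = {}
    for c in sorted(set(comb_assign.labels.values())):
        members = [s for s, lab in comb_assign.labels.items() if lab == c]
        ref_members = [s for s in members if s in assignment.labels]
        counts: dict[int, int] = {}
        for s in ref_members:
            counts[assignment.labels[s]] = counts.get(assignment.labels[s], 0) + 1
        if not counts:
            raise ValidationError(
                f"combined cluster {c} contains no reference species "
                f"(members: {sorted(set(members) & set(new_features.index))})"
            )
        ranked = sorted(counts.items(), key=lambda kv: -kv[1])
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            raise ValidationError(
                f"ambiguous mapping for combined cluster {c}: overlaps {counts}"
            )
        mapping[c] = ranked[0][0]

    new_labels = {
        s: mapping[comb_assign.labels[s]] for s in new_features.index
    }
    return NewSpeciesReport(new_labels, comb_assign, mapping)
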