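"""Distance computation, agglomerative trees, tree cuts and k-means.

The species-by-feature matrix is z-normalized per feature, pairwise
species distances are computed under one of four metrics (euclidean,
correlation, cosine, cityblock), and average-linkage trees (UPGMA,
unweighted; WPGMA, weighted) are built from each.  Tree faithfulness is
scored by the cophenetic correlation coefficient; the best-scoring
metric/linkage combination is the representative tree, which is cut at a
fixed height into clusters.  A correlation-distance k-means with
silhouette scoring provides a non-hierarchical cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "correlation", "cosine", "cityblock")
LINKAGES = ("upgma", "wpgma")
_SCIPY_METHOD = {"upgma": "average", "wpgma": "weighted"}


class ClusteringError(ValueError):
    """Raised on invalid clustering inputs."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities between named taxa."""

    ids: tuple[str, ...]
    data: np.ndarray = field(hash=False)
    metric: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ClusteringError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.isfinite(d).all():
            raise ClusteringError("non-finite distances")
        if not np.allclose(d, d.T):
            raise ClusteringError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ClusteringError("nonzero diagonal")
        if (d < -1e-12).any():
            raise ClusteringError("negative distances")
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        np.fill_diagonal(d, 0.0)
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy's condensed order."""
        return squareform(self.data, checks=False)

    def reorder(self, ids: tuple[str, ...]) -> "DistanceMatrix":
        if set(ids) != set(self.ids):
            raise ClusteringError("taxa mismatch in reorder")
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(tuple(ids), self.data[np.ix_(idx, idx)], self.metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative tree: scipy-format merge list over named leaves.

    ``merges`` rows are ``(left, right, height, size)`` with cluster
    indices 0..n-1 for leaves and n+i for the cluster created by merge i.
    """

    ids: tuple[str, ...]
    merges: np.ndarray = field(hash=False)
    linkage_name: str = ""
    metric_name: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.merges, dtype=float)
        if z.shape != (len(self.ids) - 1, 4):
            raise ClusteringError("merge list must have n-1 rows of 4")
        heights = z[:, 2]
        if (np.diff(heights) < -1e-9).any():
            raise ClusteringError("merge heights not monotone non-decreasing")
        object.__setattr__(self, "merges", z)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[str]:
        """Leaves in dendrogram display order."""
        return [self.ids[i] for i in hierarchy.leaves_list(self.merges)]


@dataclass(frozen=True)
class ClusterAssignment:
    """Species -> cluster label (contiguous small integers from 1)."""

    labels: dict[str, int] = field(hash=False)
    provenance: str = ""
    cut_height: float | None = None
    k: int | None = None

    def __post_init__(self) -> None:
        got = sorted(set(self.labels.values()))
        if got != list(range(1, len(got) + 1)):
            raise ClusteringError(f"labels not contiguous from 1: {got}")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def vector(self, ids: list[str] | tuple[str, ...]) -> np.ndarray:
        return np.array([self.labels[i] for i in ids], dtype=int)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def zscore_columns(m: pd.DataFrame) -> pd.DataFrame:
    """Standardize each feature column to mean 0, sample (n-1) variance 1."""
    if m.shape[0] < 2:
        raise ClusteringError("need at least 2 species to z-score")
    values = m.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    constant = m.columns[sd == 0.0].tolist()
    if constant:
        raise ClusteringError(f"constant feature column(s): {constant}")
    z = (values - values.mean(axis=0)) / sd
    return pd.DataFrame(z, index=m.index, columns=m.columns)


def pairwise_distances(m: pd.DataFrame, metric: str) -> DistanceMatrix:
    """Pairwise species distances over feature rows.

    Correlation distance is ``1 - Pearson r`` between the two species'
    feature vectors (range [0, 2]); cosine distance is ``1 - cosine
    similarity``; euclidean and cityblock are the standard norms.
    """
    if metric not in METRICS:
        raise ClusteringError(f"unknown metric {metric!r}; choose from {METRICS}")
    values = m.to_numpy(dtype=float)
    if metric == "correlation":
        bad = m.index[values.std(axis=1) == 0.0].tolist()
        if bad:
            raise ClusteringError(
                f"constant feature row(s) under correlation metric: {bad}"
            )
    if metric == "cosine":
        bad = m.index[np.linalg.norm(values, axis=1) == 0.0].tolist()
        if bad:
            raise ClusteringError(f"all-zero row(s) under cosine metric: {bad}")
    d = squareform(pdist(values, metric=metric))
    return DistanceMatrix(tuple(m.index), d, metric)


def linkage_tree(D: DistanceMatrix, method: str = "upgma") -> Dendrogram:
    """Build an average-linkage tree (UPGMA or WPGMA) from distances."""
    if method not in LINKAGES:
        raise ClusteringError(f"unknown linkage {method!r}; choose from {LINKAGES}")
    if D.n < 2:
        raise ClusteringError("need at least 2 taxa")
    z = hierarchy.linkage(D.condensed(), method=_SCIPY_METHOD[method])
    return Dendrogram(D.ids, z, linkage_name=method, metric_name=D.metric)


def cophenetic(D: DistanceMatrix, t: Dendrogram) -> tuple[DistanceMatrix, float]:
    """Cophenetic distances of a tree and the cophenetic correlation.

    The cophenetic distance of a leaf pair is the height of their lowest
    common merge; the coefficient is the Pearson correlation between the
    condensed original and cophenetic distance vectors.
    """
    if t.ids != D.ids:
        raise ClusteringError("dendrogram and distance matrix taxa differ")
    coph = hierarchy.cophenet(t.merges)
    coefficient = float(np.corrcoef(D.condensed(), coph)[0, 1])
    return DistanceMatrix(D.ids, squareform(coph), "cophenetic"), coefficient


def cut_tree(t: Dendrogram, height: float) -> ClusterAssignment:
    """Cut a dendrogram: merges at or above ``height`` are severed.

    Leaves connected only through merges with height strictly below the
    cutoff share a cluster.  Labels are contiguous integers from 1 in
    leaf-order of first appearance.
    """
    if height <= 0:
        raise ClusteringError("cut height must be positive")
    n = len(t.ids)
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, h, _size) in enumerate(t.merges):
        if h < height:
            node = n + i
            parent[find(int(a))] = node
            parent[find(int(b))] = node
    roots: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf in hierarchy.leaves_list(t.merges):
        r = find(int(leaf))
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[t.ids[leaf]] = roots[r]
    return ClusterAssignment(
        labels,
        provenance=f"tree:{t.metric_name}/{t.linkage_name}",
        cut_height=height,
    )


@dataclass(frozen=True)
class TreeScore:
    metric: str
    linkage: str
    tree: Dendrogram | None
    coefficient: float | None
    error: str | None = None


def select_best_tree(
    m: pd.DataFrame,
    metrics: tuple[str, ...] = METRICS,
    linkages: tuple[str, ...] = LINKAGES,
) -> list[TreeScore]:
    """Evaluate every metric x linkage tree and rank by cophenetic fit.

    Expects an already-normalized matrix.  Failing combinations (e.g. a
    constant row under the correlation metric) are recorded with their
    error rather than aborting the scan, unless every combination fails.
    Ties are broken by the fixed (metric, linkage) enumeration order.
    """
    scored: list[TreeScore] = []
    order: dict[tuple[str, str], int] = {}
    for metric in metrics:
        for link in linkages:
            order[(metric, link)] = len(order)
            try:
                D = pairwise_distances(m, metric)
                t = linkage_tree(D, link)
                _, c = cophenetic(D, t)
                scored.append(TreeScore(metric, link, t, c))
            except ClusteringError as exc:
                logger.warning("combination %s/%s failed: %s", metric, link, exc)
                scored.append(TreeScore(metric, link, None, None, error=str(exc)))
    if all(s.tree is None for s in scored):
        raise ClusteringError("every metric/linkage combination failed")
    scored.sort(
        key=lambda s: (
            -(s.coefficient if s.coefficient is not None else -np.inf),
            order[(s.metric, s.linkage)],
        )
    )
    return scored


def tree_vs_data_correlation(
    D: DistanceMatrix, t: Dendrogram
) -> tuple[float, float, float, float]:
    """Spearman and Pearson correlation of cophenetic vs original distances.

    Returns ``(rho, p_rho, r, p_r)`` with naive two-sided p-values; the
    Pearson r equals the cophenetic coefficient by definition.
    """
    if D.n < 4:
        raise ClusteringError("need at least 4 taxa (6 distance pairs)")
    coph, _ = cophenetic(D, t)
    x, y = D.condensed(), coph.condensed()
    rho, p_rho = spearmanr(x, y)
    r, p_r = pearsonr(x, y)
    return float(rho), float(p_rho), float(r), float(p_r)


# ---------------------------------------------------------------------------
# k-means under correlation distance
# ---------------------------------------------------------------------------


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm, so that correlation
    distance between rows equals squared euclidean distance / 2."""
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ClusteringError("constant row(s): correlation distance undefined")
    return centered / norms


def kmeans_correlation(
    m: pd.DataFrame,
    k: int,
    replicates: int = 8,
    seed: int | None = None,
    max_iter: int = 300,
) -> tuple[ClusterAssignment, float, pd.Series]:
    """Lloyd k-means under correlation distance, best of ``replicates``.

    Rows are centered and scaled to unit norm; centroids are
    re-standardized after every update so assignment always minimizes
    ``1 - r`` to the centroid.  A centroid left empty after an update is
    re-seeded from the point farthest from its assigned centroid
    (logged).  Replicate r uses seed ``seed + r`` (fixed offsets).
    Returns the best assignment (by total within-cluster correlation
    distance), its mean silhouette under correlation distance, and the
    per-species silhouettes.
    """
    from sklearn.metrics import silhouette_samples

    n = m.shape[0]
    if not 2 <= k < n:
        raise ClusteringError(f"need 2 <= k < n ({k=}, {n=})")
    x = _standardize_rows(m.to_numpy(dtype=float))

    best: tuple[float, np.ndarray] | None = None
    for rep in range(replicates):
        rng = np.random.default_rng(None if seed is None else seed + rep)
        centroids = x[rng.choice(n, size=k, replace=False)]
        labels = np.full(n, -1)
        for _ in range(max_iter):
            dist = 1.0 - x @ centroids.T
            new_labels = dist.argmin(axis=1)
            # re-seed empty clusters from far points in multi-member clusters
            counts = np.bincount(new_labels, minlength=k)
            while (counts == 0).any():
                c = int(np.flatnonzero(counts == 0)[0])
                own = dist[np.arange(n), new_labels]
                own[counts[new_labels] <= 1] = -np.inf
                far = int(own.argmax())
                logger.info("replicate %d: re-seeding empty cluster %d", rep, c)
                counts[new_labels[far]] -= 1
                new_labels[far] = c
                counts[c] += 1
            if (new_labels == labels).all():
                break
            labels = new_labels
            for c in range(k):
                mean = x[labels == c].mean(axis=0, keepdims=True)
                centroids[c] = _standardize_rows(mean)[0]
        inertia = float((1.0 - (x * centroids[labels]).sum(axis=1)).sum())
        if best is None or inertia < best[0]:
            best = (inertia, labels.copy())

    assert best is not None
    labels = best[1]
    # relabel contiguously from 1 in order of first appearance
    mapping: dict[int, int] = {}
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    final = {sid: mapping[lab] for sid, lab in zip(m.index, labels)}
    dmat = squareform(pdist(x, metric="correlation"))
    sil = silhouette_samples(dmat, labels, metric="precomputed")
    assignment = ClusterAssignment(final, provenance=f"kmeans:k={k}", k=k)
    return assignment, float(sil.mean()), pd.Series(sil, index=m.index)


def ordered_matrix(m: pd.DataFrame, t: Dendrogram) -> pd.DataFrame:
    """Normalized matrix with rows in dendrogram leaf order (heat-map
    companion export)."""
    return m.loc[t.leaf_order()]
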