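"""16S comparison arm: Jukes-Cantor distances, UPGMA Newick trees, and
distance-matrix correlation tests.

The phylogenetic side of the analysis consumes a pre-aligned nucleotide
alignment (aligning is the job of an external MSA tool), estimates
pairwise evolutionary distances under the one-parameter Jukes-Cantor
substitution model, builds a rooted ultrametric UPGMA tree, and compares
the phylogenetic distance matrix against the proteomic one with a Mantel
permutation test plus naive Spearman/Pearson correlations.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from scipy.cluster import hierarchy
from scipy.stats import pearsonr, spearmanr

from .cluster import ClusteringError, DistanceMatrix

logger = logging.getLogger(__name__)


class PhyloError(ValueError):
    """Raised on invalid phylogenetic inputs."""


@dataclass(frozen=True)
class AlignedSequences:
    """A multiple alignment: equal-length nucleotide strings per taxon."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...] = field(hash=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise PhyloError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise PhyloError("duplicate taxa ids in alignment")
        if not self.sequences or len(self.sequences[0]) == 0:
            raise PhyloError("empty alignment")
        length = len(self.sequences[0])
        for tid, seq in zip(self.ids, self.sequences):
            if len(seq) != length:
                raise PhyloError(
                    f"record {tid!r} has length {len(seq)}, expected {length}"
                )
        norm = tuple(s.upper().replace("U", "T") for s in self.sequences)
        object.__setattr__(self, "sequences", norm)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def length(self) -> int:
        return len(self.sequences[0])


def read_aligned_fasta(source) -> AlignedSequences:
    """Read an aligned FASTA (path, handle, or content string).

    Sequences are uppercased and RNA U normalized to T; ragged records
    raise naming the first offender.
    """
    if hasattr(source, "read"):
        handle = source
    else:
        text = str(source)
        handle = io.StringIO(text) if text.lstrip().startswith(">") else open(text)
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise PhyloError("no FASTA records found")
    length = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != length:
            raise PhyloError(
                f"record {rec.id!r} has length {len(rec.seq)}, expected {length}"
            )
    return AlignedSequences(
        tuple(r.id for r in records), tuple(str(r.seq) for r in records)
    )


_ACGT = {"A": 0, "C": 1, "G": 2, "T": 3}


def jc_distance_from_p(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p) for mismatch
    proportion p in [0, 0.75)."""
    if not 0.0 <= p < 0.75:
        raise PhyloError(f"mismatch proportion {p} outside [0, 0.75)")
    return float(-0.75 * np.log1p(-(4.0 / 3.0) * p))


def jc_distances(a: AlignedSequences, cap: float | None = None) -> DistanceMatrix:
    """Pairwise Jukes-Cantor distances from an alignment.

    Sites where either sequence has a gap or an ambiguity code are
    dropped per pair (pairwise deletion).  A pair with mismatch
    proportion p >= 0.75 is outside the model's domain and raises by
    default; passing ``cap`` instead records the pair at that distance
    (logged).  A pair with zero comparable sites always raises.
    """
    n = len(a.ids)
    codes = np.full((n, a.length), -1, dtype=np.int8)
    for i, seq in enumerate(a.sequences):
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for base, k in _ACGT.items():
            codes[i][arr == ord(base)] = k
    valid = codes >= 0
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise PhyloError(
                    f"no comparable sites between {a.ids[i]!r} and {a.ids[j]!r}"
                )
            p = float((codes[i][both] != codes[j][both]).sum() / comparable)
            if p >= 0.75:
                if cap is None:
                    raise PhyloError(
                        f"mismatch proportion {p:.4f} >= 0.75 between "
                        f"{a.ids[i]!r} and {a.ids[j]!r}: Jukes-Cantor distance undefined "
                        "(pass cap= to saturate instead)"
                    )
                logger.warning(
                    "pair (%s, %s): p=%.4f saturates the model; capped at %.4f",
                    a.ids[i], a.ids[j], p, cap,
                )
                d[i, j] = d[j, i] = cap
            else:
                d[i, j] = d[j, i] = jc_distance_from_p(p)
    return DistanceMatrix(a.ids, d, "jukes-cantor")


def _needs_quote(label: str) -> bool:
    return any(c in label for c in " \t()[]':;,")


def upgma_newick(D: DistanceMatrix) -> str:
    """UPGMA tree over a distance matrix, serialized as rooted Newick.

    Node heights are merge height / 2, so every root-to-leaf path length
    is equal (ultrametric) and the patristic distance between two leaves
    reproduces their cophenetic distance.
    """
    if D.n < 2:
        raise ClusteringError("need at least 2 taxa")
    z = hierarchy.linkage(D.condensed(), method="average")
    n = D.n
    height = np.concatenate([np.zeros(n), z[:, 2] / 2.0])

    def render(node: int) -> str:
        if node < n:
            label = D.ids[node]
            if _needs_quote(label):
                label = "'" + label.replace("'", "''") + "'"
            return label
        a, b = int(z[node - n, 0]), int(z[node - n, 1])
        parts = []
        for child in (a, b):
            branch = height[node] - height[child]
            parts.append(f"{render(child)}:{branch:.10g}")
        return "(" + ",".join(parts) + ")"

    return render(2 * n - 2) + ";"


def _condensed_normed(x: np.ndarray) -> tuple[np.ndarray, float]:
    c = x - x.mean()
    return c, float(np.sqrt((c**2).sum()))


def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    iterations: int = 250_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel permutation test between two distance matrices.

    The statistic is the Pearson correlation of the condensed vectors.
    ``iterations`` random simultaneous row/column permutations of the
    second matrix yield the null; the one-tailed (upper) p-value uses
    the +1 correction, so the smallest attainable p is
    ``1 / (1 + iterations)``.
    """
    if set(D1.ids) != set(D2.ids):
        raise PhyloError("taxa mismatch between distance matrices")
    if D1.n < 5:
        raise PhyloError("need at least 5 taxa for a meaningful Mantel test")
    D2 = D2.reorder(D1.ids)
    x = D1.condensed()
    xc, xn = _condensed_normed(x)
    y = D2.condensed()
    yc, yn = _condensed_normed(y)
    if xn == 0 or yn == 0:
        raise PhyloError("constant distance matrix: correlation undefined")
    r_obs = float(xc @ yc / (xn * yn))

    rng = np.random.default_rng(seed)
    n = D1.n
    iu = np.triu_indices(n, k=1)
    full = D2.data
    count = 0
    for _ in range(iterations):
        perm = rng.permutation(n)
        yp = full[np.ix_(perm, perm)][iu]
        ypc = yp - yp.mean()
        r_perm = float(xc @ ypc / (xn * np.sqrt((ypc**2).sum())))
        if r_perm >= r_obs:
            count += 1
    p = (1 + count) / (1 + iterations)
    return r_obs, p


def matrix_correlations(
    D1: DistanceMatrix, D2: DistanceMatrix
) -> tuple[float, float, float, float]:
    """Spearman and Pearson correlations between two distance matrices.

    Returns ``(rho, p_rho, r, p_r)`` on the condensed vectors with naive
    two-sided p-values (pairs treated as independent; the Mantel test is
    the principled alternative).
    """
    if set(D1.ids) != set(D2.ids):
        raise PhyloError("taxa mismatch between distance matrices")
    D2 = D2.reorder(D1.ids)
    x, y = D1.condensed(), D2.condensed()
    rho, p_rho = spearmanr(x, y)
    r, p_r = pearsonr(x, y)
    return float(rho), float(p_rho), float(r), float(p_r)
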