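"""Hierarchy quantification: average-linkage clustering, cophenetic
distances, and the normalized cophenetic correlation coefficient (CCC).

The CCC of a distance matrix D is the Pearson correlation, over the
N(N-1)/2 unordered pairs, between D_ij and the cophenetic distance T_ij --
the dendrogram height at which leaves i and j first merge under
average-linkage (UPGMA) clustering of D. It measures how tree-like D is:
CCC = 1 exactly when D is an ultrametric, which average linkage reproduces
as a fixed point.

Raw CCC values are high even for unstructured distance matrices, so the
statistic of interest is the CCC normalized against a shuffled null: the
upper-triangle entries of D are permuted uniformly at random (conserving
the multiset of distances while destroying any hierarchical arrangement),
each shuffled matrix is re-clustered and its CCC computed, and

    CCC_norm = (CCC - CCC_rand) / (1 - CCC_rand)

with CCC_rand the mean CCC over (by default) 10 shuffles. CCC_norm is ~0
when the observed hierarchy is no stronger than chance, 1 for a perfectly
tree-like D, and may be negative.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

try:  # C kernels, bypassing per-call linkage re-validation in hot loops
    from scipy.cluster import _hierarchy as _chier
except ImportError:  # pragma: no cover
    _chier = None

from .distances import DistanceMatrix, ectd_matrix, resistance_matrix
from .errors import DegenerateDistanceError, ValidationError
from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    PhenotypeAssignment,
    subset_group_matrix,
)
from .network import GeneNetwork, build_network

__all__ = [
    "MergeTree",
    "CopheneticMatrix",
    "CCCResult",
    "average_linkage",
    "cophenetic_matrix",
    "cophenetic_correlation",
    "shuffled_ccc_null",
    "normalized_ccc",
    "group_ccc_pipeline",
]

_METRICS = {"ectd": ectd_matrix, "resistance": resistance_matrix}


@dataclass
class MergeTree:
    """Average-linkage dendrogram: N-1 merge records in scipy linkage form
    (cluster_a, cluster_b, height, size per row)."""

    node_ids: list[str]
    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.node_ids)

    def leaf_order(self) -> list[str]:
        return [self.node_ids[i] for i in sch.leaves_list(self.linkage)]


@dataclass
class CopheneticMatrix:
    """T_ij = height of the merge first uniting leaves i and j."""

    node_ids: list[str]
    T: np.ndarray

    def condensed(self) -> np.ndarray:
        return squareform(self.T, checks=False)


def average_linkage(D: DistanceMatrix) -> MergeTree:
    """UPGMA clustering of a distance matrix.

    Ties merge the lowest-index cluster pair first (scipy's deterministic
    order), so results are reproducible across runs. Shuffled (non-metric)
    matrices are legal input; their merge heights may invert.
    """
    if D.n_nodes < 3:
        raise ValidationError("need at least 3 nodes to cluster")
    y = D.condensed()
    if np.any(np.isnan(y)):
        raise ValidationError("NaN in distance matrix")
    return MergeTree(list(D.node_ids), sch.linkage(y, method="average"))


def cophenetic_matrix(tree: MergeTree) -> CopheneticMatrix:
    coph = sch.cophenet(tree.linkage)
    return CopheneticMatrix(list(tree.node_ids), squareform(coph, checks=False))


def _pearson_condensed(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx == 0.0 or vy == 0.0:
        raise DegenerateDistanceError(
            "cophenetic correlation undefined: zero variance in the "
            "off-diagonal distances"
        )
    return float((xc @ yc) / np.sqrt(vx * vy))


def cophenetic_correlation(D: DistanceMatrix, T: CopheneticMatrix) -> float:
    """Pearson correlation between original and cophenetic distances over
    the unordered off-diagonal pairs."""
    if D.node_ids != T.node_ids:
        raise ValidationError("D and T are over different node sets")
    return _pearson_condensed(D.condensed(), T.condensed())


def _cophenet_condensed(Z: np.ndarray, n: int) -> np.ndarray:
    """Condensed cophenetic distances of a linkage matrix.

    Calls scipy's C kernel directly when available: the public wrapper
    re-validates the linkage on every call, which dominates run time in the
    shuffle-null and bootstrap loops.
    """
    if _chier is not None:
        d = np.empty(n * (n - 1) // 2)
        _chier.cophenetic_distances(Z, d, n)
        return d
    return sch.cophenet(Z)


def _ccc_of_condensed(y: np.ndarray) -> float:
    """CCC of a condensed distance vector (cluster, read heights, correlate)."""
    Z = sch.linkage(y, method="average")
    n = int(round((1 + np.sqrt(1 + 8 * len(y))) / 2))
    return _pearson_condensed(y, _cophenet_condensed(Z, n))


def shuffled_ccc_null(
    D: DistanceMatrix,
    n_rand: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """CCC of ``n_rand`` entry-shuffled copies of D, and their mean.

    Each replicate permutes the upper-triangle entries uniformly at random
    (mirrored to keep symmetry and the zero diagonal), re-clusters the
    shuffled matrix and computes its CCC. The multiset of pairwise
    distances is conserved exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    y = D.condensed()
    reps = np.array([_ccc_of_condensed(rng.permutation(y))
                     for _ in range(n_rand)])
    return reps, float(reps.mean())


def _shuffled_ccc_null_weights(
    net: GeneNetwork,
    metric: str,
    n_rand: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Alternative null: permute the network's edge weights (not the
    distances) and recompute distances per replicate."""
    w = squareform(net.weights, checks=False)
    reps = np.empty(n_rand)
    for b in range(n_rand):
        shuffled = GeneNetwork(
            list(net.node_ids), squareform(rng.permutation(w), checks=False)
        )
        Db = _METRICS[metric](shuffled)
        reps[b] = _ccc_of_condensed(Db.condensed())
    return reps, float(reps.mean())


def normalized_ccc(ccc: float, ccc_rand_mean: float) -> float:
    """(CCC - CCC_rand) / (1 - CCC_rand); 1 iff CCC == 1, may be negative."""
    if ccc_rand_mean >= 1.0:
        raise DegenerateDistanceError(
            f"shuffled-null mean CCC is {ccc_rand_mean} >= 1; "
            "normalization undefined"
        )
    return (ccc - ccc_rand_mean) / (1.0 - ccc_rand_mean)


@dataclass
class CCCResult:
    """Full record of one (gene set, group) hierarchy measurement."""

    ccc: float
    ccc_rand_mean: float
    ccc_rand_replicates: list[float]
    ccc_norm: float
    metric_tag: str
    n_genes: int
    n_samples: int
    seed: int | None
    gene_set_name: str = ""
    group: str = ""
    dropped_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "gene_set": self.gene_set_name,
            "group": self.group,
            "metric": self.metric_tag,
            "ccc": self.ccc,
            "ccc_rand_mean": self.ccc_rand_mean,
            "ccc_rand_replicates": self.ccc_rand_replicates,
            "ccc_norm": self.ccc_norm,
            "n_genes": self.n_genes,
            "n_samples": self.n_samples,
            "dropped_genes": self.dropped_genes,
            "seed": self.seed,
        }


def ccc_norm_of_matrix(
    mat: ExpressionMatrix,
    metric: str = "ectd",
    n_rand: int = 10,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    null_shuffle: str = "D",
) -> tuple[float, np.ndarray, float, float]:
    """Network -> distance -> CCC -> shuffled null -> CCC_norm for a working
    matrix (zero-variance genes already excluded).

    Returns ``(ccc, null_replicates, ccc_rand_mean, ccc_norm)``.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    net = build_network(mat)
    D = _METRICS[metric](net)
    ccc = _ccc_of_condensed(D.condensed())
    if null_shuffle == "D":
        reps, rand_mean = shuffled_ccc_null(D, n_rand=n_rand, rng=rng)
    elif null_shuffle == "weights":
        reps, rand_mean = _shuffled_ccc_null_weights(net, metric, n_rand, rng)
    else:
        raise ValueError("null_shuffle must be 'D' or 'weights'")
    return ccc, reps, rand_mean, normalized_ccc(ccc, rand_mean)


def group_ccc_pipeline(
    expr: ExpressionMatrix,
    gene_set: GeneSet | Sequence[str],
    pheno: PhenotypeAssignment,
    group: str,
    metric: str = "ectd",
    n_rand: int = 10,
    seed: int | None = None,
    null_shuffle: str = "D",
    ignore_case: bool = False,
) -> CCCResult:
    """End-to-end hierarchy measurement for one gene set in one phenotype
    group: subset, drop zero-variance genes, build the network, compute the
    chosen distance, cluster, and normalize the CCC against shuffled nulls.
    """
    if not isinstance(gene_set, GeneSet):
        gene_set = GeneSet("adhoc", "", list(gene_set))
    sub, report = subset_group_matrix(expr, gene_set, pheno, group,
                                      ignore_case=ignore_case)
    dropped = list(report.zero_variance)
    if dropped:
        keep = [g for g in sub.gene_ids if g not in set(dropped)]
        if len(keep) < 3:
            raise ValidationError(
                f"fewer than 3 genes with nonzero variance in group {group!r}"
            )
        sub = sub.subset(genes=keep)
    ccc, reps, rand_mean, norm = ccc_norm_of_matrix(
        sub, metric=metric, n_rand=n_rand, seed=seed, null_shuffle=null_shuffle
    )
    return CCCResult(
        ccc=ccc,
        ccc_rand_mean=rand_mean,
        ccc_rand_replicates=[float(r) for r in reps],
        ccc_norm=norm,
        metric_tag=metric,
        n_genes=sub.n_genes,
        n_samples=sub.n_samples,
        seed=seed,
        gene_set_name=gene_set.name,
        group=group,
        dropped_genes=dropped,
    )
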