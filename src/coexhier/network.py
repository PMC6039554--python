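"""Per-group gene co-expression network.

The edge weight between genes *i* and *j* within a phenotypic group is the
absolute standardized co-deviation summed over the group's samples,

    l_ij = | sum_k (e_ik - mu_i)(e_jk - mu_j) / (sigma_i sigma_j) |,

with mu and sigma the within-group mean and sample standard deviation of
each gene. Under the sample-sd (n-1 denominator) convention this equals
(n-1)|r_ij| for the Pearson correlation r_ij, so weights lie in [0, n-1]
and the network is invariant to shifting or positively rescaling any gene.
Correlated *and* anti-correlated gene pairs both receive strong edges; the
network encodes co-variation strength, not its sign.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import DisconnectedNetworkError, ValidationError
from .io_formats import ExpressionMatrix

__all__ = ["GeneNetwork", "group_moments", "build_network"]


@dataclass
class GeneNetwork:
    """Symmetric nonnegative edge-weight matrix over a gene set."""

    node_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if W.shape != (n, n):
            raise ValidationError(
                f"weights shape {W.shape} does not match {n} nodes"
            )
        if not np.all(np.isfinite(W)):
            raise ValidationError("network weights contain non-finite values")
        if not np.allclose(W, W.T, rtol=0, atol=1e-12):
            raise ValidationError("network weights are not symmetric")
        if np.any(np.diagonal(W) != 0):
            raise ValidationError("network weights have a nonzero diagonal")
        if np.any(W < 0):
            raise ValidationError("network weights must be nonnegative")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def is_connected(self) -> bool:
        """Connectivity of the graph on strictly positive weights."""
        n = self.n_nodes
        # all-positive off-diagonal (the generic co-expression case) is
        # trivially connected; only degenerate inputs need the full check
        if np.count_nonzero(self.weights) == n * n - n:
            return True
        n_comp, _ = connected_components(
            csr_matrix(self.weights > 0), directed=False
        )
        return n_comp == 1

    def to_edge_list(self, path: str | Path) -> None:
        """Export the upper triangle as a TSV edge list."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("node_a\tnode_b\tweight\n")
            n = self.n_nodes
            for i in range(n):
                for j in range(i + 1, n):
                    fh.write(
                        f"{self.node_ids[i]}\t{self.node_ids[j]}\t"
                        f"{self.weights[i, j]!r}\n"
                    )


def group_moments(mat: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and sample standard deviation (ddof=1) across samples."""
    if mat.n_samples < 3:
        raise ValidationError(
            f"need at least 3 samples to estimate moments, got {mat.n_samples}"
        )
    return mat.values.mean(axis=1), mat.values.std(axis=1, ddof=1)


def build_network(mat: ExpressionMatrix, epsilon: float = 0.0) -> GeneNetwork:
    """Build the co-expression network of a working matrix.

    Parameters
    ----------
    mat : ExpressionMatrix
        Working matrix (one gene set, one phenotype group). Zero-variance
        genes must already be excluded.
    epsilon : float
        Optional uniform off-diagonal weight added after construction, to
        regularize degenerate inputs whose exact-zero weights would
        disconnect the graph. 0 (default) keeps weights literal and raises
        on disconnection.
    """
    mean, sd = group_moments(mat)
    zero = [g for g, s in zip(mat.gene_ids, sd) if s == 0.0]
    if zero:
        raise ValidationError(
            f"zero-variance gene(s) {zero[:5]} ({len(zero)} total); exclude "
            "them before building the network"
        )
    z = (mat.values - mean[:, None]) / sd[:, None]
    W = np.abs(z @ z.T)
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    if epsilon:
        W += epsilon
        np.fill_diagonal(W, 0.0)
    net = GeneNetwork(list(mat.gene_ids), W)
    if not net.is_connected():
        raise DisconnectedNetworkError(
            "positive-weight gene network is disconnected; pass epsilon>0 "
            "to regularize degenerate inputs"
        )
    return net
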