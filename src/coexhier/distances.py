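"""Commute-time and resistance distances on a weighted gene network.

The effective resistance between nodes i and j treats each edge as a
conductor of conductance equal to its weight; it is computed from the
Moore-Penrose pseudoinverse of the graph Laplacian as

    r_ij = L+_ii + L+_jj - 2 L+_ij.

The Euclidean commute time distance (ECTD) is the square root of the
expected round-trip length of the natural random walk,

    ECTD_ij = sqrt(Vol * r_ij),   Vol = sum_ij W_ij,

i.e. sqrt of the commute time n(i->j) + n(j->i). Both distances shrink as
independent paths between two nodes multiply and grow when any path
lengthens, which is what makes them suitable inputs for clustering. ECTD is
invariant to uniform rescaling of all edge weights (Vol * r is
scale-free); resistance scales as 1/c.

``mean_first_passage`` solves the absorbing-chain linear system directly
and serves as an independent oracle for the Laplacian route at test scale.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .errors import DisconnectedNetworkError, ValidationError
from .network import GeneNetwork

__all__ = [
    "DistanceMatrix",
    "laplacian_pseudoinverse",
    "resistance_matrix",
    "ectd_matrix",
    "mean_first_passage",
]

#: relative eigenvalue cutoff separating the Laplacian's null space from
#: its positive spectrum; lambda_2 below this (times lambda_max) means the
#: positive-weight graph is numerically disconnected
RELATIVE_NULLSPACE_TOL = 1e-10


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise node distances."""

    node_ids: list[str]
    D: np.ndarray
    metric_tag: str  # ectd | resistance | shuffled | ultrametric

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        n = len(self.node_ids)
        if D.shape != (n, n):
            raise ValidationError(f"D shape {D.shape} does not match {n} nodes")
        if not np.all(np.isfinite(D)):
            raise ValidationError("distance matrix contains non-finite values")
        if not np.allclose(D, D.T, rtol=0, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diagonal(D) != 0):
            raise ValidationError("distance matrix has a nonzero diagonal")
        self.D = D

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        return squareform(self.D, checks=False)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.D, index=self.node_ids, columns=self.node_ids)
        df.index.name = "node_id"
        df.to_csv(path, sep="\t", lineterminator="\n")


def laplacian_pseudoinverse(net: GeneNetwork) -> np.ndarray:
    """Moore-Penrose pseudoinverse of L = diag(degree) - W.

    Uses a symmetric eigendecomposition, inverting only eigenvalues above
    ``RELATIVE_NULLSPACE_TOL * lambda_max``. For a connected graph exactly
    the constant-vector eigenvalue is dropped; a second near-zero eigenvalue
    signals a disconnected graph and raises.
    """
    W = net.weights
    L = np.diag(W.sum(axis=1)) - W
    vals, vecs = np.linalg.eigh(L)
    lam_max = vals[-1]
    if lam_max <= 0:
        raise DisconnectedNetworkError("network has no edges")
    cutoff = RELATIVE_NULLSPACE_TOL * lam_max
    if net.n_nodes >= 2 and vals[1] <= cutoff:
        raise DisconnectedNetworkError(
            "graph Laplacian has a repeated (near-)zero eigenvalue: the "
            "positive-weight network is disconnected"
        )
    inv = np.where(vals > cutoff, 1.0, np.inf)  # avoid 0-division warnings
    inv = inv / np.where(vals > cutoff, vals, 1.0)
    inv[~np.isfinite(inv)] = 0.0
    Lp = (vecs * inv) @ vecs.T
    return (Lp + Lp.T) / 2.0


def resistance_matrix(net: GeneNetwork) -> DistanceMatrix:
    """Effective-resistance distance between every node pair."""
    Lp = laplacian_pseudoinverse(net)
    d = np.diagonal(Lp)
    R = d[:, None] + d[None, :] - 2.0 * Lp
    np.fill_diagonal(R, 0.0)
    R = np.maximum(R, 0.0)  # clip eigendecomposition round-off
    return DistanceMatrix(list(net.node_ids), R, "resistance")


def ectd_matrix(net: GeneNetwork) -> DistanceMatrix:
    """Euclidean commute time distance: sqrt(Vol * resistance)."""
    R = resistance_matrix(net)
    vol = net.weights.sum()
    return DistanceMatrix(list(net.node_ids), np.sqrt(vol * R.D), "ectd")


def mean_first_passage(net: GeneNetwork) -> np.ndarray:
    """Expected first-passage steps n(i->j) of the natural random walk.

    For each target j, solves (I - Q) m = 1 where Q is the transition
    matrix restricted to the non-target states. O(N^4); intended as an
    independent oracle at test scale (N <~ 50), not for production use.
    The commute time n(i->j) + n(j->i) equals ECTD_ij squared.
    """
    W = net.weights
    n = net.n_nodes
    deg = W.sum(axis=1)
    if np.any(deg == 0):
        raise DisconnectedNetworkError("isolated node in network")
    P = W / deg[:, None]
    M = np.zeros((n, n))
    eye = np.eye(n - 1)
    for j in range(n):
        keep = [i for i in range(n) if i != j]
        Q = P[np.ix_(keep, keep)]
        try:
            m = np.linalg.solve(eye - Q, np.ones(n - 1))
        except np.linalg.LinAlgError as exc:
            raise DisconnectedNetworkError(
                "first-passage system is singular: network disconnected"
            ) from exc
        M[keep, j] = m
    return M
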