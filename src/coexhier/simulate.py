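"""Synthetic expression data with known hierarchical covariance.

The generator emulates what the pipeline is designed to detect: a group of
samples whose gene-gene covariance follows a random binary tree. Each node
of the tree (internal nodes and leaves alike) carries an i.i.d. positive
variance increment; the covariance between two genes is the total increment
on their shared ancestors. This random-effects construction is positive
definite for any tree, so no rejection sampling is needed. The tree
covariance is normalized to unit diagonal and mixed with white noise,

    Sigma = h * Sigma_tree + (1 - h) * I,

where the hierarchy strength h in [0, 1] interpolates between a fully
unstructured group (h = 0, the flat null) and a perfectly tree-structured
one (h = 1). Samples are i.i.d. multivariate-normal draws; the pipeline's
internal standardization makes the zero-mean unit-variance choice
irrelevant downstream.

Default scales mirror the cohorts the method targets: gene sets of ~80
genes and phenotype groups of a few dozen samples.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PhenotypeAssignment,
)

__all__ = [
    "GeneTree",
    "HierarchicalModelSpec",
    "sample_gene_tree",
    "generate_group",
    "make_two_group_dataset",
]


@dataclass
class GeneTree:
    """Random binary gene tree with per-node variance increments.

    ``clades`` lists every node as (member gene indices, variance
    increment); ``covariance`` is the implied leaf correlation matrix
    (unit diagonal).
    """

    n_genes: int
    clades: list[tuple[tuple[int, ...], float]]
    covariance: np.ndarray


def sample_gene_tree(
    n_genes: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GeneTree:
    """Draw a random recursive bifurcation over ``n_genes`` leaves.

    Each node (root, internal, leaf) receives an Exp(1) variance increment;
    Sigma_tree[i, j] is the summed increment over the shared ancestry of
    genes i and j, normalized afterwards to unit diagonal. Genes sharing a
    deeper ancestor are therefore more correlated, and the matrix is
    positive definite by construction (leaf increments give a strictly
    positive diagonal addition).
    """
    if n_genes < 3:
        raise ValidationError("need at least 3 genes")
    if rng is None:
        rng = np.random.default_rng(seed)
    S = np.zeros((n_genes, n_genes))
    clades: list[tuple[tuple[int, ...], float]] = []
    stack: list[np.ndarray] = [np.arange(n_genes)]
    while stack:
        idx = stack.pop()
        inc = float(rng.exponential(1.0))
        S[np.ix_(idx, idx)] += inc
        clades.append((tuple(int(i) for i in idx), inc))
        if len(idx) > 1:
            perm = rng.permutation(idx)
            cut = int(rng.integers(1, len(idx)))
            stack.append(np.sort(perm[:cut]))
            stack.append(np.sort(perm[cut:]))
    d = np.sqrt(np.diagonal(S))
    C = S / np.outer(d, d)
    return GeneTree(n_genes, clades, C)


@dataclass
class HierarchicalModelSpec:
    """Parameters of one simulated phenotype group."""

    n_genes: int = 80
    n_samples: int = 25
    hierarchy_strength: float = 0.9
    noise_sd: float = 0.0
    seed: int | None = None
    gene_prefix: str = "G"
    sample_prefix: str = "S"

    def __post_init__(self) -> None:
        if not 0.0 <= self.hierarchy_strength <= 1.0:
            raise ValidationError("hierarchy_strength must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_genes < 3:
            raise ValidationError("need at least 3 genes")
        if self.n_samples < 3:
            raise ValidationError("need at least 3 samples")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


def generate_group(
    spec: HierarchicalModelSpec,
    tree: GeneTree | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Sample a genes x samples matrix from the tree-structured model.

    Draws i.i.d. samples from N(0, Sigma) with
    Sigma = h * Sigma_tree + (1 - h) * I, plus optional white measurement
    noise of sd ``noise_sd``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if tree is None:
        tree = sample_gene_tree(spec.n_genes, rng=rng)
    if tree.n_genes != spec.n_genes:
        raise ValidationError("tree size does not match spec.n_genes")
    h = spec.hierarchy_strength
    sigma = h * tree.covariance + (1.0 - h) * np.eye(spec.n_genes)
    # PD by construction: both terms PSD, their unit-diagonal mix has
    # smallest eigenvalue bounded away from 0 unless h=1, where the leaf
    # increments keep Sigma_tree itself PD.
    chol = np.linalg.cholesky(sigma)
    X = chol @ rng.standard_normal((spec.n_genes, spec.n_samples))
    if spec.noise_sd > 0:
        X = X + spec.noise_sd * rng.standard_normal(X.shape)
    width = len(str(spec.n_genes))
    genes = [f"{spec.gene_prefix}{i + 1:0{width}d}" for i in range(spec.n_genes)]
    swidth = len(str(spec.n_samples))
    samples = [f"{spec.sample_prefix}{j + 1:0{swidth}d}"
               for j in range(spec.n_samples)]
    return ExpressionMatrix(genes, samples, X)


def make_two_group_dataset(
    n_genes: int = 80,
    n_a: int = 25,
    n_b: int = 25,
    h_a: float = 0.9,
    h_b: float = 0.0,
    seed: int | None = None,
    noise_sd: float = 0.0,
    share_tree: bool = False,
    group_labels: tuple[str, str] = ("A", "B"),
) -> tuple[ExpressionMatrix, PhenotypeAssignment, GeneSetCollection]:
    """Two independently sampled phenotype groups over a shared gene list.

    Groups get independent random trees unless ``share_tree``; the returned
    collection holds one gene set covering all simulated genes, so the
    output triple feeds straight into the analysis pipeline.
    """
    ss = np.random.SeedSequence(seed)
    rng_a, rng_b = (np.random.default_rng(c) for c in ss.spawn(2))
    la, lb = group_labels
    spec_a = HierarchicalModelSpec(n_genes, n_a, h_a, noise_sd,
                                   sample_prefix=f"{la}_S")
    spec_b = HierarchicalModelSpec(n_genes, n_b, h_b, noise_sd,
                                   sample_prefix=f"{lb}_S")
    tree_a = sample_gene_tree(n_genes, rng=rng_a)
    tree_b = tree_a if share_tree else sample_gene_tree(n_genes, rng=rng_b)
    mat_a = generate_group(spec_a, tree=tree_a, rng=rng_a)
    mat_b = generate_group(spec_b, tree=tree_b, rng=rng_b)
    expr = ExpressionMatrix(
        mat_a.gene_ids,
        mat_a.sample_ids + mat_b.sample_ids,
        np.hstack([mat_a.values, mat_b.values]),
    )
    pheno = PhenotypeAssignment(
        [la] * n_a + [lb] * n_b, expr.sample_ids
    )
    sets = GeneSetCollection([
        GeneSet("simulated_set", "all simulated genes", list(expr.gene_ids))
    ])
    return expr, pheno, sets
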