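"""Bootstrap inference for the normalized CCC and the random-gene-set
specificity control.

Uncertainty in CCC_norm is estimated by resampling a group's samples with
replacement: each replicate redraws the n sample columns, reruns the whole
network -> distance -> clustering -> normalization pipeline (with fresh
null shuffles), and records CCC_norm. The SE is the sample SD of the
replicates; the point estimate always comes from the original, unresampled
group. Group contrasts are tested with a paired-difference bootstrap
p-value and a two-sample Kolmogorov-Smirnov comparison of the replicate
distributions.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .hierarchy import ccc_norm_of_matrix
from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    PhenotypeAssignment,
    subset_group_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapDistribution",
    "GroupComparison",
    "RandomSetControl",
    "bootstrap_ccc_norm",
    "bootstrap_pvalue",
    "ks_two_sample",
    "random_geneset_specificity",
]

_MAX_REDRAWS = 10


@dataclass
class BootstrapDistribution:
    """B bootstrap replicates of CCC_norm for one (gene set, group)."""

    group_label: str
    gene_set_name: str
    metric_tag: str
    point_estimate: float
    replicates: np.ndarray
    se: float
    seed: int | None
    n_retried: int = 0
    point_ccc: float = float("nan")
    point_ccc_rand_mean: float = float("nan")

    @property
    def B(self) -> int:
        return len(self.replicates)

    def to_dict(self) -> dict:
        return {
            "group": self.group_label,
            "gene_set": self.gene_set_name,
            "metric": self.metric_tag,
            "ccc": self.point_ccc,
            "ccc_rand_mean": self.point_ccc_rand_mean,
            "ccc_norm": self.point_estimate,
            "se": self.se,
            "n_boot": self.B,
            "replicates": [float(r) for r in self.replicates],
            "seed": self.seed,
            "n_retried": self.n_retried,
        }


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    diff: float  # point_estimate(a) - point_estimate(b)
    p_boot: float
    ks_stat: float
    ks_p: float
    direction: str  # a_gt_b | b_gt_a

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "diff": self.diff,
            "direction": self.direction,
            "p_boot": self.p_boot,
            "ks_stat": self.ks_stat,
            "ks_p": self.ks_p,
        }


def _resample_values(
    sub: ExpressionMatrix, rng: np.random.Generator
) -> tuple[ExpressionMatrix, int]:
    """Column-resample with replacement, dropping genes made constant by the
    draw; redraws (up to a cap) if fewer than 3 genes survive."""
    n = sub.n_samples
    for attempt in range(_MAX_REDRAWS):
        idx = rng.integers(0, n, size=n)
        vals = sub.values[:, idx]
        keep = vals.std(axis=1) > 0.0
        if keep.sum() >= 3:
            mat = ExpressionMatrix(
                [g for g, k in zip(sub.gene_ids, keep) if k],
                [f"r{k}" for k in range(n)],
                vals[keep],
            )
            return mat, attempt
    raise ValidationError(
        f"bootstrap resample left <3 non-constant genes after "
        f"{_MAX_REDRAWS} redraws"
    )


def bootstrap_ccc_norm(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    pheno: PhenotypeAssignment,
    group: str,
    metric: str = "ectd",
    n_boot: int = 100,
    n_rand: int = 10,
    seed: int | None = None,
    null_shuffle: str = "D",
    ignore_case: bool = False,
) -> BootstrapDistribution:
    """Bootstrap distribution of CCC_norm for one group.

    Each of the ``n_boot`` replicates draws the group's n sample columns
    with replacement and reruns the full pipeline, including fresh null
    shuffles. Replicate RNG substreams are spawned from ``seed`` so the
    replicate vector is reproducible bit for bit.
    """
    sub, report = subset_group_matrix(expr, gene_set, pheno, group,
                                      ignore_case=ignore_case)
    if report.zero_variance:
        keep = [g for g in sub.gene_ids
                if g not in set(report.zero_variance)]
        if len(keep) < 3:
            raise ValidationError(
                f"fewer than 3 genes with nonzero variance in group {group!r}"
            )
        sub = sub.subset(genes=keep)

    children = np.random.SeedSequence(seed).spawn(n_boot + 1)
    point_ccc, _, point_rand, point = ccc_norm_of_matrix(
        sub, metric=metric, n_rand=n_rand,
        rng=np.random.default_rng(children[0]), null_shuffle=null_shuffle,
    )
    reps = np.empty(n_boot)
    n_retried = 0
    for b in range(n_boot):
        rng = np.random.default_rng(children[b + 1])
        mat, attempts = _resample_values(sub, rng)
        n_retried += attempts
        _, _, _, reps[b] = ccc_norm_of_matrix(
            mat, metric=metric, n_rand=n_rand, rng=rng,
            null_shuffle=null_shuffle,
        )
    if n_retried:
        logger.info("group %r: %d bootstrap redraw(s) due to constant genes",
                    group, n_retried)
    return BootstrapDistribution(
        group_label=group,
        gene_set_name=gene_set.name,
        metric_tag=metric,
        point_estimate=point,
        replicates=reps,
        se=float(reps.std(ddof=1)),
        seed=seed,
        n_retried=n_retried,
        point_ccc=point_ccc,
        point_ccc_rand_mean=point_rand,
    )


def bootstrap_pvalue(
    a: BootstrapDistribution,
    b: BootstrapDistribution,
    direction: str = "a_gt_b",
    method: str = "paired",
) -> float:
    """One-sided bootstrap p-value for a difference in CCC_norm.

    ``paired`` (default) forms replicate-wise differences Delta_b and applies
    the add-one rule p = (1 + #{Delta_b <= 0}) / (B + 1), so the smallest
    attainable p at B=100 is ~0.0099. ``percentile`` reports the plain
    fraction of differences at or below zero.
    """
    if a.B != b.B:
        raise ValidationError(
            f"bootstrap sizes differ: {a.B} vs {b.B}"
        )
    if direction == "a_gt_b":
        delta = a.replicates - b.replicates
    elif direction == "b_gt_a":
        delta = b.replicates - a.replicates
    else:
        raise ValueError("direction must be 'a_gt_b' or 'b_gt_a'")
    n_le = int(np.sum(delta <= 0.0))
    if method == "paired":
        return (1 + n_le) / (a.B + 1)
    if method == "percentile":
        return n_le / a.B
    raise ValueError("method must be 'paired' or 'percentile'")


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic (sup ECDF difference) and
    its asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("KS test needs at least 2 values per sample")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    a: BootstrapDistribution,
    b: BootstrapDistribution,
    direction: str | None = None,
    method: str = "paired",
) -> GroupComparison:
    """Paired bootstrap p-value plus KS comparison of two groups' replicate
    distributions. If ``direction`` is None the observed direction (sign of
    the point-estimate difference) is tested."""
    diff = a.point_estimate - b.point_estimate
    if direction is None:
        direction = "a_gt_b" if diff >= 0 else "b_gt_a"
    p = bootstrap_pvalue(a, b, direction=direction, method=method)
    ks_stat, ks_p = ks_two_sample(a.replicates, b.replicates)
    return GroupComparison(
        group_a=a.group_label,
        group_b=b.group_label,
        diff=diff,
        p_boot=p,
        ks_stat=ks_stat,
        ks_p=ks_p,
        direction=direction,
    )


@dataclass
class RandomSetControl:
    """Outcome of the random-gene-set specificity control."""

    count_significant: int
    n_sets: int
    k: int
    alpha: float
    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.records)


def random_geneset_specificity(
    expr: ExpressionMatrix,
    pheno: PhenotypeAssignment,
    group_a: str,
    group_b: str,
    k: int = 83,
    n_sets: int = 100,
    alpha: float = 0.05,
    metric: str = "ectd",
    n_boot: int = 100,
    n_rand: int = 10,
    seed: int | None = None,
) -> RandomSetControl:
    """Specificity control: how many of ``n_sets`` random gene sets of size
    ``k`` show significantly higher CCC_norm in group A than in group B?

    Sets are drawn uniformly without replacement from the expression
    matrix's full gene universe; each is scored with the one-sided paired
    bootstrap p-value for A > B at level ``alpha``. Raw counts, no
    multiplicity correction.
    """
    universe = list(expr.gene_ids)
    if len(universe) < k:
        raise ValidationError(
            f"gene universe has {len(universe)} genes; cannot draw sets "
            f"of size {k}"
        )
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    count = 0
    for s in range(n_sets):
        members = sorted(rng.choice(universe, size=k, replace=False))
        gs = GeneSet(f"random_{s:03d}", "random control set", list(members))
        seed_a = int(rng.integers(2**31))
        seed_b = int(rng.integers(2**31))
        boot_a = bootstrap_ccc_norm(expr, gs, pheno, group_a, metric=metric,
                                    n_boot=n_boot, n_rand=n_rand, seed=seed_a)
        boot_b = bootstrap_ccc_norm(expr, gs, pheno, group_b, metric=metric,
                                    n_boot=n_boot, n_rand=n_rand, seed=seed_b)
        p = bootstrap_pvalue(boot_a, boot_b, direction="a_gt_b")
        sig = p < alpha
        count += int(sig)
        records.append({
            "set_id": gs.name,
            "member_hash": hashlib.md5(
                ";".join(members).encode()).hexdigest()[:12],
            "ccc_norm_a": boot_a.point_estimate,
            "ccc_norm_b": boot_b.point_estimate,
            "p_boot": p,
            "significant": sig,
        })
    return RandomSetControl(
        count_significant=count, n_sets=n_sets, k=k, alpha=alpha,
        records=records,
    )
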