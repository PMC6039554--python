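"""Readers and writers for the GSEA-ecosystem file dialects (GCT 1.2, GMT,
CLS) and plain TSV, plus the subsetting step that restricts an expression
matrix to one (gene set, phenotype group) working matrix.

All inputs are gene-level: probe-to-gene collapsing and normalization are
upstream concerns and the pipeline never re-normalizes expression values.
"""
from __future__ import annotations

import logging
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PhenotypeAssignment",
    "GeneSet",
    "GeneSetCollection",
    "SubsetReport",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_phenotypes",
    "write_phenotypes",
    "subset_group_matrix",
]


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} id: {dup!r}")


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued matrix with unique row/column ids.

    Values may be on log or linear scale; the pipeline is unit-agnostic
    because the network construction standardizes each gene internally.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            n_bad = int(np.sum(~np.isfinite(self.values)))
            raise ValidationError(
                f"expression matrix contains {n_bad} non-finite value(s); "
                "use missing='drop' at load time to remove incomplete genes"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset(
        self,
        genes: list[str] | None = None,
        samples: list[str] | None = None,
    ) -> "ExpressionMatrix":
        """Restrict to the given genes/samples, preserving the *given* order."""
        gidx = (
            [self.gene_ids.index(g) for g in genes]
            if genes is not None
            else list(range(self.n_genes))
        )
        sidx = (
            [self.sample_ids.index(s) for s in samples]
            if samples is not None
            else list(range(self.n_samples))
        )
        return ExpressionMatrix(
            [self.gene_ids[i] for i in gidx],
            [self.sample_ids[j] for j in sidx],
            self.values[np.ix_(gidx, sidx)],
        )


@dataclass
class PhenotypeAssignment:
    """Per-sample phenotype labels.

    CLS files carry labels positionally (no sample ids); such assignments are
    unbound (``sample_ids is None``) and are bound to an expression matrix's
    sample order on first use.
    """

    labels: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != len(self.labels):
                raise ValidationError(
                    f"{len(self.sample_ids)} sample ids but "
                    f"{len(self.labels)} labels"
                )
            _check_unique(self.sample_ids, "sample")
        if not self.labels:
            raise ValidationError("phenotype assignment has no samples")

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.labels))

    def bind(self, sample_ids: list[str]) -> "PhenotypeAssignment":
        """Attach sample ids (positionally) to an unbound assignment."""
        if self.sample_ids is not None:
            return self
        if len(sample_ids) != len(self.labels):
            raise ValidationError(
                f"cannot bind {len(self.labels)} labels to "
                f"{len(sample_ids)} samples"
            )
        return PhenotypeAssignment(self.labels, list(sample_ids))

    def as_mapping(self) -> dict[str, str]:
        if self.sample_ids is None:
            raise ValidationError("phenotype assignment is unbound (CLS); "
                                  "bind() it to an expression matrix first")
        return dict(zip(self.sample_ids, self.labels))


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"gene (in set {self.name!r})")


class GeneSetCollection(Mapping[str, GeneSet]):
    """Ordered, name-keyed collection of gene sets (GMT content)."""

    def __init__(self, sets: list[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise ValidationError(f"duplicate gene set name: {s.name!r}")
            self._sets[s.name] = s

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, kind: str) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    if kind == "expression":
        return "gct" if suffix == "gct" else "tsv"
    if kind == "phenotype":
        return "cls" if suffix == "cls" else "tsv"
    raise ValueError(kind)


def _coerce_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Cast to float, reporting the first offending cell on failure."""
    try:
        return df.astype(float)
    except (ValueError, TypeError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[np.argmax(bad.to_numpy())]
                raise FormatError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} "
                    f"at gene {row!r}, sample {col!r}"
                ) from None
        raise  # pragma: no cover - unreachable


def _resolve_duplicates(
    df: pd.DataFrame, policy: str, path: str | Path
) -> pd.DataFrame:
    dup = df.index.duplicated(keep=False)
    if not dup.any():
        return df
    names = sorted(set(df.index[dup]))
    if policy == "error":
        raise ValidationError(
            f"{path}: duplicate gene id(s) {names[:5]} "
            f"({len(names)} total); set duplicates='first' or 'mean' to resolve"
        )
    if policy == "first":
        return df[~df.index.duplicated(keep="first")]
    if policy == "mean":
        return df.groupby(level=0, sort=False).mean()
    raise ValueError(f"unknown duplicate policy {policy!r}")


def read_expression(
    path: str | Path,
    format: str = "auto",
    duplicates: str = "error",
    missing: str = "error",
) -> ExpressionMatrix:
    """Load a genes x samples expression matrix from GCT 1.2 or TSV.

    Parameters
    ----------
    format : {"auto", "gct", "tsv"}
        "auto" chooses by file extension.
    duplicates : {"error", "first", "mean"}
        Policy for repeated gene ids.
    missing : {"error", "drop"}
        "drop" removes genes with any missing value (count logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, "expression") if format == "auto" else format

    if fmt == "gct":
        with open(path, encoding="utf-8") as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(
                    f"{path}: expected GCT version line '#1.2', got {version!r}"
                )
            dims = fh.readline().split()
            if len(dims) != 2 or not all(t.lstrip("-").isdigit() for t in dims):
                raise FormatError(f"{path}: malformed GCT dimension line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype={0: str},
                             float_precision="round_trip")
        if "Description" in df.columns:
            df = df.drop(columns="Description")
        else:  # tolerate arbitrary second-column header
            df = df.drop(columns=df.columns[0])
        if df.shape != (n_genes, n_samples):
            raise FormatError(
                f"{path}: header declares {n_genes}x{n_samples} but body "
                f"is {df.shape[0]}x{df.shape[1]}"
            )
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                         float_precision="round_trip")
    else:
        raise ValueError(f"unknown expression format {fmt!r}")

    df.index = df.index.astype(str)
    df = _resolve_duplicates(df, duplicates, path)
    df = _coerce_numeric(df, path)

    incomplete = df.isna().any(axis=1)
    if incomplete.any():
        if missing == "drop":
            logger.warning(
                "%s: dropped %d gene(s) with missing values", path,
                int(incomplete.sum()),
            )
            df = df[~incomplete]
        else:
            raise ValidationError(
                f"{path}: {int(incomplete.sum())} gene(s) have missing "
                "values; pass missing='drop' to remove them"
            )
    return ExpressionMatrix.from_frame(df)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, format: str = "auto"
) -> None:
    """Write GCT 1.2 or TSV. Floats use full repr precision, so a
    write/read cycle reproduces the matrix exactly."""
    path = Path(path)
    fmt = _infer_format(path, "expression") if format == "auto" else format
    df = expr.to_frame()
    if fmt == "gct":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
            out = df.copy()
            out.insert(0, "Description", "na")
            out.index.name = "NAME"
            out.to_csv(fh, sep="\t", lineterminator="\n")
    elif fmt == "tsv":
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", lineterminator="\n")
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} empty")
            sets.append(GeneSet(name, desc, members))
    return GeneSetCollection(sets)


def write_gene_sets(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in sets.values():
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# phenotypes (CLS / TSV)
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path, format: str = "auto") -> PhenotypeAssignment:
    """Load phenotype labels from a categorical CLS file or a two-column TSV
    (``sample_id<TAB>label``, no header). CLS assignments are unbound."""
    path = Path(path)
    fmt = _infer_format(path, "phenotype") if format == "auto" else format

    if fmt == "cls":
        with open(path, encoding="utf-8") as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if len(lines) < 3:
            raise FormatError(f"{path}: CLS needs header, label and data lines")
        header = lines[0].split()
        if len(header) != 3:
            raise FormatError(f"{path}: malformed CLS header {lines[0]!r}")
        n_samples, n_classes = int(header[0]), int(header[1])
        if not lines[1].startswith("#"):
            raise FormatError(f"{path}: CLS second line must start with '#'")
        class_names = lines[1].lstrip("#").split()
        if len(class_names) != n_classes:
            raise FormatError(
                f"{path}: header declares {n_classes} classes but label "
                f"line has {len(class_names)}"
            )
        tokens = lines[2].split()
        if len(tokens) != n_samples:
            raise FormatError(
                f"{path}: header declares {n_samples} samples but data "
                f"line has {len(tokens)}"
            )
        if all(t.isdigit() for t in tokens):
            idx = [int(t) for t in tokens]
            if max(idx) >= n_classes:
                raise FormatError(f"{path}: class index out of range")
            labels = [class_names[i] for i in idx]
        else:
            labels = tokens
        return PhenotypeAssignment(labels)

    if fmt == "tsv":
        sample_ids: list[str] = []
        labels: list[str] = []
        with open(path, encoding="utf-8", newline="") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\r\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: expected sample_id<TAB>label"
                    )
                sample_ids.append(fields[0])
                labels.append(fields[1])
        return PhenotypeAssignment(labels, sample_ids)

    raise ValueError(f"unknown phenotype format {fmt!r}")


def write_phenotypes(
    pheno: PhenotypeAssignment, path: str | Path, format: str = "auto"
) -> None:
    path = Path(path)
    fmt = _infer_format(path, "phenotype") if format == "auto" else format
    if fmt == "cls":
        groups = pheno.groups
        index = {g: i for i, g in enumerate(groups)}
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"{len(pheno.labels)} {len(groups)} 1\n")
            fh.write("# " + " ".join(groups) + "\n")
            fh.write(" ".join(str(index[l]) for l in pheno.labels) + "\n")
    elif fmt == "tsv":
        if pheno.sample_ids is None:
            raise ValidationError("cannot write unbound phenotypes as TSV")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for s, l in zip(pheno.sample_ids, pheno.labels):
                fh.write(f"{s}\t{l}\n")
    else:
        raise ValueError(f"unknown phenotype format {fmt!r}")


# ---------------------------------------------------------------------------
# subsetting
# ---------------------------------------------------------------------------

@dataclass
class SubsetReport:
    """Accounting of what the (gene set, group) restriction kept and lost."""

    gene_set_name: str
    group: str
    n_requested: int
    present_genes: list[str]
    missing_genes: list[str]
    zero_variance: list[str] = field(default_factory=list)
    n_samples: int = 0
    dropped_samples: int = 0


def subset_group_matrix(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    pheno: PhenotypeAssignment,
    group: str,
    ignore_case: bool = False,
) -> tuple[ExpressionMatrix, SubsetReport]:
    """Restrict ``expr`` to the gene set's members (in gene-set file order)
    and the samples of one phenotype group.

    Genes constant across the group's samples are flagged in the report's
    ``zero_variance`` list; the network builder requires them to be excluded.
    """
    pheno = pheno.bind(expr.sample_ids)
    if group not in pheno.groups:
        raise ValidationError(
            f"group {group!r} not among phenotype labels {pheno.groups}"
        )

    known = set(expr.sample_ids)
    group_samples = [
        s for s, l in zip(pheno.sample_ids, pheno.labels)  # type: ignore[arg-type]
        if l == group and s in known
    ]
    dropped = sum(
        1 for s, l in zip(pheno.sample_ids, pheno.labels)  # type: ignore[arg-type]
        if l == group and s not in known
    )
    if dropped:
        logger.warning(
            "group %r: %d labeled sample(s) absent from expression matrix",
            group, dropped,
        )
    if len(group_samples) < 3:
        raise ValidationError(
            f"group {group!r} has {len(group_samples)} usable samples; "
            "need at least 3"
        )

    if ignore_case:
        lookup = {g.lower(): g for g in expr.gene_ids}
        present = [lookup[g.lower()] for g in gene_set.genes
                   if g.lower() in lookup]
        missing = [g for g in gene_set.genes if g.lower() not in lookup]
    else:
        have = set(expr.gene_ids)
        present = [g for g in gene_set.genes if g in have]
        missing = [g for g in gene_set.genes if g not in have]
    if len(present) < 3:
        raise ValidationError(
            f"gene set {gene_set.name!r}: only {len(present)} member(s) "
            "present in the expression matrix; need at least 3"
        )

    sub = expr.subset(genes=present, samples=group_samples)
    sd = sub.values.std(axis=1)
    zero_var = [g for g, s in zip(sub.gene_ids, sd) if s == 0.0]

    report = SubsetReport(
        gene_set_name=gene_set.name,
        group=group,
        n_requested=len(gene_set.genes),
        present_genes=present,
        missing_genes=missing,
        zero_variance=zero_var,
        n_samples=len(group_samples),
        dropped_samples=dropped,
    )
    return sub, report
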