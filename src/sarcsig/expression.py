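"""Expression matrices, phenotype tables, and the plumbing around them.

The central container is :class:`ExpressionMatrix`, a genes x samples table of
log2 expression values with optional per-gene genomic annotation.  Everything
downstream (differential expression, signature discovery, evaluation) consumes
this type.  Phenotypes are kept separately in a :class:`PhenotypeTable` mapping
sample ids to a disease class (healthy control, uncomplicated or complicated
sarcoidosis) and a population label (African American / European American).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DISEASE_CLASSES",
    "POPULATIONS",
    "ExpressionMatrix",
    "PhenotypeTable",
    "read_expression_matrix",
    "read_phenotypes",
    "read_gene_annotation",
    "filter_sex_chromosomes",
    "log2_transform",
    "standardize_genes",
    "match_genes",
    "collapse_duplicate_symbols",
]

#: Closed vocabulary for disease status: healthy control, uncomplicated
#: sarcoidosis, complicated sarcoidosis (cardiac, neurologic, or FVC<50%).
DISEASE_CLASSES = ("HC", "US", "CS")

#: Closed vocabulary for self-identified population.
POPULATIONS = ("AA", "EA")

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})


class ExpressionDataError(ValueError):
    """Raised on malformed expression, phenotype, or annotation input."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 expression values, genes as rows, samples as columns.

    Parameters
    ----------
    values
        DataFrame of finite floats indexed by gene symbol with sample-id
        columns.  Gene symbols are case-sensitive strings and must be unique,
        as must sample ids.
    annotation
        Optional per-gene genomic annotation with columns ``chrom``,
        ``start``, ``end`` (0-based half-open bp coordinates), indexed by
        gene symbol.  Only genes present in ``values`` are meaningful.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ExpressionDataError(f"duplicate gene symbol(s): {dup}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ExpressionDataError(f"duplicate sample id(s): {dup}")
        arr = v.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ExpressionDataError("expression values must be finite")
        if self.annotation is not None:
            missing = {"chrom", "start", "end"} - set(self.annotation.columns)
            if missing:
                raise ExpressionDataError(
                    f"annotation lacks column(s): {sorted(missing)}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order; unknown genes error."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"gene(s) not in matrix: {missing}")
        ann = None
        if self.annotation is not None:
            keep = [g for g in genes if g in self.annotation.index]
            ann = self.annotation.loc[keep]
        return ExpressionMatrix(self.values.loc[genes], ann)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"sample(s) not in matrix: {missing}")
        return ExpressionMatrix(self.values[samples], self.annotation)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.6g")


@dataclass(frozen=True)
class PhenotypeTable:
    """Sample id -> (disease_class in {HC, US, CS}, population in {AA, EA})."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("disease_class", "population"):
            if col not in t.columns:
                raise ExpressionDataError(f"phenotype table lacks column {col!r}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()].unique().tolist()
            raise ExpressionDataError(f"duplicate phenotype sample id(s): {dup}")
        bad = set(t["disease_class"]) - set(DISEASE_CLASSES)
        if bad:
            raise ExpressionDataError(f"unknown disease class(es): {sorted(bad)}")
        bad = set(t["population"]) - set(POPULATIONS)
        if bad:
            raise ExpressionDataError(f"unknown population(s): {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    def classes_for(self, samples: list[str]) -> pd.Series:
        missing = [s for s in samples if s not in self.table.index]
        if missing:
            raise ExpressionDataError(f"sample(s) lack phenotype records: {missing}")
        return self.table.loc[samples, "disease_class"]

    def select_samples(
        self,
        classes: list[str] | None = None,
        population: str | None = None,
    ) -> list[str]:
        """Sample ids matching the given disease classes and/or population."""
        t = self.table
        mask = np.ones(len(t), dtype=bool)
        if classes is not None:
            unknown = set(classes) - set(DISEASE_CLASSES)
            if unknown:
                raise ExpressionDataError(f"unknown disease class(es): {sorted(unknown)}")
            mask &= t["disease_class"].isin(classes).to_numpy()
        if population is not None:
            if population not in POPULATIONS:
                raise ExpressionDataError(f"unknown population: {population!r}")
            mask &= (t["population"] == population).to_numpy()
        return t.index[mask].tolist()

    def binary_labels(
        self,
        samples: list[str],
        case_classes: list[str],
        control_classes: list[str],
    ) -> np.ndarray:
        """+1 for case samples, -1 for controls; errors on other classes."""
        cls = self.classes_for(samples)
        y = np.where(cls.isin(case_classes), 1, np.where(cls.isin(control_classes), -1, 0))
        if (y == 0).any():
            stray = cls[y == 0].unique().tolist()
            raise ExpressionDataError(
                f"samples with class(es) {stray} are neither case nor control"
            )
        return y.astype(int)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# readers


def read_expression_matrix(path, annotation: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a genes-as-rows TSV: first column gene symbol, header of sample ids.

    Rejects empty files, ragged rows (naming the offending line), non-numeric
    body cells, and duplicated gene symbols.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ExpressionDataError(f"{path}: no data rows")
        n_fields = len(header.split("\t"))
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != n_fields:
                raise ExpressionDataError(
                    f"{path}: ragged row at line {lineno} "
                    f"(expected {n_fields} fields)"
                )
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ExpressionDataError(f"{path}: no data rows")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    if len(non_numeric):
        coerced = df[non_numeric].apply(pd.to_numeric, errors="coerce")
        bad_rows = df.index[coerced.isna().any(axis=1)].tolist()
        raise ExpressionDataError(
            f"{path}: non-numeric expression value(s) in row(s) {bad_rows}"
        )
    if df.isna().to_numpy().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ExpressionDataError(f"{path}: missing value(s) in row(s) {bad}")
    return ExpressionMatrix(df.astype(float), annotation)


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype TSV with columns sample_id, disease_class, population."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "disease_class", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ExpressionDataError(f"{path}: missing column(s) {sorted(missing)}")
    return PhenotypeTable(df.set_index("sample_id"))


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a BED-like TSV (symbol, chrom, start, end; 0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["gene", "chrom", "start", "end"],
        header=None,
        dtype={"gene": str, "chrom": str},
        comment="#",
    )
    if (df["end"] < df["start"]).any():
        bad = df.loc[df["end"] < df["start"], "gene"].tolist()
        raise ExpressionDataError(f"{path}: end < start for gene(s) {bad}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].unique().tolist()
        raise ExpressionDataError(f"{path}: duplicate annotation for gene(s) {dup}")
    return df.set_index("gene")


# ---------------------------------------------------------------------------
# transforms


def filter_sex_chromosomes(
    m: ExpressionMatrix, missing_annotation: str = "drop"
) -> ExpressionMatrix:
    """Remove genes on chromosomes X and Y (gender confounding control).

    Genes lacking annotation are dropped with a warning by default;
    ``missing_annotation="error"`` raises instead.  Idempotent; input gene
    order is preserved.
    """
    if m.annotation is None:
        raise ExpressionDataError("gene annotation required to filter sex chromosomes")
    annotated = m.values.index.isin(m.annotation.index)
    if not annotated.all():
        missing = m.values.index[~annotated].tolist()
        if missing_annotation == "error":
            raise ExpressionDataError(f"gene(s) lacking annotation: {missing}")
        warnings.warn(
            f"dropping {len(missing)} gene(s) lacking annotation", stacklevel=2
        )
    keep = []
    for g in m.values.index:
        if g in m.annotation.index and str(m.annotation.loc[g, "chrom"]) not in SEX_CHROMOSOMES:
            keep.append(g)
    if not keep:
        warnings.warn("all genes removed by sex-chromosome filter", stacklevel=2)
    return ExpressionMatrix(m.values.loc[keep], m.annotation)


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Map linear-scale values v -> log2(v + offset)."""
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    arr = m.values.to_numpy()
    if (arr < 0).any():
        raise ExpressionDataError("log2_transform requires nonnegative values")
    return replace(m, values=np.log2(m.values + offset))


def standardize_genes(m: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Z-score each gene row (mean 0, unit sample SD).

    Constant rows become all-zeros with a warning; single-sample input errors
    because a sample SD is undefined.
    """
    if m.n_samples < 2:
        raise ExpressionDataError("standardize_genes requires >=2 samples")
    arr = m.values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene row(s) standardized to zeros",
            stacklevel=2,
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (arr - mu) / safe_sd
    z[constant, :] = 0.0
    return replace(
        m, values=pd.DataFrame(z, index=m.values.index, columns=m.values.columns)
    )


def match_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict]:
    """Restrict both matrices to the shared gene symbols, in a's order.

    Returns the two restricted matrices plus a report dict with the per-side
    unmatched counts.  Used for cross-platform cohort alignment, where gene
    identity is the (case-sensitive) symbol string.
    """
    b_set = set(b.gene_ids)
    shared = [g for g in a.gene_ids if g in b_set]
    if not shared:
        raise ExpressionDataError("no shared gene symbols between matrices")
    report = {
        "n_shared": len(shared),
        "unmatched_a": a.n_genes - len(shared),
        "unmatched_b": b.n_genes - len(shared),
    }
    return a.subset_genes(shared), b.subset_genes(shared), report


def collapse_duplicate_symbols(values: pd.DataFrame) -> pd.DataFrame:
    """Collapse multi-probe symbols to the row with the highest mean expression.

    Cross-platform validation cohorts may carry several probes per symbol; the
    highest-mean-expression probe is the conventional representative.
    """
    if not values.index.has_duplicates:
        return values
    means = values.mean(axis=1)
    keep_pos = (
        pd.Series(np.arange(len(values)), index=values.index)
        .groupby(level=0, sort=False)
        .apply(lambda s: s.iloc[int(np.argmax(means.iloc[s.to_numpy()].to_numpy()))])
    )
    collapsed = values.iloc[np.sort(keep_pos.to_numpy())]
    return collapsed
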