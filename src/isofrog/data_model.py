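"""Domain types and I/O for isoform function prediction.

The learning problem pairs a gene-level expression matrix ``Xg`` (genes x
RNA-seq experiments) with an isoform-level matrix ``Xiso`` (isoforms x the
same experiments).  Each RNA-seq experiment is one *feature*.  For a given GO
term, genes annotated to the term are labelled 1 and all others 0
(closed-world assumption); the task of the predictor is to transfer those
gene-level labels to individual isoforms.

Genes with a single isoform (SIGs) label their isoform directly; genes with
two or more isoforms (MIGs) are ambiguous bags in the multiple-instance
sense.  The :class:`GeneIsoformMap` caches that partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneIsoformMap",
    "AnnotationTable",
    "PredictionTask",
    "FeatureSubset",
    "load_expression_matrix",
    "write_expression_matrix",
    "load_gene_isoform_map",
    "load_annotations",
    "load_homolog_groups",
    "build_task",
    "filter_terms",
    "apply_feature_subset",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """An expression matrix with named rows (genes or isoforms) and columns
    (RNA-seq experiments).  Values are raw expression units (TPM/FPKM);
    the container is unit-agnostic."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise DataError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} col ids"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise DataError("duplicate row ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise DataError("duplicate column ids")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_features(self) -> int:
        return len(self.col_ids)

    def row_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.row_ids)}

    def restrict_rows(self, row_ids: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset in the given order."""
        idx = self.row_index()
        rows = [idx[r] for r in row_ids]
        return ExpressionMatrix(list(row_ids), list(self.col_ids), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


@dataclass
class GeneIsoformMap:
    """Many-to-one mapping of isoforms to genes with a cached SIG/MIG split."""

    gene_of: dict[str, str]
    isoforms_of: dict[str, list[str]] = field(init=False)
    sigs: list[str] = field(init=False)
    migs: list[str] = field(init=False)

    def __post_init__(self) -> None:
        iso_of: dict[str, list[str]] = {}
        for iso, gene in self.gene_of.items():
            iso_of.setdefault(gene, []).append(iso)
        self.isoforms_of = iso_of
        self.sigs = [g for g, isos in iso_of.items() if len(isos) == 1]
        self.migs = [g for g, isos in iso_of.items() if len(isos) >= 2]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "GeneIsoformMap":
        gene_of: dict[str, str] = {}
        for gene, iso in pairs:
            if iso in gene_of and gene_of[iso] != gene:
                raise DataError(
                    f"isoform {iso} maps to both {gene_of[iso]} and {gene}"
                )
            gene_of[iso] = gene
        return cls(gene_of)

    @property
    def genes(self) -> list[str]:
        return list(self.isoforms_of)

    @property
    def isoforms(self) -> list[str]:
        return list(self.gene_of)

    def restrict_genes(self, genes: Sequence[str]) -> "GeneIsoformMap":
        keep = set(genes)
        return GeneIsoformMap(
            {iso: g for iso, g in self.gene_of.items() if g in keep}
        )


@dataclass
class AnnotationTable:
    """Gene -> GO-term annotation pairs.

    Term sizes are always computed over a reference gene universe (the genes
    present in the expression data), not over all genes the raw file happens
    to mention.
    """

    genes_of_term: dict[str, set[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationTable":
        by_term: dict[str, set[str]] = {}
        for gene, term in pairs:
            by_term.setdefault(term, set()).add(gene)
        return cls(by_term)

    @property
    def terms(self) -> list[str]:
        return list(self.genes_of_term)

    def term_size(self, term: str, universe: Iterable[str]) -> int:
        uni = set(universe)
        return len(self.genes_of_term.get(term, set()) & uni)

    def annotated_genes(self, term: str) -> set[str]:
        return set(self.genes_of_term.get(term, set()))


@dataclass(frozen=True)
class FeatureSubset:
    """An ordered set of column indices into a task's feature axis."""

    indices: tuple[int, ...]

    def __init__(self, indices: Iterable[int]):
        idx = tuple(sorted(int(i) for i in indices))
        if len(idx) == 0:
            raise DataError("feature subset must contain at least one feature")
        if len(set(idx)) != len(idx):
            raise DataError("feature subset indices must be unique")
        if idx[0] < 0:
            raise DataError(f"negative feature index {idx[0]}")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, i: int) -> bool:
        return i in self.indices

    def __iter__(self):
        return iter(self.indices)

    @property
    def cardinality(self) -> int:
        return len(self.indices)


@dataclass
class PredictionTask:
    """One GO term's learning problem.

    ``Xg`` and ``Xiso`` are column-centered (each matrix by its OWN column
    means — per-domain centering aligns the domain means, the first half of
    the domain-alignment requirement).  The means removed are retained so a
    fitted model can center new rows given in the same coordinates.
    """

    term_id: str
    gene_ids: list[str]
    iso_ids: list[str]
    col_ids: list[str]
    Xg: np.ndarray          # centered, n_g x n_f
    Xiso: np.ndarray        # centered, n_iso x n_f
    yg: np.ndarray          # binary, n_g
    mapping: GeneIsoformMap
    gene_col_means: np.ndarray
    iso_col_means: np.ndarray

    def __post_init__(self) -> None:
        self.yg = np.asarray(self.yg, dtype=float)
        if self.Xg.shape != (len(self.gene_ids), len(self.col_ids)):
            raise DataError("Xg shape inconsistent with ids")
        if self.Xiso.shape != (len(self.iso_ids), len(self.col_ids)):
            raise DataError("Xiso shape inconsistent with ids")
        if len(self.yg) != len(self.gene_ids):
            raise DataError("label vector length mismatch")
        if not (0 < self.yg.sum() < len(self.yg)):
            raise DataError(
                f"degenerate label vector for term {self.term_id}: "
                f"{int(self.yg.sum())} of {len(self.yg)} genes positive"
            )

    @property
    def n_features(self) -> int:
        return len(self.col_ids)

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def iso_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.iso_ids)}

    def label_of_gene(self, gene: str) -> int:
        return int(self.yg[self.gene_index[gene]])

    def restrict_genes(self, genes: Sequence[str]) -> "PredictionTask":
        """Training view: keep only the given genes (and their isoforms),
        re-centering both matrices on the retained rows.

        The stored column means are the offsets applied *relative to the
        parent task's coordinates*, so predictions on parent-coordinate rows
        of held-out isoforms center correctly.
        """
        gidx = self.gene_index
        rows_g = [gidx[g] for g in genes]
        sub_map = self.mapping.restrict_genes(genes)
        iso_ids = [t for t in self.iso_ids if t in sub_map.gene_of]
        tidx = self.iso_index
        rows_t = [tidx[t] for t in iso_ids]
        Xg = self.Xg[rows_g]
        Xiso = self.Xiso[rows_t]
        mg = Xg.mean(axis=0)
        mt = Xiso.mean(axis=0)
        return PredictionTask(
            term_id=self.term_id,
            gene_ids=list(genes),
            iso_ids=iso_ids,
            col_ids=list(self.col_ids),
            Xg=Xg - mg,
            Xiso=Xiso - mt,
            yg=self.yg[rows_g],
            mapping=sub_map,
            gene_col_means=mg,
            iso_col_means=mt,
        )


# ---------------------------------------------------------------------------
# Readers / writers


def load_expression_matrix(path: str | Path, expected_axis: str = "genes") -> ExpressionMatrix:
    """Read a TSV expression matrix: header of experiment ids, first column
    the gene/isoform ids.  Errors name the offending id or cell."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except pd.errors.EmptyDataError:
        raise DataError(f"empty expression file: {path}") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"empty expression file: {path}")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise DataError(f"duplicate id {dup[0]} in {path} ({expected_axis})")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise DataError(
                f"non-numeric value at row {bad!r}, column {col!r} in {path}"
            ) from None
    if df.isna().any().any():
        row, col = next(
            (r, c) for r in df.index for c in df.columns if pd.isna(df.at[r, c])
        )
        raise DataError(f"missing value at row {row!r}, column {col!r} in {path}")
    return ExpressionMatrix(
        [str(r) for r in df.index], [str(c) for c in df.columns], df.to_numpy(float)
    )


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="id")


def _read_two_col(path: str | Path, header: bool) -> list[tuple[str, str]]:
    df = pd.read_csv(
        path, sep="\t", header=0 if header else None, dtype=str, usecols=[0, 1]
    )
    if df.shape[1] != 2:
        raise DataError(f"expected two tab-separated columns in {path}")
    df = df.dropna()
    return [(str(a), str(b)) for a, b in df.itertuples(index=False)]


def load_gene_isoform_map(path: str | Path, header: bool = False) -> GeneIsoformMap:
    """Read gene_id<TAB>isoform_id pairs."""
    return GeneIsoformMap.from_pairs(_read_two_col(path, header))


def load_annotations(path: str | Path, header: bool = False) -> AnnotationTable:
    """Read gene_id<TAB>term_id pairs."""
    return AnnotationTable.from_pairs(_read_two_col(path, header))


def load_homolog_groups(path: str | Path, header: bool = False) -> dict[str, str]:
    """Read gene_id<TAB>group_id pairs; genes absent from the file are
    treated as singleton groups downstream."""
    return dict(_read_two_col(path, header))


# ---------------------------------------------------------------------------
# Task assembly


def build_task(
    Xg: ExpressionMatrix,
    Xiso: ExpressionMatrix,
    mapping: GeneIsoformMap,
    annotations: AnnotationTable,
    term_id: str,
) -> PredictionTask:
    """Assemble one GO term's prediction task.

    Labels: ``yg[i] = 1`` iff gene i is annotated to ``term_id``, else 0
    (genes with no annotation rows at all are negatives for every term).
    Both matrices are column-centered by their own means.
    """
    if Xg.col_ids != Xiso.col_ids:
        raise DataError("gene and isoform matrices have different experiment columns")
    gene_set = set(Xg.row_ids)
    iso_set = set(Xiso.row_ids)
    unmapped = iso_set - set(mapping.gene_of)
    if unmapped:
        raise DataError(
            f"{len(unmapped)} isoforms absent from the gene-isoform map, "
            f"e.g. {sorted(unmapped)[0]}"
        )
    missing_genes = set(mapping.isoforms_of) - gene_set
    if missing_genes:
        raise DataError(
            f"{len(missing_genes)} mapped genes absent from the gene matrix, "
            f"e.g. {sorted(missing_genes)[0]}"
        )
    missing_isos = set(mapping.gene_of) - iso_set
    if missing_isos:
        raise DataError(
            f"{len(missing_isos)} mapped isoforms absent from the isoform matrix, "
            f"e.g. {sorted(missing_isos)[0]}"
        )
    annotated = annotations.annotated_genes(term_id) & gene_set
    yg = np.array([1.0 if g in annotated else 0.0 for g in Xg.row_ids])
    if yg.sum() == 0 or yg.sum() == len(yg):
        raise DataError(
            f"degenerate label vector: term {term_id} annotates "
            f"{int(yg.sum())} of {len(yg)} genes"
        )
    mg = Xg.values.mean(axis=0)
    mt = Xiso.values.mean(axis=0)
    return PredictionTask(
        term_id=term_id,
        gene_ids=list(Xg.row_ids),
        iso_ids=list(Xiso.row_ids),
        col_ids=list(Xg.col_ids),
        Xg=Xg.values - mg,
        Xiso=Xiso.values - mt,
        yg=yg,
        mapping=mapping,
        gene_col_means=mg,
        iso_col_means=mt,
    )


def filter_terms(
    annotations: AnnotationTable,
    universe: Iterable[str],
    min_size: int = 5,
    max_size: int = 1000,
) -> AnnotationTable:
    """Drop terms that are too specific (< ``min_size`` annotated dataset
    genes) or too general (> ``max_size``).  Sizes are recomputed over
    ``universe`` (the genes present in the expression data).  Idempotent."""
    if min_size < 1:
        raise DataError("min_size must be >= 1")
    if max_size < min_size:
        raise DataError("max_size must be >= min_size")
    uni = set(universe)
    kept = {
        term: genes & uni
        for term, genes in annotations.genes_of_term.items()
        if min_size <= len(genes & uni) <= max_size
    }
    if not kept:
        warnings.warn("no GO terms survive the size filter", stacklevel=2)
    return AnnotationTable(kept)


def apply_feature_subset(task: PredictionTask, subset: FeatureSubset) -> PredictionTask:
    """Column-restrict both matrices of a task to a feature subset.

    Retained columns keep the original column order.  The matrices are
    re-centered (a numerical no-op for exactly centered input, but it guards
    against accumulated drift in long pipelines).
    """
    idx = np.asarray(subset.indices, dtype=int)
    if idx.max() >= task.n_features:
        raise DataError(
            f"feature index {int(idx.max())} out of range for {task.n_features} features"
        )
    Xg = task.Xg[:, idx]
    Xiso = task.Xiso[:, idx]
    mg = Xg.mean(axis=0)
    mt = Xiso.mean(axis=0)
    return PredictionTask(
        term_id=task.term_id,
        gene_ids=list(task.gene_ids),
        iso_ids=list(task.iso_ids),
        col_ids=[task.col_ids[i] for i in idx],
        Xg=Xg - mg,
        Xiso=Xiso - mt,
        yg=task.yg.copy(),
        mapping=task.mapping,
        gene_col_means=task.gene_col_means[idx] + mg,
        iso_col_means=task.iso_col_means[idx] + mt,
    )
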