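"""Readers, writers and validated containers for the pipeline's tables.

All on-disk formats are tab-separated text with optional ``#``-prefixed
metadata lines. Gene identifiers are opaque strings: subgenome membership
comes only from the triad map columns, never from parsing identifier text,
so the pipeline is independent of any particular genome annotation's naming
scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DesignMismatchError,
    DuplicateGeneAcrossTriadsError,
    DuplicateTriadIdError,
    MalformedTableError,
)

__all__ = [
    "ExpressionMatrix",
    "TriadMap",
    "GeneSetAnnotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "read_triad_map",
    "write_triad_map",
    "read_annotation",
    "write_annotation",
    "read_pyro_table",
    "write_results",
    "read_results",
]

_SUBGENOMES = ("A", "B", "D")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample abundance matrix (FPKM-scale) plus its design.

    Parameters
    ----------
    values
        DataFrame indexed by gene_id with one column per sample_id; entries
        are non-negative finite abundances.
    design
        DataFrame indexed by sample_id with columns ``condition`` and
        ``replicate``; every sample column of ``values`` must appear here.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise MalformedTableError(f"duplicated gene_id rows: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            raise MalformedTableError("duplicated sample columns")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise MalformedTableError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise MalformedTableError("expression values must be finite")
        if (arr < 0).any():
            raise MalformedTableError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise DesignMismatchError(f"samples absent from design: {missing}")
        if "condition" not in self.design.columns:
            raise DesignMismatchError("design table lacks a 'condition' column")
        counts = self.design.loc[list(self.values.columns), "condition"].value_counts()
        singles = counts[counts < 2]
        if len(singles):
            warnings.warn(
                "conditions with a single replicate: "
                + ", ".join(singles.index.astype(str)),
                stacklevel=2,
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.design.loc[list(self.values.columns), "condition"]))

    def samples_for(self, condition: str) -> list[str]:
        sel = self.design.loc[list(self.values.columns)]
        out = list(sel.index[sel["condition"] == condition])
        if not out:
            raise DesignMismatchError(f"condition {condition!r} not in design")
        return out

    def replicates(self, condition: str) -> pd.DataFrame:
        """Gene-by-replicate sub-matrix for one condition."""
        return self.values[self.samples_for(condition)]

    def condition_means(self, condition: str) -> pd.Series:
        return self.replicates(condition).mean(axis=1)


@dataclass
class TriadMap:
    """Collection of homoeologous triads: one gene per subgenome (A, B, D).

    The three members of a triad are distinct, and no gene belongs to more
    than one triad, so gene coverage is exactly ``3 * len(triads)``.
    """

    table: pd.DataFrame  # columns: triad_id, gene_A, gene_B, gene_D, syntenic

    def __post_init__(self) -> None:
        required = ["triad_id", "gene_A", "gene_B", "gene_D"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise MalformedTableError(f"triad map lacks columns: {missing}")
        if "syntenic" not in self.table.columns:
            self.table = self.table.assign(syntenic=True)
        self.table = self.table.reset_index(drop=True)
        tid = self.table["triad_id"]
        if tid.duplicated().any():
            raise DuplicateTriadIdError(
                f"duplicated triad ids: {list(tid[tid.duplicated()].unique()[:5])}"
            )
        genes = pd.concat([self.table[f"gene_{s}"] for s in _SUBGENOMES])
        if genes.duplicated().any():
            raise DuplicateGeneAcrossTriadsError(
                "gene ids shared between or within triads: "
                f"{list(genes[genes.duplicated()].unique()[:5])}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> pd.Index:
        """All member genes, triad-major order (A, B, D per triad)."""
        cols = [self.table[f"gene_{s}"] for s in _SUBGENOMES]
        return pd.Index(np.stack(cols, axis=1).ravel())

    @property
    def n_genes(self) -> int:
        return 3 * len(self.table)

    def syntenic_only(self) -> "TriadMap":
        return TriadMap(self.table[self.table["syntenic"].astype(bool)].copy())


@dataclass
class GeneSetAnnotation:
    """Flat gene-to-term annotation (e.g. GO) as unique (gene, term) pairs."""

    pairs: pd.DataFrame  # columns: gene_id, term_id

    def __post_init__(self) -> None:
        for c in ("gene_id", "term_id"):
            if c not in self.pairs.columns:
                raise MalformedTableError(f"annotation lacks column {c!r}")
        self.pairs = self.pairs[["gene_id", "term_id"]].drop_duplicates().reset_index(drop=True)

    @property
    def genes(self) -> set:
        return set(self.pairs["gene_id"])

    @property
    def terms(self) -> set:
        return set(self.pairs["term_id"])

    def term_sizes(self) -> pd.Series:
        return self.pairs.groupby("term_id")["gene_id"].nunique()

    def genes_for(self, term_id: str) -> set:
        return set(self.pairs.loc[self.pairs["term_id"] == term_id, "gene_id"])


# -- TSV plumbing --------------------------------------------------------------


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise MalformedTableError(f"{path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise MalformedTableError(f"{path}: empty file") from exc
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a design table (sample_id, condition, replicate) indexed by sample."""
    df = _read_tsv(path, dtype={"sample_id": str, "condition": str})
    for c in ("sample_id", "condition", "replicate"):
        if c not in df.columns:
            raise MalformedTableError(f"design file lacks column {c!r}")
    if df["sample_id"].duplicated().any():
        raise MalformedTableError("duplicated sample_id in design")
    return df.set_index("sample_id")


def read_expression_matrix(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column ``gene_id``) with its design."""
    df = _read_tsv(path)
    if df.shape[1] < 2 or df.columns[0] != "gene_id":
        raise MalformedTableError(
            f"{path}: expected header starting with 'gene_id' plus sample columns"
        )
    df = df.set_index("gene_id")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise MalformedTableError(f"{path}: non-numeric values in column {col!r}")
    design = read_design(design_path)
    return ExpressionMatrix(values=df.astype(float), design=design)


def read_triad_map(path: str | Path) -> TriadMap:
    df = _read_tsv(path, dtype=str)
    if "syntenic" in df.columns:
        df["syntenic"] = df["syntenic"].map(
            {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
        )
        if df["syntenic"].isna().any():
            raise MalformedTableError(f"{path}: unparseable 'syntenic' values")
    return TriadMap(df)


def read_annotation(path: str | Path) -> GeneSetAnnotation:
    """Read a two-column (gene_id, term_id) TSV; a headerless file is accepted."""
    df = _read_tsv(path, dtype=str)
    if not {"gene_id", "term_id"}.issubset(df.columns):
        df = _read_tsv(path, dtype=str, header=None, names=["gene_id", "term_id"])
    return GeneSetAnnotation(df)


def read_pyro_table(path: str | Path) -> pd.DataFrame:
    """Read pyrosequencing percentages (triad_id, pct_A, pct_B, pct_D[, snp_label])."""
    df = _read_tsv(path)
    required = ["triad_id", "pct_A", "pct_B", "pct_D"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedTableError(f"{path}: pyro table lacks columns {missing}")
    return df


def _header_lines(params: Mapping[str, object] | None) -> str:
    from . import __version__

    lines = [f"# triadshift {__version__}"]
    if params:
        kv = " ".join(f"{k}={v}" for k, v in params.items())
        lines.append(f"# params: {kv}")
    return "\n".join(lines) + "\n"


def write_results(
    table: pd.DataFrame,
    path: str | Path,
    params: Mapping[str, object] | None = None,
    index: bool = False,
    float_format: str = "%.6g",
) -> None:
    """Write any result table as TSV with a ``#`` metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        table.to_csv(fh, sep="\t", index=index, float_format=float_format)


def read_results(path: str | Path, index_col=None) -> pd.DataFrame:
    """Re-read a table written by :func:`write_results`."""
    return _read_tsv(path, index_col=index_col)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    design_path: str | Path | None = None,
    params: Mapping[str, object] | None = None,
) -> None:
    out = matrix.values.reset_index()
    out.columns = ["gene_id", *matrix.values.columns]
    write_results(out, path, params=params)
    if design_path is not None:
        write_results(matrix.design.reset_index(), design_path)


def write_triad_map(triads: TriadMap, path: str | Path) -> None:
    write_results(triads.table, path)


def write_annotation(annotation: GeneSetAnnotation, path: str | Path) -> None:
    write_results(annotation.pairs, path)
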