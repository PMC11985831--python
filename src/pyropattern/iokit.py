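"""Validated readers/writers for the pipeline's external formats.

Containers
----------
ExpressionMatrix   gene x sample real matrix, log2 or linear scale
GeneSetCollection  named gene sets (GMT-backed)
SurvTable          per-sample survival + clinical covariates (DataFrame)
CellAnnotation     per-cell sample / cell-type / malignancy table (DataFrame)
EdgeList           undirected gene-gene edges

All readers are strict: malformed input raises ``ValueError`` naming the
offending row or column; nothing is silently coerced.  Gene identifiers are
HGNC-style symbols matched case-sensitively after whitespace trimming.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "EdgeList",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_gmt",
    "write_gmt",
    "read_table",
    "read_counts_mtx",
    "validate_surv_table",
    "validate_cell_annotation",
]

KARYOTYPE_RISK_LEVELS = ("favorable", "intermediate/normal", "poor")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with an explicit scale flag.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are genes, columns are samples.
    scale : {"log2", "linear"}
        Scale of the stored values.  Most of the pipeline operates on
        log2-transformed expression; NMF consumes the linear scale.
    meta : dict
        Free-form provenance (generator parameters, seeds, ...).
    """

    data: pd.DataFrame
    scale: str = "log2"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals.astype(float)).all():
            bad = np.argwhere(~np.isfinite(vals.astype(float)))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_linear(self) -> "ExpressionMatrix":
        """Return the matrix on the linear scale (2**x for log2 input)."""
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.exp2(self.data), scale="linear", meta=dict(self.meta))

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        vals = self.data.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative values cannot be log2-transformed")
        return ExpressionMatrix(np.log2(self.data + 1.0), scale="log2", meta=dict(self.meta))

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[genes], scale=self.scale, meta=dict(self.meta))


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, as stored in a GMT file."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name: {name!r}")
        members = list(members)
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = (description, members)


@dataclass
class EdgeList:
    """Undirected, deduplicated gene-gene edges (no self-loops)."""

    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        clean: list[tuple[str, str]] = []
        for a, b in self.edges:
            if a == b:
                continue
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            clean.append(tuple(sorted((a, b))))  # type: ignore[arg-type]
        self.edges = clean

    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_matrix_tsv(path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    """Read a gene x sample TSV matrix (first column = gene symbols).

    Rejects duplicate identifiers, non-numeric cells and ragged rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample identifiers: {dups}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene identifiers: {dups}")
    df.index = df.index.str.strip()
    try:
        numeric = df.astype(float)
    except ValueError:
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell at gene {gene!r}, sample {sample!r}: {cell!r}"
                    ) from None
        raise
    if numeric.isna().any().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value in row {gene!r} (ragged or empty cell)")
    return ExpressionMatrix(numeric, scale=scale)


def write_matrix_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with a leading ``gene`` identifier column."""
    df = expr.data.copy()
    df.index.name = "gene"
    df.to_csv(Path(path), sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file (name TAB description TAB members...).

    Duplicate members within a set are deduplicated with a warning;
    duplicate set names are an error.
    """
    path = Path(path)
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            members = [m.strip() for m in members if m.strip()]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r} deduplicated")
            if name in coll:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            coll.add(name, deduped, desc)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for name, (desc, members) in coll.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# typed tables
# ---------------------------------------------------------------------------

def validate_surv_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a survival table (index = sample id).

    Requires ``os_time`` > 0 and ``os_event`` in {0, 1}; optional ``age``,
    ``sex`` and ``karyotype_risk`` columns are type-checked when present.
    """
    for col in ("os_time", "os_event"):
        if col not in df.columns:
            raise ValueError(f"survival table missing mandatory column {col!r}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in survival table: {dups}")
    t = pd.to_numeric(df["os_time"], errors="raise")
    if (t <= 0).any():
        bad = df.index[t <= 0].tolist()
        raise ValueError(f"os_time must be > 0; offending samples: {bad}")
    ev = pd.to_numeric(df["os_event"], errors="raise")
    if not ev.isin([0, 1]).all():
        bad = df.index[~ev.isin([0, 1])].tolist()
        raise ValueError(f"os_event must be 0 or 1; offending samples: {bad}")
    out = df.copy()
    out["os_time"] = t.astype(float)
    out["os_event"] = ev.astype(int)
    if "karyotype_risk" in out.columns:
        unknown = set(out["karyotype_risk"].dropna()) - set(KARYOTYPE_RISK_LEVELS)
        if unknown:
            raise ValueError(
                f"unknown karyotype_risk categories {sorted(unknown)}; "
                f"expected one of {KARYOTYPE_RISK_LEVELS}"
            )
    return out


def validate_cell_annotation(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-cell annotation table (index = cell id)."""
    for col in ("sample_id", "cell_type", "malignant"):
        if col not in df.columns:
            raise ValueError(f"cell annotation missing mandatory column {col!r}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate cell ids: {dups}")
    if df["sample_id"].astype(str).str.len().eq(0).any():
        raise ValueError("cell annotation contains empty sample ids")
    mal = pd.to_numeric(df["malignant"], errors="raise")
    if not mal.isin([0, 1]).all():
        raise ValueError("malignant flag must be 0 or 1")
    out = df.copy()
    out["malignant"] = mal.astype(int)
    return out


def read_table(path: str | Path, schema: str,
               colmap: Mapping[str, str] | None = None):
    """Read and validate a typed TSV table.

    Parameters
    ----------
    schema : {"survival", "cells", "edges"}
        ``survival`` -> survival DataFrame indexed by sample id;
        ``cells``    -> cell annotation DataFrame indexed by cell id;
        ``edges``    -> :class:`EdgeList` (self-loops dropped with a warning,
        duplicate/mirrored edges collapsed).
    colmap : mapping, optional
        Renames file columns to the schema's canonical names before
        validation (e.g. ``{"OS.time": "os_time"}``).
    """
    path = Path(path)
    if schema == "edges":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: edge list needs two columns")
        pairs = []
        for _, row in df.iterrows():
            a, b = str(row.iloc[0]).strip(), str(row.iloc[1]).strip()
            if a == b:
                warnings.warn(f"{path}: self-loop {a!r}-{b!r} dropped")
                continue
            pairs.append((a, b))
        return EdgeList(pairs)

    df = pd.read_csv(path, sep="\t", index_col=0)
    if colmap:
        df = df.rename(columns=dict(colmap))
    if schema == "survival":
        return validate_surv_table(df)
    if schema == "cells":
        return validate_cell_annotation(df)
    raise ValueError(f"unknown schema {schema!r}")


# ---------------------------------------------------------------------------
# sparse counts (10x-style MTX triple)
# ---------------------------------------------------------------------------

def read_counts_mtx(mtx_path: str | Path, features_path: str | Path,
                    barcodes_path: str | Path) -> pd.DataFrame:
    """Read a gene x cell count matrix from an MTX + features + barcodes triple."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).toarray()
    genes = [line.split("\t")[0].strip()
             for line in Path(features_path).read_text().splitlines() if line.strip()]
    cells = [line.strip() for line in Path(barcodes_path).read_text().splitlines() if line.strip()]
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"MTX shape {mat.shape} does not match features x barcodes "
            f"({len(genes)} x {len(cells)})"
        )
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    df = pd.DataFrame(mat, index=genes, columns=cells)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers in features file: {dups}")
    if df.columns.has_duplicates:
        raise ValueError("duplicate cell barcodes")
    return df
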