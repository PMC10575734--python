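"""Readers and writers for gene sets, expression matrices, and result tables.

Supported formats are deliberately plain-text: GMT for gene sets, dense
delimited tables or MatrixMarket coordinate triplets for expression, and
CSV/TSV for annotations and results.  Delimiters are inferred from the file
extension (``.csv`` -> comma, anything else -> tab) unless overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("persistkit")

__all__ = [
    "FormatError",
    "GeneSet",
    "ExpressionMatrix",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_table",
    "detect_delimiter",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def detect_delimiter(path: str | Path, override: str | None = None) -> str:
    """Pick the field delimiter for *path* from its extension.

    ``.csv`` maps to comma; everything else (``.tsv``, ``.txt``, ...) to tab.
    An explicit *override* always wins.
    """
    if override is not None:
        return override
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers.

    Gene order is preserved (first occurrence wins on duplicates).
    """

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        if not self.genes:
            raise ValueError(f"GeneSet {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"GeneSet {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class ExpressionMatrix:
    """Genes-by-observations matrix of normalized expression.

    ``values`` is a DataFrame indexed by gene identifier with one column per
    observation; ``obs`` holds per-observation annotations (patient,
    timepoint, condition, ...) indexed by observation identifier.  Values are
    expected on a log-like normalized scale and are never re-normalized here.
    """

    values: pd.DataFrame
    obs: pd.DataFrame = field(default_factory=pd.DataFrame)
    timepoint_vocabulary: tuple[str, ...] = ("pre", "on", "relapse")

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate observation identifiers: {dupes[:5]}")
        # strip whitespace so identifiers compare cleanly
        self.values.index = self.values.index.astype(str).str.strip()
        self.values.columns = self.values.columns.astype(str).str.strip()
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            n_bad = int((~np.isfinite(self.values.to_numpy(dtype=float))).sum())
            raise ValueError(f"expression matrix contains {n_bad} non-finite values")
        if self.obs.empty:
            self.obs = pd.DataFrame(index=self.values.columns)
        else:
            self.obs = self.obs.loc[self.values.columns]
        if "timepoint" in self.obs.columns:
            bad = set(self.obs["timepoint"].dropna()) - set(self.timepoint_vocabulary)
            if bad:
                raise ValueError(
                    f"timepoint values {sorted(bad)} outside vocabulary "
                    f"{self.timepoint_vocabulary}"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def obs_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def n_obs(self) -> int:
        return len(self.values.columns)

    def gene(self, gene_id: str, case_insensitive: bool = False) -> pd.Series:
        """Expression of one gene across observations.

        Matching is case-sensitive after whitespace trimming; pass
        ``case_insensitive=True`` for a fallback lookup (useful when mixing
        human ``CD36`` with mouse ``Cd36`` symbols).
        """
        key = gene_id.strip()
        if key in self.values.index:
            return self.values.loc[key]
        if case_insensitive:
            lowered = self.values.index.str.lower()
            hits = np.flatnonzero(lowered == key.lower())
            if len(hits) == 1:
                return self.values.iloc[hits[0]]
            if len(hits) > 1:
                raise KeyError(f"gene {gene_id!r} is ambiguous case-insensitively")
        raise KeyError(f"gene {gene_id!r} not present in matrix")

    def subset_obs(self, obs_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(obs_ids)].copy(), self.obs.loc[list(obs_ids)].copy())


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one gene set per tab-separated line.

    Fields are ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Duplicate
    genes within a line are collapsed, keeping first-occurrence order.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has {len(fields)} fields, need >= 3")
            name, description, *genes = fields
            deduped = list(dict.fromkeys(g.strip() for g in genes if g.strip()))
            if not deduped:
                raise FormatError(f"{path}: line {lineno} ({name!r}) has an empty gene list")
            sets.append(GeneSet(name=name, description=description, genes=tuple(deduped)))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_expression(
    path: str | Path,
    dialect: str = "dense",
    *,
    rows_path: str | Path | None = None,
    cols_path: str | Path | None = None,
    orientation: str = "genes_by_obs",
    delimiter: str | None = None,
    annotations: str | Path | pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix.

    ``dialect='dense'`` expects a delimited table with gene rows and
    observation columns (first column = gene identifiers).  For
    ``dialect='mtx_triplet'`` supply the MatrixMarket coordinate file as
    *path* plus plain-text *rows_path* / *cols_path* name files (one name
    per line); *orientation* states explicitly whether matrix rows are genes
    (``genes_by_obs``) or observations (``obs_by_genes``) — it is never
    guessed.
    """
    if dialect == "dense":
        sep = detect_delimiter(path, delimiter)
        df = pd.read_csv(path, sep=sep, index_col=0)
    elif dialect == "mtx_triplet":
        if rows_path is None or cols_path is None:
            raise ValueError("mtx_triplet dialect needs rows_path and cols_path")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows = [ln.strip() for ln in Path(rows_path).read_text().splitlines() if ln.strip()]
        cols = [ln.strip() for ln in Path(cols_path).read_text().splitlines() if ln.strip()]
        if mat.shape[0] != len(rows):
            raise FormatError(
                f"row-name file has {len(rows)} names but matrix has {mat.shape[0]} rows"
            )
        if mat.shape[1] != len(cols):
            raise FormatError(
                f"column-name file has {len(cols)} names but matrix has {mat.shape[1]} columns"
            )
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=rows, columns=cols)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if orientation == "obs_by_genes":
        df = df.T
    elif orientation != "genes_by_obs":
        raise ValueError(f"unknown orientation {orientation!r}")

    obs = pd.DataFrame()
    if annotations is not None:
        obs = annotations if isinstance(annotations, pd.DataFrame) else read_annotations(annotations)
    return ExpressionMatrix(values=df, obs=obs)


def write_expression(matrix: ExpressionMatrix, path: str | Path, delimiter: str | None = None) -> None:
    sep = detect_delimiter(path, delimiter)
    matrix.values.to_csv(path, sep=sep)


def read_annotations(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a per-observation annotation table (first column = observation id)."""
    sep = detect_delimiter(path, delimiter)
    return pd.read_csv(path, sep=sep, index_col=0)


def write_table(records: pd.DataFrame, path: str | Path, delimiter: str | None = None) -> None:
    """Write a result table as delimited text.

    Column order follows the DataFrame; missing values become empty fields;
    fields containing the delimiter are quoted by the CSV writer.
    """
    if records.shape[1] == 0:
        raise ValueError("result table has no columns (empty header)")
    sep = detect_delimiter(path, delimiter)
    records.to_csv(path, sep=sep, index=False, na_rep="")
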