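"""Expression matrix and cell annotation handling.

Loads gene x cell count matrices (MatrixMarket triplet with gene/cell
sidecars, or dense TSV), attaches cell-type annotations, normalizes to
counts per million (CPM), and aggregates per-cell-type mean expression.
The per-type means are the sole expression summary consumed by the
downstream specificity calculation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "CellAnnotation",
    "MeanExpressionTable",
    "load_expression",
    "load_annotation",
    "cpm_normalize",
    "mean_by_cell_type",
]

#: cells-per-type count below which a warning is logged (very small groups
#: give noisy per-type means but are still analyzed, matching practice with
#: rare populations such as endothelial nuclei).
SMALL_TYPE_WARN = 10


@dataclass
class ExpressionMatrix:
    """Nonnegative gene x cell expression matrix with identifiers.

    Parameters
    ----------
    genes : sequence of str
        Unique gene identifiers, one per matrix row.
    cells : sequence of str
        Unique cell identifiers, one per matrix column.
    values : ndarray
        Dense (n_genes, n_cells) array of nonnegative counts or CPM.
    unit : {"counts", "cpm"}
        Measurement unit of ``values``.
    """

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Index(self.genes)
            raise ValueError(
                "duplicate gene identifiers: "
                + ", ".join(sorted(dupes[dupes.duplicated()].unique()[:5]))
            )
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell identifiers")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite entries")
        if (self.values < 0).any():
            raise ValueError("expression matrix contains negative values")
        if self.unit not in ("counts", "cpm"):
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class CellAnnotation:
    """Mapping of cell identifiers to cell-type labels.

    ``types`` preserves first-appearance order of the k distinct labels;
    at least two types are required so that every cell type has a
    non-empty reference set for the fold-change specificity.
    """

    cell_to_type: Mapping[str, str]
    types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cell_to_type = dict(self.cell_to_type)
        if not self.types:
            seen: dict[str, None] = {}
            for t in self.cell_to_type.values():
                seen.setdefault(t, None)
            self.types = list(seen)
        if len(self.types) < 2:
            raise ValueError(
                f"need at least 2 cell types, got {len(self.types)}: {self.types}"
            )

    @property
    def k(self) -> int:
        return len(self.types)

    def cells_of_type(self, cell_type: str) -> list[str]:
        return [c for c, t in self.cell_to_type.items() if t == cell_type]


@dataclass
class MeanExpressionTable:
    """Per-cell-type arithmetic mean expression (genes x k) with group sizes."""

    genes: list[str]
    types: list[str]
    means: np.ndarray
    n_cells: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.n_cells = np.asarray(self.n_cells, dtype=int)
        if self.means.shape != (len(self.genes), len(self.types)):
            raise ValueError("means shape does not match genes x types")
        if (self.means < 0).any():
            raise ValueError("negative mean expression")
        if (self.n_cells < 1).any():
            raise ValueError("every retained cell type needs >= 1 cell")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=self.genes, columns=self.types)


def _looks_like_mtx(path: Path) -> bool:
    name = path.name.lower()
    if name.endswith((".mtx", ".mtx.gz")):
        return True
    try:
        with open(path, "rb") as fh:
            return fh.read(14) == b"%%MatrixMarket"
    except OSError:
        return False


def load_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Load a counts matrix from MTX (with sidecars) or dense TSV.

    MatrixMarket input stores genes as rows and cells as columns; the
    sidecar files list one gene / cell identifier per line in row /
    column order. Dense TSV input has a header row of cell identifiers
    and the gene identifier in the first column.
    """
    matrix_path = Path(matrix_path)
    if not matrix_path.exists():
        raise FileNotFoundError(matrix_path)

    if _looks_like_mtx(matrix_path):
        if genes_path is None or cells_path is None:
            raise ValueError(
                "MatrixMarket input requires both a gene and a cell sidecar file"
            )
        try:
            mat = scipy.io.mmread(str(matrix_path))
        except ValueError as exc:
            raise ValueError(f"malformed MatrixMarket file {matrix_path}: {exc}") from exc
        genes = _read_id_list(genes_path)
        cells = _read_id_list(cells_path)
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix declares shape {mat.shape} but sidecars list "
                f"{len(genes)} genes and {len(cells)} cells"
            )
        values = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        return ExpressionMatrix(genes, cells, values, unit="counts")

    try:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed dense TSV {matrix_path}: {exc}") from exc
    if df.index.has_duplicates:
        raise ValueError(
            "duplicate gene rows in "
            f"{matrix_path}: {sorted(df.index[df.index.duplicated()].unique()[:5])}"
        )
    non_numeric = df.columns[df.dtypes == object]
    if len(non_numeric):
        raise ValueError(
            f"non-numeric expression values in columns {list(non_numeric[:5])}"
        )
    return ExpressionMatrix(
        list(df.index.astype(str)),
        list(df.columns.astype(str)),
        df.to_numpy(dtype=float),
        unit="counts",
    )


def _read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise ValueError(f"empty identifier sidecar {path}")
    return ids


def load_annotation(path: str | Path, expr: ExpressionMatrix) -> CellAnnotation:
    """Read a cell_id/cell_type TSV and align it to the expression matrix.

    Cells found in only one of the two inputs are dropped with a warning;
    zero overlap or fewer than two surviving cell types is fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"annotation {path} must have 2 columns (cell_id, cell_type)")
    df = df.iloc[:, :2]
    df.columns = ["cell_id", "cell_type"]
    if df["cell_id"].duplicated().any():
        raise ValueError(f"duplicate cell_id entries in annotation {path}")

    expr_cells = set(expr.cells)
    ann_cells = set(df["cell_id"])
    extra = ann_cells - expr_cells
    missing = expr_cells - ann_cells
    if extra:
        logger.warning(
            "%d annotated cells absent from the expression matrix; ignored", len(extra)
        )
    if missing:
        logger.warning(
            "%d expression-matrix cells have no annotation; dropped from analysis",
            len(missing),
        )
    kept = df[df["cell_id"].isin(expr_cells)]
    if kept.empty:
        raise ValueError("no overlap between annotated cells and expression matrix")

    mapping = dict(zip(kept["cell_id"], kept["cell_type"]))
    types = list(dict.fromkeys(kept["cell_type"]))
    if len(types) < 2:
        raise ValueError(
            f"need at least 2 cell types after alignment, got {len(types)}"
        )
    ann = CellAnnotation(mapping, types)
    for t in types:
        n = len(ann.cells_of_type(t))
        if n < SMALL_TYPE_WARN:
            logger.warning("cell type %r has only %d cells; means will be noisy", t, n)
    return ann


def cpm_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell to counts per million (column sums become 1e6)."""
    if expr.unit != "counts":
        raise ValueError(f"cpm_normalize expects counts, got unit {expr.unit!r}")
    libsize = expr.values.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValueError(
            f"cell {expr.cells[zero[0]]!r} has zero library size; "
            "remove empty cells before normalization"
        )
    values = expr.values * (1e6 / libsize)
    return ExpressionMatrix(expr.genes, expr.cells, values, unit="cpm")


def mean_by_cell_type(expr: ExpressionMatrix, ann: CellAnnotation) -> MeanExpressionTable:
    """Average CPM expression of every gene within each annotated cell type."""
    if expr.unit != "cpm":
        raise ValueError("mean_by_cell_type expects a CPM-normalized matrix")
    col = {c: i for i, c in enumerate(expr.cells)}
    means = np.empty((expr.n_genes, ann.k))
    n_cells = np.empty(ann.k, dtype=int)
    for j, t in enumerate(ann.types):
        idx = [col[c] for c in ann.cells_of_type(t) if c in col]
        if not idx:
            raise ValueError(f"cell type {t!r} has no cells in the expression matrix")
        means[:, j] = expr.values[:, idx].mean(axis=1)
        n_cells[j] = len(idx)
    return MeanExpressionTable(list(expr.genes), list(ann.types), means, n_cells)
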