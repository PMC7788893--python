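"""Cell type-specificity and cell-type score of genes.

The specificity of gene g in cell type c is the minimum fold change of
its mean expression against every other cell type:

    specificity[g, c] = min over r != c of mean[g, c] / mean[g, r]

The cell-type score standardizes each gene's specificity vector by its
own median and interquartile range across cell types:

    score[g, c] = (specificity[g, c] - median_g) / IQR_g

A positive score therefore means the gene is more specific to c than to
the typical cell type; at most floor(k/2) of a gene's k scores can be
positive, which is what makes a positive threshold selective.

Ratio conventions for zero means: x/0 with x > 0 is +inf (the candidate
type wins only if every reference is silent), 0/0 contributes nothing
(NA for that reference), and a gene whose references are all NA gets NA
specificity. Median and IQR use the linear-interpolation quantile
definition (R type 7); rows with an infinite median or a zero IQR
yield NA scores, and a +inf specificity maps to a +inf score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .expression import MeanExpressionTable

logger = logging.getLogger(__name__)

__all__ = [
    "SpecificityTable",
    "ScoreTable",
    "compute_specificity",
    "compute_score",
    "score_correlation",
    "write_score_table",
    "read_score_table",
]


@dataclass
class SpecificityTable:
    """Per-gene, per-cell-type minimum fold change; NaN marks NA."""

    genes: list[str]
    types: list[str]
    specificity: np.ndarray

    def __post_init__(self) -> None:
        self.specificity = np.asarray(self.specificity, dtype=float)
        if self.specificity.shape != (len(self.genes), len(self.types)):
            raise ValueError("specificity shape does not match genes x types")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.specificity, index=self.genes, columns=self.types)


@dataclass
class ScoreTable:
    """Median/IQR-standardized specificity; NaN marks NA."""

    genes: list[str]
    types: list[str]
    score: np.ndarray
    specificity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.genes), len(self.types)):
            raise ValueError("score shape does not match genes x types")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.score, index=self.genes, columns=self.types)

    def scores_for_type(self, cell_type: str) -> pd.Series:
        if cell_type not in self.types:
            raise ValueError(f"unknown cell type {cell_type!r}")
        return self.to_frame()[cell_type]


def compute_specificity(means: MeanExpressionTable) -> SpecificityTable:
    """Minimum fold change of per-type mean expression against each other type."""
    M = means.means
    k = M.shape[1]
    if k < 2:
        raise ValueError("specificity needs at least 2 cell types")
    spec = np.full_like(M, np.nan, dtype=float)
    for c in range(k):
        others = np.delete(M, c, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = M[:, [c]] / others  # x/0 -> inf, 0/0 -> nan
        defined = ~np.all(np.isnan(ratios), axis=1)
        with np.errstate(invalid="ignore"):
            spec[defined, c] = np.nanmin(ratios[defined], axis=1)
    return SpecificityTable(list(means.genes), list(means.types), spec)


def _quantile_type7(sorted_vals: np.ndarray, p: float) -> float:
    """Linear-interpolation quantile on pre-sorted values, +inf-safe."""
    n = sorted_vals.size
    h = (n - 1) * p
    lo = math.floor(h)
    g = h - lo
    a = sorted_vals[lo]
    if g == 0:
        return float(a)
    b = sorted_vals[lo + 1]
    if np.isinf(b):
        return float(b) if not np.isinf(a) else float(a)
    return float(a + g * (b - a))


def compute_score(spec: SpecificityTable) -> ScoreTable:
    """Standardize each gene's specificity by its median and IQR across types.

    Genes with fewer than two non-NA specificities, zero IQR, or an
    infinite median get an all-NA score row (logged). A +inf
    specificity (a gene silent in every other type) always maps to a
    +inf score — it passes any finite threshold — even when it makes
    the row's IQR infinite, in which case the row's finite entries are
    NA.
    """
    S = spec.specificity
    score = np.full_like(S, np.nan, dtype=float)
    n_degenerate = 0
    for i in range(S.shape[0]):
        row = S[i]
        vals = np.sort(row[~np.isnan(row)])
        if vals.size < 2:
            n_degenerate += 1
            continue
        med = _quantile_type7(vals, 0.5)
        if not np.isfinite(med):
            n_degenerate += 1
            continue
        iqr = _quantile_type7(vals, 0.75) - _quantile_type7(vals, 0.25)
        exclusive = np.isposinf(row)
        if not np.isfinite(iqr) or iqr == 0:
            if exclusive.any():
                score[i, exclusive] = np.inf
            else:
                n_degenerate += 1
            continue
        with np.errstate(invalid="ignore"):
            score[i] = (row - med) / iqr
    if n_degenerate:
        logger.info(
            "%d genes have undefined scores (too few defined specificities, "
            "zero IQR, or infinite median/IQR)",
            n_degenerate,
        )
    return ScoreTable(list(spec.genes), list(spec.types), score, specificity=S)


def score_correlation(scores: ScoreTable, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Spearman correlation of cell-type score vectors across genes.

    Each pair uses only genes with defined scores in both types; pairs
    sharing fewer than ``min_shared`` genes yield NaN with a warning.
    """
    k = len(scores.types)
    S = scores.score
    out = np.full((k, k), np.nan)
    np.fill_diagonal(out, 1.0)
    for a in range(k):
        for b in range(a + 1, k):
            mask = ~np.isnan(S[:, a]) & ~np.isnan(S[:, b])
            if mask.sum() < min_shared:
                logger.warning(
                    "cell types %r and %r share only %d scored genes; "
                    "correlation undefined",
                    scores.types[a],
                    scores.types[b],
                    int(mask.sum()),
                )
                continue
            rho = stats.spearmanr(S[mask, a], S[mask, b]).statistic
            out[a, b] = out[b, a] = rho
    return pd.DataFrame(out, index=scores.types, columns=scores.types)


def write_score_table(scores: ScoreTable, path: str | Path) -> None:
    """Write the long-format gene/cell_type/specificity/score TSV.

    Only rows with a defined (non-NA) specificity are emitted; an
    undefined score on a defined specificity is rendered as "NA".
    """
    if scores.specificity is None:
        raise ValueError("score table lacks its specificity provenance")
    rows = []
    for i, g in enumerate(scores.genes):
        for j, t in enumerate(scores.types):
            s = scores.specificity[i, j]
            if np.isnan(s):
                continue
            sc = scores.score[i, j]
            rows.append(
                (g, t, _fmt(s), "NA" if np.isnan(sc) else _fmt(sc))
            )
    df = pd.DataFrame(rows, columns=["gene", "cell_type", "specificity", "score"])
    df.to_csv(path, sep="\t", index=False)


def _fmt(x: float) -> str:
    if np.isposinf(x):
        return "Inf"
    return format(x, ".10g")


def read_score_table(path: str | Path) -> ScoreTable:
    """Read a long-format score TSV (possibly produced by another metric).

    Returns a wide ScoreTable; (gene, cell_type) pairs absent from the
    file get NA scores.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "cell_type": str})
    required = {"gene", "cell_type", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"score table {path} needs columns {sorted(required)}")
    df["score"] = df["score"].replace({"NA": np.nan, "Inf": np.inf}).astype(float)
    genes = list(dict.fromkeys(df["gene"]))
    types = list(dict.fromkeys(df["cell_type"]))
    wide = df.pivot_table(index="gene", columns="cell_type", values="score", aggfunc="first")
    wide = wide.reindex(index=genes, columns=types)
    spec = None
    if "specificity" in df.columns:
        df["specificity"] = (
            df["specificity"].replace({"NA": np.nan, "Inf": np.inf}).astype(float)
        )
        spec = (
            df.pivot_table(index="gene", columns="cell_type", values="specificity", aggfunc="first")
            .reindex(index=genes, columns=types)
            .to_numpy()
        )
    return ScoreTable(genes, types, wide.to_numpy(), specificity=spec)
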