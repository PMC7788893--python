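"""Weighted gene interaction networks and cell type-specific subnetworks.

The reference network is an undirected weighted edge list (for example a
tissue-specific functional network downloaded as "top edges"). Stages:
drop the lowest-ranked fraction of edges by weight, restrict to the
genes present in the expression data, then induce one subnetwork per
cell type on the genes whose cell-type score exceeds a threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .scoring import ScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "CellTypeNetwork",
    "load_network",
    "write_network",
    "filter_by_weight_rank",
    "restrict_to_genes",
    "extract_cell_type_network",
    "jaccard_similarity",
]

_EDGE_COLS = ["gene1", "gene2", "weight"]


@dataclass
class GeneNetwork:
    """Undirected weighted network stored as a canonical edge table.

    Edges are canonicalized so gene1 < gene2 and each unordered pair
    appears once; ``vertices`` is the union of edge endpoints plus any
    explicitly retained isolated genes.
    """

    edges: pd.DataFrame
    vertices: frozenset[str] = field(default_factory=frozenset)
    label: str = ""

    def __post_init__(self) -> None:
        df = self.edges.reset_index(drop=True)
        if list(df.columns) != _EDGE_COLS:
            raise ValueError(f"edge table must have columns {_EDGE_COLS}")
        if (df["gene1"] >= df["gene2"]).any():
            raise ValueError("edges must be canonicalized with gene1 < gene2")
        if df.duplicated(subset=["gene1", "gene2"]).any():
            raise ValueError("duplicate edges in canonical edge table")
        w = df["weight"].to_numpy()
        if not np.isfinite(w).all() or (w < 0).any():
            raise ValueError("edge weights must be finite and >= 0")
        endpoint = set(df["gene1"]) | set(df["gene2"])
        if not self.vertices:
            self.vertices = frozenset(endpoint)
        elif not endpoint <= self.vertices:
            raise ValueError("vertex set does not cover all edge endpoints")
        self.edges = df

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_weighted_edges_from(
            self.edges.itertuples(index=False, name=None), weight="weight"
        )
        return g


@dataclass
class CellTypeNetwork:
    """A score-thresholded induced subnetwork for one cell type."""

    network: GeneNetwork
    cell_type: str
    threshold: float
    score_source: str = ""

    @property
    def vertices(self) -> frozenset[str]:
        return self.network.vertices

    @property
    def edges(self) -> pd.DataFrame:
        return self.network.edges


def _canonicalize(df: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
    """Order endpoints, drop self-loops, deduplicate pairs keeping max weight."""
    u = df["gene1"].astype(str)
    v = df["gene2"].astype(str)
    g1 = u.where(u < v, v)
    g2 = v.where(u < v, u)
    out = pd.DataFrame({"gene1": g1, "gene2": g2, "weight": df["weight"].astype(float)})
    loops = int((out["gene1"] == out["gene2"]).sum())
    if loops:
        out = out[out["gene1"] != out["gene2"]]
    before = len(out)
    out = (
        out.groupby(["gene1", "gene2"], as_index=False, sort=True)["weight"].max()
    )
    dups = before - len(out)
    return out.reset_index(drop=True), loops, dups


def load_network(path: str | Path, label: str | None = None) -> GeneNetwork:
    """Read a 3-column (gene1, gene2, weight) edge list, gzip-transparent.

    Reversed duplicates collapse to one edge keeping the maximum weight;
    self-loops are dropped. Both events are counted in the log.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=_EDGE_COLS,
        dtype={"gene1": str, "gene2": str, "weight": str},
    )
    if df.empty:
        raise ValueError(f"network file {path} contains no edges")
    weights = pd.to_numeric(df["weight"], errors="coerce")
    bad = np.flatnonzero(weights.isna().to_numpy())
    if bad.size:
        raise ValueError(
            f"non-numeric weight at data line {bad[0] + 1} of {path}: "
            f"{df['weight'].iloc[bad[0]]!r}"
        )
    df["weight"] = weights
    edges, loops, dups = _canonicalize(df)
    if loops:
        logger.info("dropped %d self-loop edges from %s", loops, path)
    if dups:
        logger.info("collapsed %d duplicate edges (max weight kept) from %s", dups, path)
    return GeneNetwork(edges, label=label or str(path))


def write_network(
    net: GeneNetwork, path: str | Path, vertices_path: str | Path | None = None
) -> None:
    """Write the edge list as 3-column TSV, optionally plus a vertex list."""
    net.edges.to_csv(path, sep="\t", header=False, index=False)
    if vertices_path is not None:
        with open(vertices_path, "w") as fh:
            for v in sorted(net.vertices):
                fh.write(v + "\n")


def filter_by_weight_rank(net: GeneNetwork, drop_fraction: float) -> GeneNetwork:
    """Remove the floor(drop_fraction * m) lowest-weight edges.

    Ties are broken deterministically by the canonical (gene1, gene2)
    key, so the removed set is well defined even under heavy weight
    ties. Vertices are recomputed from the surviving edges.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError(f"drop_fraction must be in [0, 1), got {drop_fraction}")
    if net.n_edges == 0:
        raise ValueError("cannot rank-filter an empty network")
    n_drop = math.floor(drop_fraction * net.n_edges)
    if n_drop == 0:
        return GeneNetwork(net.edges.copy(), label=net.label)
    ranked = net.edges.sort_values(
        ["weight", "gene1", "gene2"], kind="mergesort"
    ).iloc[n_drop:]
    kept = ranked.sort_values(["gene1", "gene2"], kind="mergesort").reset_index(drop=True)
    logger.info(
        "weight-rank filter: dropped %d of %d edges; %d genes remain",
        n_drop,
        net.n_edges,
        len(set(kept["gene1"]) | set(kept["gene2"])),
    )
    return GeneNetwork(kept, label=net.label)


def restrict_to_genes(net: GeneNetwork, genes: Iterable[str]) -> GeneNetwork:
    """Induced subgraph on the intersection of network vertices and ``genes``.

    Intersection members that lose all their edges stay in the vertex
    set as isolated vertices.
    """
    genes = set(genes)
    keep = frozenset(net.vertices & genes)
    if not keep:
        raise ValueError(
            "no overlap between network vertices and the supplied gene set "
            f"({net.n_vertices} network genes, {len(genes)} supplied)"
        )
    mask = net.edges["gene1"].isin(keep) & net.edges["gene2"].isin(keep)
    edges = net.edges[mask].reset_index(drop=True)
    logger.info(
        "gene restriction: %d -> %d edges, %d -> %d genes",
        net.n_edges,
        len(edges),
        net.n_vertices,
        len(keep),
    )
    return GeneNetwork(edges, vertices=keep, label=net.label)


def extract_cell_type_network(
    net: GeneNetwork,
    scores: ScoreTable,
    cell_type: str,
    threshold: float,
) -> CellTypeNetwork:
    """Induce the subnetwork on genes scoring strictly above ``threshold``.

    Genes with NA score are excluded whatever the threshold. Qualifying
    genes that end up isolated are retained: they are legitimate draws
    for the permutation null and count toward mapped disease genes.
    """
    if cell_type not in scores.types:
        raise ValueError(f"unknown cell type {cell_type!r}; have {scores.types}")
    col = scores.types.index(cell_type)
    s = scores.score[:, col]
    passing = {
        g for g, v in zip(scores.genes, s) if not np.isnan(v) and v > threshold
    }
    keep = frozenset(net.vertices & passing)
    if not keep:
        logger.warning(
            "no genes pass score > %g in cell type %r within the network",
            threshold,
            cell_type,
        )
        empty = pd.DataFrame(columns=_EDGE_COLS).astype(
            {"gene1": str, "gene2": str, "weight": float}
        )
        return CellTypeNetwork(
            GeneNetwork(empty, vertices=frozenset(), label=net.label),
            cell_type,
            threshold,
        )
    mask = net.edges["gene1"].isin(keep) & net.edges["gene2"].isin(keep)
    sub = GeneNetwork(
        net.edges[mask].reset_index(drop=True), vertices=keep, label=net.label
    )
    logger.info(
        "cell type %r, score > %g: %d genes, %d interactions",
        cell_type,
        threshold,
        sub.n_vertices,
        sub.n_edges,
    )
    return CellTypeNetwork(sub, cell_type, threshold)


def jaccard_similarity(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Intersection-over-union of two gene sets; NaN if both are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        logger.warning("Jaccard similarity of two empty sets is undefined")
        return float("nan")
    return len(a & b) / len(union)
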