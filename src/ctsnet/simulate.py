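"""Synthetic expression and network fixtures with planted ground truth.

Every pipeline stage can be exercised without external downloads:

* ``simulate_expression`` draws negative-binomial background counts with
  a common per-gene mean across cell types and multiplies each planted
  marker gene's mean by a fold change in its home type only, so marker
  specificity converges to the fold change as sampling noise vanishes.
* ``simulate_network`` builds a uniform random background graph and
  plants a connected module (random spanning tree) among a designated
  subset of disease genes; the remaining disease genes are scattered.

These generators emulate the statistical structure the scoring and
module statistics assume — they do not model dropout, batch effects,
library-size gradients, or scale-free degree distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .expression import CellAnnotation, ExpressionMatrix
from .network import GeneNetwork, write_network

__all__ = ["FixtureTruth", "simulate_expression", "simulate_network", "write_fixture"]


@dataclass
class FixtureTruth:
    """Ground truth of a simulated fixture, JSON-serializable."""

    seed: int
    params: dict = field(default_factory=dict)
    planted_markers: dict[str, list[str]] = field(default_factory=dict)
    planted_module: list[str] = field(default_factory=list)
    disease_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def simulate_expression(
    n_genes: int = 2000,
    k: int = 5,
    cells_per_type: int = 50,
    marker_frac: float = 0.02,
    fold: float = 4.0,
    dispersion: float = 0.1,
    base_mean: float = 5.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, CellAnnotation, FixtureTruth]:
    """Simulate a count matrix with planted cell-type marker genes.

    Background counts follow a gamma-Poisson (negative binomial) with a
    lognormal per-gene base mean shared by all cell types; variance is
    mu * (1 + dispersion * mu), so ``dispersion = 0`` is the Poisson
    limit. The first ``k * round(marker_frac * n_genes)`` genes are
    markers, partitioned evenly over the k types; a marker's mean is
    multiplied by ``fold`` in its home type.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    n_markers = int(round(marker_frac * n_genes))
    if n_markers < 1:
        raise ValueError("marker_frac * n_genes must be >= 1 per cell type")
    if k * n_markers > n_genes:
        raise ValueError(
            f"{k} types x {n_markers} markers exceed {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    types = [f"type{j + 1}" for j in range(k)]
    base = base_mean * rng.lognormal(mean=0.0, sigma=0.5, size=n_genes)

    planted = {
        types[j]: genes[j * n_markers : (j + 1) * n_markers] for j in range(k)
    }
    counts = np.empty((n_genes, k * cells_per_type))
    cells: list[str] = []
    mapping: dict[str, str] = {}
    for j, t in enumerate(types):
        mu = base.copy()
        mu[j * n_markers : (j + 1) * n_markers] *= fold
        block = slice(j * cells_per_type, (j + 1) * cells_per_type)
        lam = np.tile(mu[:, None], (1, cells_per_type))
        if dispersion > 0:
            shape = 1.0 / dispersion
            lam = rng.gamma(shape, lam * dispersion)
        counts[:, block] = rng.poisson(lam)
        for i in range(cells_per_type):
            cid = f"cell{j * cells_per_type + i:05d}"
            cells.append(cid)
            mapping[cid] = t

    expr = ExpressionMatrix(genes, cells, counts, unit="counts")
    ann = CellAnnotation(mapping, types)
    truth = FixtureTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "k": k,
            "cells_per_type": cells_per_type,
            "marker_frac": marker_frac,
            "fold": fold,
            "dispersion": dispersion,
            "base_mean": base_mean,
        },
        planted_markers={t: list(gs) for t, gs in planted.items()},
    )
    return expr, ann, truth


def simulate_network(
    n_vertices: int = 500,
    n_edges: int = 1250,
    module_size: int = 10,
    n_disease_genes: int = 30,
    genes: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[GeneNetwork, list[str], FixtureTruth]:
    """Simulate a random network with a planted connected disease module.

    The background graph samples ``n_edges`` distinct vertex pairs
    uniformly; ``module_size`` disease genes are additionally connected
    by a random spanning tree (guaranteeing one disease component of at
    least that size), and the remaining disease genes are scattered
    uniformly. Edge weights are uniform on (0, 1].
    """
    if genes is not None:
        genes = list(genes)
        if len(genes) != n_vertices:
            n_vertices = len(genes)
    else:
        genes = [f"g{i:05d}" for i in range(n_vertices)]
    if not 0 <= module_size <= n_disease_genes <= n_vertices:
        raise ValueError(
            "need 0 <= module_size <= n_disease_genes <= n_vertices, got "
            f"{module_size}, {n_disease_genes}, {n_vertices}"
        )
    n_pairs = n_vertices * (n_vertices - 1) // 2
    if n_edges > n_pairs:
        raise ValueError(f"n_edges {n_edges} exceeds {n_pairs} possible pairs")
    if module_size >= 2 and n_edges < module_size - 1:
        raise ValueError("n_edges must be >= module_size - 1")

    rng = np.random.default_rng(seed)
    disease_idx = rng.choice(n_vertices, size=n_disease_genes, replace=False)
    disease = [genes[i] for i in disease_idx]
    module = disease[:module_size]

    # background: uniform sample of distinct unordered pairs, decoded from
    # linear indices over the upper triangle
    lin = rng.choice(n_pairs, size=n_edges, replace=False)
    i = (
        n_vertices
        - 2
        - np.floor(
            np.sqrt(4 * n_vertices * (n_vertices - 1) - 8 * lin - 7) / 2 - 0.5
        ).astype(np.int64)
    )
    j = lin + i + 1 - i * (2 * n_vertices - i - 1) // 2
    pairs = {(int(a), int(b)) if a < b else (int(b), int(a)) for a, b in zip(i, j)}

    # planted module: random recursive tree over the module genes
    mod_idx = disease_idx[:module_size]
    for pos in range(1, module_size):
        anchor = mod_idx[rng.integers(pos)]
        a, b = int(mod_idx[pos]), int(anchor)
        pairs.add((a, b) if a < b else (b, a))

    rows = []
    for a, b in sorted(pairs):
        u, v = genes[a], genes[b]
        if u > v:
            u, v = v, u
        rows.append((u, v, float(1.0 - rng.random())))
    edges = (
        pd.DataFrame(rows, columns=["gene1", "gene2", "weight"])
        .sort_values(["gene1", "gene2"], kind="mergesort")
        .reset_index(drop=True)
    )
    net = GeneNetwork(edges, vertices=frozenset(genes), label=f"simulated(seed={seed})")
    truth = FixtureTruth(
        seed=seed,
        params={
            "n_vertices": n_vertices,
            "n_edges": n_edges,
            "module_size": module_size,
            "n_disease_genes": n_disease_genes,
        },
        planted_module=list(module),
        disease_genes=list(disease),
    )
    return net, disease, truth


def write_fixture(
    out_dir: str | Path,
    expr: ExpressionMatrix,
    ann: CellAnnotation,
    net: GeneNetwork,
    disease_genes: Sequence[str],
    truth: FixtureTruth | None = None,
) -> dict[str, Path]:
    """Write a fixture in the exact on-disk formats the pipeline consumes.

    Emits MTX + gene/cell sidecars, annotation TSV, edge-list TSV,
    disease-gene list, and (if given) a truth JSON. Returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.txt",
        "cells": out / "cells.txt",
        "annotation": out / "annotation.tsv",
        "network": out / "network.tsv",
        "disease_genes": out / "disease_genes.txt",
    }
    values = expr.values
    integral = expr.unit == "counts" and np.all(values == np.round(values))
    sparse = scipy.sparse.coo_matrix(values.astype(np.int64) if integral else values)
    scipy.io.mmwrite(str(paths["matrix"]), sparse, field="integer" if integral else "real")
    paths["genes"].write_text("\n".join(expr.genes) + "\n")
    paths["cells"].write_text("\n".join(expr.cells) + "\n")
    pd.DataFrame(
        {"cell_id": list(ann.cell_to_type), "cell_type": list(ann.cell_to_type.values())}
    ).to_csv(paths["annotation"], sep="\t", index=False)
    write_network(net, paths["network"])
    paths["disease_genes"].write_text("\n".join(disease_genes) + "\n")
    if truth is not None:
        paths["truth"] = out / "truth.json"
        truth.to_json(paths["truth"])
    return paths
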