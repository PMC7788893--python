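"""Disease gene modules and their permutation significance test.

Disease-associated genes are mapped onto each cell type-specific
network; the connected components they form are candidate disease gene
modules. Significance assumes, as the null, that disease genes do not
preferentially interact: T genes (T = mapped disease genes) are drawn
uniformly without replacement from the network's vertices, the largest
connected-component size S_rand among them is recorded, and the
permutation p-value of an observed module of size S_obs is the fraction
of replicates with S_rand strictly greater than S_obs. Benjamini-
Hochberg correction across candidates yields q-values; q < 0.1 is
called significant by default.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .network import CellTypeNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateModule",
    "PermutationNull",
    "ModuleReport",
    "load_disease_genes",
    "candidate_modules",
    "permutation_null",
    "permutation_pvalue",
    "bh_adjust",
    "identify_modules",
]


@dataclass
class CandidateModule:
    """A connected component of disease genes in a cell type-specific network."""

    cell_type: str
    genes: tuple[str, ...]
    edges: pd.DataFrame
    size: int

    def __post_init__(self) -> None:
        self.genes = tuple(sorted(self.genes))
        if self.size != len(self.genes):
            raise ValueError("module size must equal its gene count")


@dataclass
class PermutationNull:
    """Null distribution of the largest component size among t random genes."""

    t: int
    s_rand: np.ndarray
    seed: object
    n_perm: int

    def __post_init__(self) -> None:
        self.s_rand = np.asarray(self.s_rand, dtype=int)
        if self.s_rand.shape != (self.n_perm,):
            raise ValueError("s_rand length must equal n_perm")


@dataclass
class ModuleReport:
    """Tabulated candidates with permutation p, BH q, and significance calls."""

    table: pd.DataFrame
    params: dict = field(default_factory=dict)
    modules: list[CandidateModule] = field(default_factory=list)

    COLUMNS = [
        "cell_type",
        "module_id",
        "size",
        "T",
        "p_perm",
        "q_fdr",
        "significant",
        "genes",
    ]

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out_dir / "module_report.tsv", sep="\t", index=False)
        with open(out_dir / "module_report_params.json", "w") as fh:
            json.dump(self.params, fh, indent=2, sort_keys=True)
        for mod, mid in zip(self.modules, self.table["module_id"]):
            mod.edges.to_csv(
                out_dir / f"module_{mid}_edges.tsv", sep="\t", header=False, index=False
            )


def load_disease_genes(path: str | Path) -> list[str]:
    """Read one gene symbol per line; '#' comments and blanks are skipped.

    Duplicates are removed preserving first occurrence.
    """
    genes: list[str] = []
    seen: set[str] = set()
    dups = 0
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if not sym or sym.startswith("#"):
                continue
            if sym in seen:
                dups += 1
                continue
            seen.add(sym)
            genes.append(sym)
    if not genes:
        raise ValueError(f"disease gene list {path} contains no genes")
    if dups:
        logger.info("removed %d duplicate symbols from %s", dups, path)
    return genes


def mapped_disease_genes(ctn: CellTypeNetwork, disease_genes: Sequence[str]) -> list[str]:
    """Disease genes present in the cell type-specific network (defines T)."""
    vs = ctn.vertices
    return [g for g in dict.fromkeys(disease_genes) if g in vs]


def candidate_modules(
    ctn: CellTypeNetwork,
    disease_genes: Sequence[str],
    min_module_size: int = 2,
) -> list[CandidateModule]:
    """Connected components of disease genes, largest first.

    A single disease gene with no disease-gene neighbor is not a module
    under the default ``min_module_size`` of 2; pass 1 to count
    singletons. Ties in size are broken by the sorted gene tuple so the
    ordering is deterministic.
    """
    mapped = mapped_disease_genes(ctn, disease_genes)
    if not mapped:
        logger.warning(
            "no disease genes present in the %r network", ctn.cell_type
        )
        return []
    mapped_set = set(mapped)
    e = ctn.edges
    mask = e["gene1"].isin(mapped_set) & e["gene2"].isin(mapped_set)
    sub = nx.Graph()
    sub.add_nodes_from(mapped)
    sub.add_edges_from(e.loc[mask, ["gene1", "gene2"]].itertuples(index=False, name=None))
    modules = []
    for comp in nx.connected_components(sub):
        if len(comp) < min_module_size:
            continue
        comp_edges = e[mask & e["gene1"].isin(comp)].reset_index(drop=True)
        modules.append(
            CandidateModule(ctn.cell_type, tuple(sorted(comp)), comp_edges, len(comp))
        )
    modules.sort(key=lambda m: (-m.size, m.genes))
    return modules


def permutation_null(
    ctn: CellTypeNetwork,
    t: int,
    n_perm: int = 1000,
    seed: object = 1,
) -> PermutationNull:
    """Draw t random vertices n_perm times; record largest component sizes.

    Each replicate samples uniformly without replacement from the
    network's vertex set (isolated vertices included) and measures the
    largest connected component of the induced subgraph with union-find.
    Fully reproducible given the seed.
    """
    verts = sorted(ctn.vertices)
    n = len(verts)
    if not 1 <= t <= n:
        raise ValueError(f"t must be in [1, {n}], got {t}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    index = {v: i for i, v in enumerate(verts)}
    e = ctn.edges
    eu = np.fromiter((index[g] for g in e["gene1"]), dtype=np.int64, count=len(e))
    ev = np.fromiter((index[g] for g in e["gene2"]), dtype=np.int64, count=len(e))

    rng = np.random.default_rng(seed)
    s_rand = np.empty(n_perm, dtype=int)
    mask = np.zeros(n, dtype=bool)
    for rep in range(n_perm):
        sel = rng.choice(n, size=t, replace=False)
        mask[sel] = True
        keep = np.flatnonzero(mask[eu] & mask[ev])
        s_rand[rep] = _largest_component(sel, eu[keep], ev[keep])
        mask[sel] = False
    return PermutationNull(t=t, s_rand=s_rand, seed=seed, n_perm=n_perm)


def _largest_component(sel: np.ndarray, eu: np.ndarray, ev: np.ndarray) -> int:
    """Largest component size among selected vertices via union-find."""
    parent = {int(v): int(v) for v in sel}
    size = {int(v): 1 for v in sel}

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    best = 1
    for a, b in zip(eu.tolist(), ev.tolist()):
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        if size[ra] < size[rb]:
            ra, rb = rb, ra
        parent[rb] = ra
        size[ra] += size[rb]
        if size[ra] > best:
            best = size[ra]
    return best


def permutation_pvalue(
    s_obs: int, null: PermutationNull, pseudocount: bool = False
) -> float:
    """Fraction of null replicates whose S_rand strictly exceeds S_obs.

    With ``pseudocount`` the (n + 1) / (N + 1) estimator is used
    instead, which never returns exactly zero.
    """
    n = int(np.count_nonzero(null.s_rand > s_obs))
    if pseudocount:
        return (n + 1) / (null.n_perm + 1)
    return n / null.n_perm


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _type_seed(seed: int, cell_type: str) -> np.random.SeedSequence:
    """Permutation stream keyed by (seed, cell type name) only.

    Independent of how many cell types share the run, so a single-type
    invocation reproduces the matching slice of a multi-type run.
    """
    digest = zlib.crc32(cell_type.encode())
    return np.random.SeedSequence([int(seed), digest])


def identify_modules(
    ctn_per_type: Mapping[str, CellTypeNetwork],
    disease_genes: Sequence[str],
    n_perm: int = 1000,
    seed: int = 1,
    fdr_cutoff: float = 0.1,
    min_module_size: int = 2,
    fdr_scope: str = "global",
    pseudocount: bool = False,
) -> ModuleReport:
    """Run the full module search and permutation test over all cell types.

    One shared null is computed per (cell type, T) and reused for every
    candidate in that network, since T is the same for all of them.
    ``fdr_scope`` selects whether BH pools candidates across cell types
    ("global", the default) or corrects within each cell type
    ("per-cell-type"). Per-cell-type permutation streams are derived
    deterministically from ``seed`` by cell-type name, so results do not
    depend on mapping order.
    """
    if fdr_scope not in ("global", "per-cell-type"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    rows: list[dict] = []
    modules: list[CandidateModule] = []
    for cell_type, ctn in ctn_per_type.items():
        mapped = mapped_disease_genes(ctn, disease_genes)
        t_count = len(mapped)
        cands = candidate_modules(ctn, disease_genes, min_module_size=min_module_size)
        if not cands:
            continue
        null = permutation_null(
            ctn, t_count, n_perm=n_perm, seed=_type_seed(seed, cell_type)
        )
        for i, mod in enumerate(cands):
            rows.append(
                {
                    "cell_type": cell_type,
                    "module_id": f"{cell_type}.{i + 1}",
                    "size": mod.size,
                    "T": t_count,
                    "p_perm": permutation_pvalue(mod.size, null, pseudocount=pseudocount),
                }
            )
            modules.append(mod)

    params = {
        "n_perm": n_perm,
        "seed": seed,
        "fdr_cutoff": fdr_cutoff,
        "min_module_size": min_module_size,
        "fdr_scope": fdr_scope,
        "pseudocount": pseudocount,
        "n_disease_genes": len(list(dict.fromkeys(disease_genes))),
    }
    if not rows:
        logger.warning("no candidate modules in any cell type")
        table = pd.DataFrame(columns=ModuleReport.COLUMNS)
        return ModuleReport(table, params, [])

    table = pd.DataFrame(rows)
    if fdr_scope == "global":
        table["q_fdr"] = bh_adjust(table["p_perm"].to_numpy())
    else:
        table["q_fdr"] = np.nan
        for ct, idx in table.groupby("cell_type").groups.items():
            table.loc[idx, "q_fdr"] = bh_adjust(table.loc[idx, "p_perm"].to_numpy())
    table["significant"] = table["q_fdr"] < fdr_cutoff
    table["genes"] = [";".join(m.genes) for m in modules]
    table = table[ModuleReport.COLUMNS]
    return ModuleReport(table, params, modules)
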