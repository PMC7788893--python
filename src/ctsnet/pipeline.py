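"""End-to-end pipeline: expression -> scores -> subnetworks -> modules.

Stage order: load expression and annotation, CPM-normalize, average per
cell type, compute specificity and scores, rank-filter the reference
network by weight, restrict it to the measured genes, induce one
score-thresholded network per cell type, then detect and test disease
gene modules. Every stage logs its attrition counts and the resolved
run configuration is serialized next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import expression as expr_mod
from . import modules as mod_mod
from . import network as net_mod
from . import scoring as score_mod

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A fatal pipeline failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    expression: str
    annotation: str
    network: str
    disease_genes: str
    out_dir: str
    genes_sidecar: str | None = None
    cells_sidecar: str | None = None
    score_table: str | None = None  # externally computed scores, skips scoring
    drop_weight_fraction: float = 0.2
    score_threshold: float = 0.0
    n_perm: int = 1000
    seed: int = 1
    fdr_cutoff: float = 0.1
    min_module_size: int = 2
    fdr_scope: str = "global"
    pseudocount: bool = False

    def validate(self) -> None:
        if not 0 <= self.drop_weight_fraction < 1:
            raise ValueError("drop_weight_fraction must be in [0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.fdr_cutoff <= 1:
            raise ValueError("fdr_cutoff must be in (0, 1]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> mod_mod.ModuleReport:
    """Execute all stages and write artifacts into ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)

    expr = _stage("expression")(expr_mod.load_expression)(
        config.expression, config.genes_sidecar, config.cells_sidecar
    )
    ann = _stage("annotation")(expr_mod.load_annotation)(config.annotation, expr)

    if config.score_table is not None:
        scores = _stage("scoring")(score_mod.read_score_table)(config.score_table)
    else:
        cpm = _stage("normalization")(expr_mod.cpm_normalize)(expr)
        means = _stage("aggregation")(expr_mod.mean_by_cell_type)(cpm, ann)
        spec = _stage("scoring")(score_mod.compute_specificity)(means)
        scores = _stage("scoring")(score_mod.compute_score)(spec)
        _stage("scoring")(score_mod.write_score_table)(scores, out / "scores.tsv")

    net = _stage("network")(net_mod.load_network)(config.network)
    net = _stage("network")(net_mod.filter_by_weight_rank)(
        net, config.drop_weight_fraction
    )
    net = _stage("network")(net_mod.restrict_to_genes)(net, scores.genes)

    ctn_per_type = {}
    net_dir = out / "cell_type_networks"
    net_dir.mkdir(exist_ok=True)
    for cell_type in scores.types:
        ctn = _stage("network")(net_mod.extract_cell_type_network)(
            net, scores, cell_type, config.score_threshold
        )
        ctn_per_type[cell_type] = ctn
        net_mod.write_network(
            ctn.network,
            net_dir / f"{cell_type}_edges.tsv",
            net_dir / f"{cell_type}_genes.txt",
        )

    disease = _stage("disease-genes")(mod_mod.load_disease_genes)(config.disease_genes)
    report = _stage("modules")(mod_mod.identify_modules)(
        ctn_per_type,
        disease,
        n_perm=config.n_perm,
        seed=config.seed,
        fdr_cutoff=config.fdr_cutoff,
        min_module_size=config.min_module_size,
        fdr_scope=config.fdr_scope,
        pseudocount=config.pseudocount,
    )
    report.params["score_threshold"] = config.score_threshold
    report.params["drop_weight_fraction"] = config.drop_weight_fraction
    report.write(out)
    n_sig = int(report.table["significant"].sum()) if len(report.table) else 0
    logger.info(
        "pipeline finished: %d candidate modules, %d significant at q < %g",
        len(report.table),
        n_sig,
        config.fdr_cutoff,
    )
    return report
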