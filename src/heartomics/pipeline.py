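"""End-to-end orchestration of the five prioritization stages.

Stage order: expression integration -> enrichment -> interactome ->
phenotype distance -> drug annotation.  Each stage writes its TSVs into the
output directory, parameters are echoed into the summary for provenance,
warnings are collected into a machine-readable sidecar, and any stage's hard
error aborts with a stage-tagged exception (partial outputs retained).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import drugs as drug_mod
from . import enrichment as enr
from . import expression as expr
from . import interactome as inter
from . import io as hio
from . import phenotype as phen

logger = logging.getLogger("heartomics.pipeline")

#: stage names in execution order; CLI exit codes are 10 + stage index
STAGES = ("expression", "enrichment", "interactome", "phenotype_distance", "drug_annotation")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for exit-code mapping."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths and all stage thresholds of one pipeline run."""

    expression_paths: dict[str, str] = field(default_factory=dict)  # dataset_id -> path
    gmt_paths: list[str] = field(default_factory=list)
    ppi_path: str | None = None
    causal_path: str | None = None
    drug_path: str | None = None  # None -> packaged fixture
    reference_proteome_path: str | None = None
    outdir: str = "heartomics_out"
    # thresholds
    z_hi: float = expr.Z_HI
    z_lo: float = expr.Z_LO
    p_max: float = expr.P_MAX
    pct_min: float = 50.0
    q_max: float = enr.Q_MAX
    confidence_cutoff: float = inter.CONFIDENCE_CUTOFF
    confidence_scale: str = "auto"
    min_phenotypes: int = phen.MIN_PHENOTYPES
    dmax: float = math.inf
    alpha: float = phen.ALPHA
    comparison_method: str = "welch"
    min_phase: int = drug_mod.MIN_PHASE
    require_consistent_direction: bool = True

    def params(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("expression_paths", "gmt_paths", "ppi_path", "causal_path",
                  "drug_path", "reference_proteome_path", "outdir"):
            d.pop(k)
        d["dmax"] = "inf" if math.isinf(self.dmax) else self.dmax
        return d


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.rows: list[dict] = []

    def emit(self, record):
        self.rows.append(
            {"stage": record.name.rsplit(".", 1)[-1], "level": record.levelname,
             "message": record.getMessage()}
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the consolidated report bundle.

    Returns the report dict (DataFrames plus summary blocks) also written to
    ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logging.getLogger("heartomics").addHandler(collector)
    report: dict = {}
    try:
        summary: dict = {"parameters": config.params()}

        # -- stage 1: expression integration -------------------------------
        stage = "expression"
        try:
            profiles = [
                hio.read_expression_profiles(path, ds)
                for ds, path in sorted(config.expression_paths.items())
            ]
            if len(profiles) < 2:
                raise ValueError("need >=2 expression datasets to integrate")
            ztables = [
                expr.classify_genes(
                    expr.compute_zscores(p), config.z_hi, config.z_lo, config.p_max
                )
                for p in profiles
            ]
            per_dataset = [expr.significant_genes(zt) for zt in ztables]
            integrated = expr.intersect_datasets(
                per_dataset, require_consistent_direction=config.require_consistent_direction
            )
            report["zscores"] = expr.zscore_long_table(ztables)
            report["integrated_genes"] = expr.integrated_table(integrated, ztables)
            report["cell_type_summary"] = expr.summarize_cell_types(
                ztables, integrated, pct_min=config.pct_min
            )
            ct_map = expr.primary_cell_type_map(integrated, ztables)
            summary["signature_1_expression"] = {
                "n_datasets": len(profiles),
                "per_dataset_significant": {s.dataset_id: len(s.genes) for s in per_dataset},
                "n_integrated_genes": len(integrated.genes),
            }
        except Exception as e:
            raise StageError(stage, str(e)) from e

        # -- stage 2: enrichment -------------------------------------------
        stage = "enrichment"
        try:
            dbs = [hio.read_gmt(p) for p in config.gmt_paths]
            if dbs and integrated.genes:
                enrichment = enr.enrich(integrated.genes, dbs, q_max=config.q_max)
            else:
                if not dbs:
                    logger.warning("no annotation sources configured; enrichment skipped")
                else:
                    logger.warning("integrated gene set empty; enrichment skipped")
                enrichment = pd.DataFrame(
                    columns=["source", "term", "description", "k", "K", "n", "N",
                             "p", "q", "significant", "overlap_genes"]
                )
            report["enrichment"] = enrichment
            summary["signature_2_enrichment"] = {
                "n_sources": len(dbs),
                "n_terms_tested": int(len(enrichment)),
                "n_significant_terms": int(enrichment["significant"].sum()) if len(enrichment) else 0,
            }
        except Exception as e:
            raise StageError(stage, str(e)) from e

        # -- stage 3: interactome ------------------------------------------
        stage = "interactome"
        try:
            if config.ppi_path is None:
                raise ValueError("no protein-interaction edge file configured")
            edges = hio.read_confidence_edges(config.ppi_path, scale=config.confidence_scale)
            meta = {
                g: {"cell_type": ct, "direction": integrated.directions.get(g, "")}
                for g, ct in ct_map.items()
            }
            net = inter.build_network(
                edges, set(integrated.genes), cutoff=config.confidence_cutoff, node_metadata=meta
            )
            centr = inter.centrality_table(net)
            proteome = set()
            if config.reference_proteome_path:
                proteome = set(
                    pd.read_csv(config.reference_proteome_path, sep="\t", comment="#")
                    .iloc[:, 0].astype(str)
                )
            net_summary = inter.network_summary(net, centr, proteome)
            report["network_edges"] = inter.edge_table(net)
            report["centrality"] = centr
            summary["signature_3_interactome"] = net_summary
        except Exception as e:
            raise StageError(stage, str(e)) from e

        # -- stage 4: phenotype distance -----------------------------------
        stage = "phenotype_distance"
        try:
            if config.causal_path is None:
                raise ValueError("no causal edge file configured")
            causal = hio.read_causal_edges(config.causal_path)
            cnet = phen.CausalNetwork.from_edges(causal)
            proteins = sorted(net.nodes) if net.number_of_nodes() else sorted(integrated.genes)
            matrix = phen.distance_matrix(cnet, proteins)
            prioritized = phen.prioritize_targets(
                matrix, min_phenotypes=config.min_phenotypes, dmax=config.dmax
            )
            comparisons = phen.compare_phenotypes(
                matrix, alpha=config.alpha, method=config.comparison_method
            )
            ct_ranking = phen.cell_type_distance(matrix, ct_map)
            report["distance_matrix"] = matrix.reset_index()
            report["prioritized_targets"] = prioritized
            report["phenotype_comparisons"] = comparisons
            report["cell_type_distance"] = ct_ranking
            means = phen.phenotype_means(matrix)
            summary["signature_4_phenotype_distance"] = {
                "n_proteins_scored": int(len(matrix)),
                "phenotype_mean_dpath": {k: round(float(v), 4) for k, v in means.items()},
                "n_prioritized": int(len(prioritized)),
                "n_significant_pairs": int(comparisons["significant"].sum()) if len(comparisons) else 0,
            }
        except Exception as e:
            raise StageError(stage, str(e)) from e

        # -- stage 5: drug annotation --------------------------------------
        stage = "drug_annotation"
        try:
            table = (
                hio.read_drug_table(config.drug_path)
                if config.drug_path
                else drug_mod.packaged_drug_table()
            )
            mapping = drug_mod.annotate_targets(
                prioritized["protein"], table, min_phase=config.min_phase
            )
            report["drug_annotations"] = drug_mod.annotation_table(mapping)
            report["sankey"] = drug_mod.sankey_table(mapping)
            summary["signature_5_drugs"] = mapping.summary
        except Exception as e:
            raise StageError(stage, str(e)) from e

        report["summary"] = summary
        report["warnings"] = pd.DataFrame(
            collector.rows, columns=["stage", "level", "message"]
        )
        hio.write_report(report, outdir)
        return report
    finally:
        # retain partial outputs on failure
        if "summary" not in report:
            partial = {k: v for k, v in report.items() if isinstance(v, pd.DataFrame)}
            if partial:
                hio.write_report(partial, outdir)
        logging.getLogger("heartomics").removeHandler(collector)
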