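"""End-to-end orchestration of the discovery pipeline.

Stages: differential screen (tumor vs every normal stage + intersection) →
survival evaluation of the nominated lncRNA → co-expression network on the
tumor samples → MCL/hub function prediction.  Each stage is independently
runnable; ``run_all`` chains them and emits a machine-readable JSON summary
whose config echo is sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import DomainError
from .function import annotate_lncrnas, hub_subnetworks, mcl_cluster
from .io import (
    GeneCatalog,
    read_expression_matrix,
    read_gene_catalog,
    read_sample_sheet,
    write_network,
)
from .network import build_network, network_summary
from .screen import screen_candidates, write_screen_results
from .survival import survival_report, write_km_curve
from .simulate import SyntheticConfig, generate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Paths, thresholds and method switches for a full run."""

    matrix: str
    sheet: str
    biotypes: str
    gmt: str | None = None
    outdir: str = "results"
    fc_threshold: float = 2.0
    de_p_threshold: float = 0.05
    de_use_adjusted_p: bool = True
    t_flavor: str = "student"
    edge_alpha: float = 0.01
    edge_correction: str = "bonferroni"
    correlation_method: str = "pearson"
    enrichment_threshold: float = 0.01
    ties_method: str = "efron"
    endpoint: str = "OS"
    tumor_group: str = "DLBCL"
    network_samples: str = "tumor"  # "tumor" | "all"
    network_genes: str = "all"  # "all" | "candidates"
    mcl_inflation: float = 2.0
    mcl_expansion: int = 2
    mcl_prune: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_p_threshold", "edge_alpha", "enrichment_threshold"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise DomainError(f"{name} must lie in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_inputs(config: PipelineConfig):
    mat = read_expression_matrix(config.matrix)
    sheet = read_sample_sheet(config.sheet)
    catalog = read_gene_catalog(config.biotypes, config.gmt)
    return mat, sheet, catalog


def run_simulate(config: SyntheticConfig, outdir) -> dict:
    dataset = generate_dataset(config)
    paths = write_dataset(dataset, outdir)
    return {"paths": paths, "truth": {"biomarker": dataset.truth.biomarker}}


def run_screen(config: PipelineConfig, mat=None, sheet=None, catalog=None) -> dict:
    if mat is None:
        mat, sheet, catalog = _load_inputs(config)
    result = screen_candidates(
        mat,
        sheet,
        fc_threshold=config.fc_threshold,
        p_threshold=config.de_p_threshold,
        tumor_group=config.tumor_group,
        use_adjusted_p=config.de_use_adjusted_p,
        flavor=config.t_flavor,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_screen_results(result, outdir / "contrasts.tsv", outdir / "candidates.txt")
    lnc = result.candidate_lncrnas(catalog)
    coding = [g for g in result.intersection if g not in set(lnc)]
    return {
        "result": result,
        "summary": {
            "n_candidates": len(result.intersection),
            "candidate_lncrnas": lnc,
            "n_candidate_coding": len(coding),
            "stages": result.stages,
        },
    }


def run_survival(config: PipelineConfig, gene: str, mat=None, sheet=None, stratify_ipi=False) -> dict:
    if mat is None:
        mat, sheet, _ = _load_inputs(config)
    if gene not in mat.index:
        raise DomainError(f"gene {gene!r} absent from expression matrix")
    tumor = sheet[sheet["group"] == config.tumor_group]
    marker = mat.loc[gene, tumor.index]
    report = survival_report(
        tumor,
        marker,
        covariates=["gender", "subtype", "ipi_group"],
        endpoint=config.endpoint,
        ties=config.ties_method,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, curve in report["km"].items():
        write_km_curve(curve, outdir / f"km_{gene}_{label}.tsv")
    summary = {
        "gene": gene,
        "endpoint": report["endpoint"],
        "n": report["n"],
        "threshold": report["threshold"],
        "n_low": report["n_low"],
        "n_high": report["n_high"],
        "five_year": report["five_year"],
        "log_rank_p": report["log_rank"]["p"],
        "hazard_ratio_low_vs_high": float(report["univariate"]["low_vs_high"].hazard_ratio[0]),
        "hr_ci": [
            float(report["univariate"]["low_vs_high"].ci_low[0]),
            float(report["univariate"]["low_vs_high"].ci_high[0]),
        ],
        "cox_p": float(report["univariate"]["low_vs_high"].p[0]),
    }
    if stratify_ipi:
        from .survival import ipi_stratified_analysis

        strata = ipi_stratified_analysis(marker, tumor, endpoint=config.endpoint)
        summary["ipi_strata"] = {
            name: {
                "n_low": res["n_low"],
                "n_high": res["n_high"],
                "log_rank_p": res["log_rank"]["p"],
                "hazard_ratio": float(res["cox"].hazard_ratio[0]),
            }
            for name, res in strata.items()
        }
    return {"report": report, "summary": summary}


def run_network(config: PipelineConfig, mat=None, sheet=None, catalog=None, genes=None) -> dict:
    if mat is None:
        mat, sheet, catalog = _load_inputs(config)
    if config.network_samples == "tumor":
        samples = sheet.loc[sheet["group"] == config.tumor_group, "sample_id"].tolist()
        mat = mat[samples]
    graph = build_network(
        mat,
        catalog,
        method=config.correlation_method,
        alpha=config.edge_alpha,
        correction=config.edge_correction,
        genes=genes,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_network(graph, outdir / "network_edges.tsv", format="edge_list")
    summary = network_summary(graph)
    with open(outdir / "network_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return {"network": graph, "summary": summary}


def run_annotate(config: PipelineConfig, network, catalog) -> dict:
    partition = mcl_cluster(
        network,
        inflation=config.mcl_inflation,
        expansion=config.mcl_expansion,
        prune_threshold=config.mcl_prune,
    )
    hubs = hub_subnetworks(network)
    annotations = (
        annotate_lncrnas(
            partition, hubs, catalog, network, threshold=config.enrichment_threshold
        )
        if catalog.terms
        else {}
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partition.to_frame(network).to_csv(outdir / "modules.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(h.center, nb) for h in hubs for nb in sorted(h.neighbors)],
        columns=["center", "neighbor"],
    ).to_csv(outdir / "hubs.tsv", sep="\t", index=False)
    with open(outdir / "annotations.json", "w", encoding="utf-8") as fh:
        json.dump(annotations, fh, indent=2, sort_keys=True)
    return {
        "partition": partition,
        "hubs": hubs,
        "annotations": annotations,
        "summary": {
            "n_modules": len(partition.modules),
            "n_hubs": len(hubs),
            "n_annotated_lncrnas": sum(
                1 for a in annotations.values() if a["module_terms"] or a["hub_terms"]
            ),
        },
    }


def run_all(config: PipelineConfig) -> dict:
    """Chain screen → survival (top lncRNA candidate) → network → annotation."""
    mat, sheet, catalog = _load_inputs(config)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    screen_out = run_screen(config, mat, sheet, catalog)
    summary["screen"] = screen_out["summary"]

    lnc_candidates = screen_out["summary"]["candidate_lncrnas"]
    if lnc_candidates:
        cands = screen_out["result"].candidates
        ranked = sorted(lnc_candidates, key=lambda g: (cands.loc[g, "anova_p"], g))
        target = ranked[0]
        surv_out = run_survival(config, target, mat, sheet, stratify_ipi=True)
        summary["survival"] = surv_out["summary"]
    else:
        logger.warning("no lncRNA candidate nominated; survival stage skipped")
        summary["survival"] = None

    genes = None
    if config.network_genes == "candidates":
        genes = screen_out["result"].intersection
        if len(genes) < 2:
            raise DomainError("fewer than 2 candidate genes for network construction")
    net_out = run_network(config, mat, sheet, catalog, genes=genes)
    summary["network"] = net_out["summary"]

    ann_out = run_annotate(config, net_out["network"], catalog)
    summary["function"] = ann_out["summary"]
    if lnc_candidates and ann_out["annotations"].get(target):
        summary["function"]["candidate_annotation"] = ann_out["annotations"][target]

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
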