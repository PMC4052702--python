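"""End-to-end orchestration: load -> autoscale -> PLS -> VIP -> permutation
FDR -> selection -> enrichment -> network, with a deterministic run report.

Every stage writes its intermediate table to the output directory so each
step can be re-run and inspected in isolation. The JSON/text report
records the sample design, selection counts (total / up / down), the
top enriched terms, the hub genes, and every threshold and modelling
choice in effect — including the choices the method leaves open (scaling
convention, FDR estimator variant, direction rule), so a reader can
compare a run against any narrative description of the workflow.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import enrichment as enr
from . import network as net
from . import pls, significance
from .io import (
    align,
    read_annotation,
    read_edges,
    read_expression_matrix,
    read_gene_map,
    read_labels,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    Defaults: 3 latent variables, 10000 permutations, FDR < 0.05
    (strict), hub degree > 10 (strict), top 10 terms.
    """

    expression: str = ""
    labels: str = ""
    annotation: str = ""
    edges: str = ""
    gene_map: str = ""           # optional probe -> gene TSV
    outdir: str = "plsdex_run"
    case_label: str = "patient"
    n_components: int = 3
    n_permutations: int = 10_000
    fdr_threshold: float = 0.05
    hub_threshold: int = 10      # exclusive
    top_k_terms: int = 10
    scale: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError(
                f"fdr_threshold must be in (0, 1], got {self.fdr_threshold}"
            )
        if self.hub_threshold < 0:
            raise ValueError("hub_threshold must be >= 0")
        if self.top_k_terms < 1:
            raise ValueError("top_k_terms must be >= 1")


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML config, filling defaults and rejecting unknown keys."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {unknown}")
    return RunConfig(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all artifacts to ``config.outdir``.

    Returns the run report as a dict. Any stage failure aborts with a
    stage-named error and removes this run's partial outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str) -> Path:
        path = outdir / name
        written.append(path)
        return path

    stage = "load"
    try:
        matrix = read_expression_matrix(config.expression)
        labels = read_labels(config.labels, case_label=config.case_label)
        matrix, labels = align(matrix, labels)
        gene_map = read_gene_map(config.gene_map) if config.gene_map else None
        annotation = read_annotation(config.annotation) if config.annotation else None
        edge_list = read_edges(config.edges) if config.edges else None

        stage = "pls"
        X, y, prep = pls.autoscale(matrix, labels, scale=config.scale)
        model = pls.nipals_pls(
            X, y, config.n_components, preprocessing=prep,
            sample_ids=matrix.sample_ids,
        )
        observed = pls.vip(model)
        scores = pls.sample_scores(model, labels)
        scores.to_csv(emit("scores.tsv"), sep="\t", index=False, lineterminator="\n")

        stage = "permutation"
        null = significance.permutation_null(
            X, y, config.n_components,
            n_permutations=config.n_permutations,
            seed=config.seed,
            probe_ids=model.probe_ids,
        )
        fdr = significance.empirical_fdr(observed, null)

        stage = "selection"
        direction = significance.direction(matrix, labels)
        table = significance.select_de(
            observed, fdr, direction,
            threshold=config.fdr_threshold, gene_map=gene_map,
        )
        table.to_csv(emit("significance.tsv"), sep="\t", index=False,
                     lineterminator="\n")
        sel = table[table.selected]
        id_col = "gene_id" if "gene_id" in table.columns else "probe_id"
        selected_genes = set(sel[id_col].dropna())

        stage = "enrichment"
        top = None
        if annotation is not None:
            background = set(table[id_col].dropna())
            results = enr.enrich(selected_genes, background, annotation)
            results.to_csv(emit("enrichment.tsv"), sep="\t", index=False,
                           lineterminator="\n")
            top = enr.top_terms(results, config.top_k_terms)

        stage = "network"
        hub_list: list[str] = []
        if edge_list is not None:
            network = net.build_network(table, edge_list)
            net.export_network(
                network, emit("network.sif"), emit("network_nodes.tsv"),
                hub_threshold=config.hub_threshold,
            )
            hub_list = sorted(net.hubs(network, config.hub_threshold))

        stage = "report"
        n_up = int((sel.direction == "up").sum())
        n_down = int((sel.direction == "down").sum())
        report = {
            "n_probes": matrix.shape[0],
            "n_probes_modeled": len(model.probe_ids),
            "n_samples": {
                "patient": int(labels.status.sum()),
                "control": int((1 - labels.status).sum()),
            },
            "n_components": model.n_components,
            "n_permutations": config.n_permutations,
            "fdr_threshold": config.fdr_threshold,
            "n_selected": int(sel.shape[0]),
            "n_up": n_up,
            "n_down": n_down,
            "top_terms": (
                top[["term_id", "term_name", "term_class", "k", "K", "p_value"]]
                .to_dict(orient="records")
                if top is not None else []
            ),
            "hub_threshold": config.hub_threshold,
            "hubs": hub_list,
            "seed": config.seed,
            "choices": {
                "scaling": "autoscale (center + unit variance)" if config.scale
                           else "center only",
                "y_coding": "0/1 centered",
                "fdr_estimator": "pooled permutation tail ratio, closed (>=) "
                                 "tail counts, running-minimum monotonization",
                "selection": "fdr < threshold (strict)",
                "direction_rule": "patient vs control raw log2 group means; "
                                  "ties -> down",
                "hub_rule": "degree strictly greater than threshold",
            },
        }
        with open(emit("report.json"), "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(emit("report.txt"), "w", encoding="utf-8") as fh:
            fh.write(_format_report(report))
        return report
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def _format_report(report: dict) -> str:
    lines = [
        "PLS-VIP differential expression run",
        "===================================",
        f"probes: {report['n_probes']} ({report['n_probes_modeled']} modeled)",
        f"samples: {report['n_samples']['patient']} patients, "
        f"{report['n_samples']['control']} controls",
        f"latent variables: {report['n_components']}; "
        f"permutations: {report['n_permutations']}; seed: {report['seed']}",
        f"selected at FDR < {report['fdr_threshold']}: {report['n_selected']} "
        f"({report['n_down']} depressed, {report['n_up']} overexpressed in patients)",
        "",
        f"top enriched terms (k/K in term, p-value):",
    ]
    for t in report["top_terms"]:
        lines.append(
            f"  {t['term_id']}  {t['term_name']}  [{t['term_class']}]  "
            f"{t['k']}/{t['K']}  p={t['p_value']:.3g}"
        )
    lines += [
        "",
        f"hub genes (degree > {report['hub_threshold']}): "
        + (", ".join(report["hubs"]) if report["hubs"] else "none"),
        "",
    ]
    return "\n".join(lines)
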