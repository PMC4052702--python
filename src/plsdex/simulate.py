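"""Synthetic two-group microarray data with known ground truth.

Emulates the study design the pipeline targets: a patients-vs-controls
log2 expression matrix (23 vs 11 samples by default), a planted subset
of differentially expressed probes with shifts of both signs, an
optional array-wide latent confounder of the kind that motivates using
PLS over per-probe tests, plus toy annotation and interaction fixtures
with one planted enriched term and planted hub genes.

The expression model per probe ``j`` and sample ``s`` is::

    x_js = mu_j + delta_j * class_s + gamma_j * b_s + eps_js

with baseline ``mu_j ~ U(baseline_range)``, planted shift
``delta_j = ±effect_size`` for DE probes (0 otherwise), a per-sample
latent factor ``b_s ~ N(0, confounder_sd)`` loading on every probe with
``gamma_j ~ N(0, 1)`` when the confounder is enabled, and i.i.d. noise
``eps_js ~ N(0, sigma^2)``. Everything is drawn from one seeded
generator in a fixed order, so outputs are fully deterministic.

Synthetic probes map 1:1 to synthetic genes (``P0001`` -> ``G0001``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AnnotationMap,
    EdgeList,
    ExpressionMatrix,
    SampleLabels,
    write_annotation,
    write_edges,
    write_expression_matrix,
    write_labels,
)

__all__ = ["SyntheticConfig", "GroundTruth", "generate_expression",
           "generate_annotation", "generate_edges", "generate_all", "write_dataset"]

TERM_CLASSES = ("Process", "Function", "Component")


@dataclass
class SyntheticConfig:
    """Study-design parameters for the generator.

    Defaults mirror the target design: 23 patients vs 11 controls, 1000
    probes with 50 planted differential probes at a |log2 shift| of 1.0
    (25% shifted up in patients), per-probe noise sd 0.5 on the log2
    scale, confounder disabled.
    """

    n_patients: int = 23
    n_controls: int = 11
    n_probes: int = 1000
    n_de: int = 50
    effect_size: float = 1.0
    frac_up: float = 0.25
    sigma: float = 0.5
    confounder_sd: float = 0.0
    class_correlated_confounder: bool = False
    baseline_range: tuple[float, float] = (6.0, 12.0)
    n_terms: int = 40
    term_size_range: tuple[int, int] = (10, 40)
    enriched_de_fraction: float = 0.8
    n_hubs: int = 2
    hub_degrees: tuple[int, ...] = (20, 14)
    n_background_edges: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("n_patients and n_controls must each be >= 2")
        if self.n_de > self.n_probes:
            raise ValueError(f"n_de ({self.n_de}) exceeds n_probes ({self.n_probes})")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not 0 <= self.frac_up <= 1:
            raise ValueError(f"frac_up must be in [0, 1], got {self.frac_up}")
        if self.confounder_sd < 0:
            raise ValueError(f"confounder_sd must be >= 0, got {self.confounder_sd}")
        if self.baseline_range[0] > self.baseline_range[1]:
            raise ValueError(f"invalid baseline_range {self.baseline_range}")


@dataclass
class GroundTruth:
    """Planted signal: which probes differ, which term is enriched, which
    genes are hubs."""

    de_probes: dict[str, str]          # probe_id -> planted sign ('up'/'down')
    enriched_term_id: str | None = None
    planted_hub_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _probe_id(j: int, width: int) -> str:
    return f"P{j + 1:0{width}d}"


def probe_to_gene(probe_id: str) -> str:
    return "G" + probe_id[1:]


def generate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleLabels, GroundTruth]:
    """Draw the expression matrix, labels, and planted-probe truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients + config.n_controls
    p = config.n_probes
    width = max(4, len(str(p)))
    probe_ids = [_probe_id(j, width) for j in range(p)]
    sample_ids = [f"patient_{i + 1:02d}" for i in range(config.n_patients)] + [
        f"control_{i + 1:02d}" for i in range(config.n_controls)
    ]
    cls = np.array([1.0] * config.n_patients + [0.0] * config.n_controls)

    mu = rng.uniform(*config.baseline_range, size=p)
    de_idx = rng.choice(p, size=config.n_de, replace=False)
    n_up = int(round(config.frac_up * config.n_de))
    signs = np.array([1.0] * n_up + [-1.0] * (config.n_de - n_up))
    delta = np.zeros(p)
    delta[de_idx] = signs * config.effect_size

    X = mu[:, None] + delta[:, None] * cls[None, :]
    if config.confounder_sd > 0:
        b = rng.normal(0.0, config.confounder_sd, size=n)
        if config.class_correlated_confounder:
            # shift the factor by class so it partially mimics the signal
            b = b + (cls - cls.mean()) * config.confounder_sd
        gamma = rng.normal(0.0, 1.0, size=p)
        X = X + gamma[:, None] * b[None, :]
    X = X + rng.normal(0.0, config.sigma, size=(p, n))

    matrix = ExpressionMatrix(pd.DataFrame(X, index=probe_ids, columns=sample_ids))
    labels = SampleLabels(
        pd.Series(cls.astype(int), index=sample_ids),
        group_names={1: "patient", 0: "control"},
    )
    truth = GroundTruth(
        de_probes={
            probe_ids[j]: ("up" if delta[j] > 0 else "down") for j in sorted(de_idx)
        }
    )
    return matrix, labels, truth


def generate_annotation(config: SyntheticConfig, truth: GroundTruth) -> AnnotationMap:
    """Toy term annotations with one term enriched in planted DE genes.

    Non-designated terms sample genes uniformly from the whole gene
    universe; the designated term draws ``enriched_de_fraction`` of its
    members from planted DE genes and the rest from the background.
    """
    rng = np.random.default_rng(config.seed + 1)
    width = max(4, len(str(config.n_probes)))
    all_genes = [probe_to_gene(_probe_id(j, width)) for j in range(config.n_probes)]
    de_genes = sorted(probe_to_gene(pid) for pid in truth.de_probes)
    non_de = sorted(set(all_genes) - set(de_genes))
    rows: list[tuple[str, str, str, str]] = []
    lo, hi = config.term_size_range
    enriched_term = "GO:SYN0001"
    for t in range(config.n_terms):
        term_id = f"GO:SYN{t + 1:04d}"
        term_class = TERM_CLASSES[t % len(TERM_CLASSES)]
        size = int(rng.integers(lo, hi + 1))
        if term_id == enriched_term and de_genes:
            n_from_de = min(len(de_genes), int(round(config.enriched_de_fraction * size)))
            members = list(rng.choice(de_genes, size=n_from_de, replace=False))
            members += list(rng.choice(non_de, size=size - n_from_de, replace=False))
        else:
            members = list(rng.choice(all_genes, size=size, replace=False))
        for g in sorted(set(members)):
            rows.append((g, term_id, f"synthetic term {t + 1}", term_class))
    truth.enriched_term_id = enriched_term if de_genes else None
    return AnnotationMap(
        pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name", "term_class"])
    )


def generate_edges(config: SyntheticConfig, truth: GroundTruth) -> EdgeList:
    """Random interaction edges over DE genes with planted hub nodes.

    A sparse random background graph over the DE genes is augmented by
    connecting each planted hub to enough distinct partners that its
    degree in the DE-induced subgraph exceeds 10; any non-hub pushed
    above 10 by chance has excess background edges removed so the hub
    set is exactly the planted one.
    """
    rng = np.random.default_rng(config.seed + 2)
    de_genes = sorted(probe_to_gene(pid) for pid in truth.de_probes)
    if len(de_genes) < max(config.hub_degrees, default=0) + 1:
        raise ValueError(
            "not enough DE genes to realize the requested hub degrees"
        )
    hubs = [str(h) for h in rng.choice(de_genes, size=config.n_hubs, replace=False)]
    deg: dict[str, int] = {g: 0 for g in de_genes}
    edges: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> bool:
        if a == b:
            return False
        e = (a, b) if a <= b else (b, a)
        if e in edges:
            return False
        edges.add(e)
        deg[a] += 1
        deg[b] += 1
        return True

    # sparse background
    for _ in range(config.n_background_edges):
        a, b = rng.choice(de_genes, size=2, replace=False)
        add(a, b)
    # planted hubs
    for hub, target in zip(hubs, config.hub_degrees):
        partners = [g for g in de_genes if g != hub]
        rng.shuffle(partners)
        for g in partners:
            if deg[hub] >= target:
                break
            add(hub, g)
    # keep chance high-degree non-hubs below the threshold
    for g in sorted(deg):
        if g in hubs:
            continue
        while deg[g] > 10:
            victims = [
                e for e in sorted(edges) if g in e and e[0] not in hubs and e[1] not in hubs
            ]
            if not victims:
                break
            a, b = victims[0]
            edges.discard((a, b))
            deg[a] -= 1
            deg[b] -= 1
    truth.planted_hub_ids = sorted(hubs)
    return EdgeList(pd.DataFrame(sorted(edges), columns=["gene_a", "gene_b"]))


def generate_all(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleLabels, AnnotationMap, EdgeList, GroundTruth]:
    """Generate every fixture the pipeline consumes, sharing one truth."""
    matrix, labels, truth = generate_expression(config)
    annotation = generate_annotation(config, truth)
    edges = generate_edges(config, truth)
    return matrix, labels, annotation, edges, truth


def write_dataset(config: SyntheticConfig, outdir: str | Path) -> GroundTruth:
    """Generate and write expression.tsv, labels.tsv, annotation.tsv,
    edges.tsv, gene_map.tsv and truth.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, labels, annotation, edges, truth = generate_all(config)
    write_expression_matrix(matrix, outdir / "expression.tsv")
    write_labels(labels, outdir / "labels.tsv")
    write_annotation(annotation, outdir / "annotation.tsv")
    write_edges(edges, outdir / "edges.tsv")
    gene_map = pd.DataFrame(
        {"probe_id": matrix.probe_ids,
         "gene_id": [probe_to_gene(p) for p in matrix.probe_ids]}
    )
    gene_map.to_csv(outdir / "gene_map.tsv", sep="\t", index=False, lineterminator="\n")
    truth.to_json(outdir / "truth.json")
    return truth
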