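"""Interaction network over selected genes: degrees and hub calls.

The network is the induced subgraph of the interaction edge list on the
selected genes — an edge survives only if both endpoints are selected;
selected genes with no surviving interaction remain as isolated nodes.
A gene's degree is its number of distinct interaction partners, and
genes with degree strictly greater than the hub threshold (default 10)
are called hub molecules.

Exports are Cytoscape-loadable plain text: a SIF edge file plus a node
attribute table carrying degree (size channel), regulation direction
(color channel: up = overexpressed in patients, down = depressed) and
the hub flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .io import EdgeList

__all__ = ["InteractionNetwork", "build_network", "degrees", "hubs", "export_network"]

DEFAULT_HUB_THRESHOLD = 10  # exclusive: hub iff degree > 10


@dataclass
class InteractionNetwork:
    graph: nx.Graph  # nodes carry a 'direction' attribute in {'up', 'down'}

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]


def build_network(
    selected: pd.DataFrame | set[str],
    edges: EdgeList,
    direction: dict[str, str] | None = None,
) -> InteractionNetwork:
    """Induce the interaction subgraph on the selected genes.

    ``selected`` is either a significance table (rows with
    ``selected == True`` and a ``gene_id`` — falling back to ``probe_id``
    — define the node set) or a plain set of gene ids. Self-loops and
    duplicate edges are already collapsed by :class:`~plsdex.io.EdgeList`.
    """
    if isinstance(selected, pd.DataFrame):
        sel = selected[selected["selected"]]
        id_col = "gene_id" if "gene_id" in sel.columns else "probe_id"
        genes = set(sel[id_col].dropna())
        if direction is None:
            direction = dict(zip(sel[id_col], sel["direction"]))
    else:
        genes = set(selected)
    g = nx.Graph()
    g.add_nodes_from(genes)
    for a, b in edges.pairs:
        if a in genes and b in genes:
            g.add_edge(a, b)
    nx.set_node_attributes(
        g, {v: (direction or {}).get(v, "down") for v in g.nodes}, "direction"
    )
    return InteractionNetwork(g)


def degrees(network: InteractionNetwork) -> dict[str, int]:
    """Distinct-neighbor count per node."""
    return {v: d for v, d in network.graph.degree()}


def hubs(network: InteractionNetwork, min_exclusive: int = DEFAULT_HUB_THRESHOLD) -> set[str]:
    """Nodes with degree strictly greater than ``min_exclusive``."""
    return {v for v, d in network.graph.degree() if d > min_exclusive}


def export_network(
    network: InteractionNetwork,
    sif_path: str | Path,
    nodes_path: str | Path,
    hub_threshold: int = DEFAULT_HUB_THRESHOLD,
) -> None:
    """Write a SIF edge file and a node attribute TSV.

    The SIF uses the ``pp`` (protein-protein) interaction type; isolated
    nodes are written as single-field SIF lines so Cytoscape keeps them.
    The node table holds gene, degree, direction and hub columns.
    """
    deg = degrees(network)
    hub_set = hubs(network, hub_threshold)
    edge_lines = [f"{a}\tpp\t{b}" for a, b in sorted(network.edges)]
    isolated = sorted(v for v, d in deg.items() if d == 0)
    with open(sif_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(edge_lines + isolated))
        if edge_lines or isolated:
            fh.write("\n")
    table = pd.DataFrame(
        {
            "gene": sorted(network.nodes),
        }
    )
    table["degree"] = table["gene"].map(deg)
    table["direction"] = table["gene"].map(
        nx.get_node_attributes(network.graph, "direction")
    )
    table["hub"] = table["gene"].isin(hub_set)
    table.to_csv(nodes_path, sep="\t", index=False, lineterminator="\n")


def read_sif(path: str | Path) -> EdgeList:
    """Read back a SIF file written by :func:`export_network`."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                rows.append((fields[0], fields[2]))
    return EdgeList(pd.DataFrame(rows, columns=["gene_a", "gene_b"]))
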