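"""Interaction network over differential genes and degree-based hub calls.

Induces the interaction subgraph on the (here: perfectly recovered)
differential genes, computes each gene's number of distinct interaction
partners, and calls genes with degree > 10 hub molecules.
"""

from plsdex import (
    SyntheticConfig, generate_expression, generate_edges,
    build_network, degrees, hubs, export_network,
)
from plsdex.simulate import probe_to_gene

cfg = SyntheticConfig(seed=41)
_, _, truth = generate_expression(cfg)
edges = generate_edges(cfg, truth)

de_genes = {probe_to_gene(p) for p in truth.de_probes}
net = build_network(de_genes, edges)

deg = degrees(net)
hub_set = hubs(net, min_exclusive=10)
print(f"nodes: {len(net.nodes)}, edges: {len(net.edges)}")
top5 = sorted(deg.items(), key=lambda kv: -kv[1])[:5]
for gene, d in top5:
    mark = "  <-- hub" if gene in hub_set else ""
    print(f"  {gene}: degree {d}{mark}")
print(f"hub genes (degree > 10): {sorted(hub_set)}")
print(f"planted hubs:            {truth.planted_hub_ids}")

export_network(net, "scratch_network.sif", "scratch_network_nodes.tsv")
print("wrote scratch_network.sif / scratch_network_nodes.tsv "
      "(Cytoscape-loadable; node size ~ degree, color ~ direction)")
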