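"""The whole workflow in one call: simulate, run, read the report.

Equivalent shell usage:

    plsdex simulate --out data --seed 7
    plsdex run --config run.yaml
"""

import json
import tempfile
from pathlib import Path

from plsdex import RunConfig, SyntheticConfig, run_pipeline, write_dataset

with tempfile.TemporaryDirectory() as tmp:
    data = Path(tmp) / "data"
    cfg = SyntheticConfig(n_probes=300, n_de=30, effect_size=2.0,
                          hub_degrees=(15, 12), seed=7)
    truth = write_dataset(cfg, data)
    report = run_pipeline(RunConfig(
        expression=str(data / "expression.tsv"),
        labels=str(data / "labels.tsv"),
        annotation=str(data / "annotation.tsv"),
        edges=str(data / "edges.tsv"),
        gene_map=str(data / "gene_map.tsv"),
        outdir=str(Path(tmp) / "run"),
        n_permutations=200,
        seed=8,
    ))
    print((Path(tmp) / "run" / "report.txt").read_text())
    print("planted hubs:", truth.planted_hub_ids,
          "— reported:", report["hubs"])
    print("selected:", report["n_selected"],
          "= up", report["n_up"], "+ down", report["n_down"])
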