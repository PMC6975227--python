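"""End-to-end pipeline run with a manifest, plus the enrichment stage.

Equivalent to `ceranet all --out scratch/example_run --seed 1` on the shell.
"""

from pathlib import Path

import pandas as pd

from ceranet import PipelineConfig, run_all

cfg = PipelineConfig(out_dir="scratch/example_run", seed=1)
manifest = run_all(cfg)

for stage, info in manifest["stages"].items():
    detail = {k: v for k, v in info.items() if k != "status"}
    print(f"{stage:>9}: {info['status']} {detail}")

enr = pd.read_csv(Path(cfg.out_dir) / "enrichment.tsv", sep="\t")
row = enr.iloc[0]
print(f"\ncancer-gene catalog: {row['overlap']} of {row['set_in_universe']} "
      f"expressed catalog genes among the network's {row['network_genes']} "
      f"protein-coding genes (universe {row['universe']}); "
      f"hypergeometric p = {row['p_value']:.2e}")
# The run directory holds every stage's TSV/JSON output plus manifest.json
# and the resolved configuration for reproducibility.
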