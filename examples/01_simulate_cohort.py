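"""Generate a synthetic tumor/normal cohort with planted ground truth.

The generator emulates a class-imbalanced RNA-seq cohort (mRNA + lncRNA +
miRNA), plants differential expression, negatively correlated miRNA->target
regulatory trios, AGO CLIP coverage of true target sites, and survival times
driven by a prognostic module.
"""

from collections import Counter

from ceranet import SimConfig, simulate_cohort, write_dataset

cfg = SimConfig(seed=1)
cohort = simulate_cohort(cfg)

print(f"samples: {cfg.n_tumor} tumor + {cfg.n_normal} normal")
print(f"molecules: {cfg.n_mrna} mRNA, {cfg.n_lncrna} lncRNA, {cfg.n_mirna} miRNA")
directions = Counter(cohort.ledger.de_molecules.values())
print(f"planted DE: {len(cohort.ledger.de_molecules)} molecules {dict(directions)}")
print(f"planted regulatory edges: {len(cohort.ledger.regulatory_edges)} "
      f"(miRNA -> lncRNA/mRNA, negative correlation ~{cfg.planted_edge_r})")
print(f"prognostic module: {len(cohort.ledger.prognostic_module)} molecules, "
      f"hazard ratio {cfg.hazard_ratio} for module-low samples")
print(f"candidate target sites: {len(cohort.candidates)}, "
      f"AGO CLIP peaks: {len(cohort.clip_sites)}")

manifest = write_dataset(cohort, "scratch/example_dataset")
print(f"wrote {len(manifest['files'])} files to scratch/example_dataset/")
# Everything downstream (DE calls, network, survival) can now be checked
# against ground_truth.json.
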