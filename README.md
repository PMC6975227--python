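# ceranet

Dysregulated lncRNA–miRNA–mRNA network analysis for tumor/normal RNA-seq
cohorts: differential expression with ON/OFF binarization, AGO-CLIP-supported
miRNA target filtering, correlation-filtered tripartite network construction
with scale-free topology diagnostics, clique-extension module detection, and
Kaplan–Meier / log-rank survival stratification of modules and genes. A
synthetic-cohort generator with planted ground truth makes every stage
testable end to end without any data download.

## The problem and the method

Competing-endogenous-RNA (ceRNA) analyses ask how lncRNAs and mRNAs that
share miRNA binding sites co-regulate each other through miRNA sequestration,
and which of those circuits are rewired in cancer. `ceranet` implements a
*dysregulated* variant of this analysis for class-imbalanced tumor/normal
cohorts (the motivating setting is invasive breast carcinoma with ~1000
tumors against ~100 normals):

1. **Pre-processing** — molecules with expression 0 in more than 10% of
   normal samples are eliminated.
2. **Two-branch differential expression** — molecules with <30% zeros among
   tumor samples take a Welch t-test and are called at fold change
   FC > 2 (up) or FC < 0.5 (down) with Benjamini–Hochberg FDR < 0.01;
   heavily zero-inflated molecules are binarized (ON = value > 0) and tested
   by a two-sided Fisher's exact test on the ON/OFF × tumor/normal table,
   with "ON in cancer" when the tumor ON-frequency is at least twice the
   normal one, FDR < 0.01.
3. **Target filtering** — candidate miRNA target sites (an external
   prediction table, or an exact 7-mer seed-complementarity scan of the
   3'UTR for mRNAs / full transcript for lncRNAs) are retained only when the
   site overlaps ≥ 1 AGO CLIP-seq binding interval on the same transcript
   (0-based half-open coordinates, ≥ 1 shared base).
4. **Network construction** — a three-step filter over the (miRNA, target)
   pairs: keep DE molecules only; keep pairs with |Pearson r| > 0.4 and
   p < 0.01 across samples (p from t = r·√((n−2)/(1−r²))); keep only miRNAs
   that retain both a lncRNA and an mRNA partner. The result is tripartite
   by construction and is profiled with degree fractions, a log10–log10 OLS
   power-law fit of the degree histogram, shortest-path and closeness
   diagnostics.
5. **Modules and survival** — modules grow from maximal cliques by absorbing
   vertices whose connectivity ratio to the cluster is ≥ 0.6; each module
   (or single gene) is scored per tumor sample as the mean z-scored
   expression, samples are split into two groups by exact 1-D k-means
   (k = 2), and the groups are compared with a two-sided log-rank test at
   α = 0.05 on Kaplan–Meier curves.
6. **Enrichment** — upper-tail hypergeometric tests of the network's
   protein-coding genes against reference catalogs (cancer genes,
   housekeeping genes, RNA-binding proteins), with the universe taken as the
   expressed (post-prefilter) protein-coding genes.

The synthetic generator (`ceranet.simulate`) plants all of the above —
up/down and OFF-in-cancer DE, negatively correlated miRNA→target trios with
a configurable pooled correlation, exact CLIP coverage fractions, and
exponential survival with a configurable hazard ratio between module-low and
module-high samples — and records the truth in a ledger for recovery checks.

## Worked example

```python
from ceranet import (SimConfig, simulate_cohort, call_differential_expression,
                     filter_by_clip, collapse_to_pairs, build_network,
                     survival_screen)

cohort = simulate_cohort(SimConfig(seed=1))          # 100 tumor + 50 normal
de = call_differential_expression(cohort.combined)   # two-branch DE
pairs = collapse_to_pairs(filter_by_clip(cohort.candidates, cohort.clip_sites))
net = build_network(de, pairs, cohort.combined, r_cut=0.4, p_cut=0.01)
res = survival_screen({"planted": cohort.ledger.prognostic_module},
                      cohort.combined, cohort.clinical, seed=1)[0]
```

This prints (via `python examples/04_dysregulated_network.py` and
`examples/05_modules_and_survival.py`):

```
network: 60 nodes, 40 edges
node classes: {'miRNA': 20, 'mRNA': 20, 'lncRNA': 20}
planted-edge recall: 1.00
edge correlations: min r -0.74, max r -0.64 (all negative: miRNA repression)
planted module (9 molecules): log-rank chi2 = 47.0, p = 7.25e-12
groups: 53 module-high vs 47 module-low samples; worse survival in the module-low group
```

All 40 planted regulatory edges pass the DE + correlation + shared-miRNA
filters, their correlations sit at the configured −0.7, and the planted
prognostic module (whose low-expression samples carry a 3× hazard) is
flagged with a vanishing log-rank p — the low-expression group fares worse,
as planted. The `examples/` directory has one short script per capability;
`ceranet all --out run --seed 1` runs the same pipeline from the shell and
writes every stage's tables plus a run manifest.

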