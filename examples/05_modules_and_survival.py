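"""Module detection and survival stratification.

Clique-extension module detection is shown on a dense demonstration graph
(the tripartite dysregulation network itself is triangle-free, so at
threshold 0.6 its stars cannot grow). The survival screen then stratifies
tumor samples by the planted module's average z-scored expression using an
exact two-group 1-D k-means split and compares the groups by log-rank.
"""

import networkx as nx

from ceranet import (
    SimConfig,
    clique_extension_clusters,
    km_curve,
    simulate_cohort,
    survival_screen,
)

# module detection on a dense graph: two overlapping communities
g = nx.Graph()
for block in ("abcde", "defgh"):
    g.add_edges_from((x, y) for i, x in enumerate(block) for y in block[i + 1:])
g.add_edge("x", "a"), g.add_edge("x", "b"), g.add_edge("x", "c")
mods = clique_extension_clusters(g, threshold=0.6, min_size=3)
for i, m in enumerate(mods, 1):
    print(f"module {i}: {sorted(m.nodes)} (seed clique size {m.seed_size}, "
          f"absorbed {[n for n, _ in m.additions]})")

# survival screen of the planted prognostic module
cohort = simulate_cohort(SimConfig(seed=1))
res = survival_screen(
    {"planted_module": cohort.ledger.prognostic_module},
    cohort.combined, cohort.clinical, alpha=0.05, seed=1,
)[0]
print(f"\nplanted module ({len(cohort.ledger.prognostic_module)} molecules): "
      f"log-rank chi2 = {res.chi_square:.1f}, p = {res.p_value:.2e}")
print(f"groups: {res.n_high} module-high vs {res.n_low} module-low samples; "
      f"worse survival in the module-{res.direction} group")

clin = cohort.clinical.set_index("sample_id").loc[res.labels.index]
lo = res.labels == 0
km = km_curve(clin["time_days"][lo], clin["event"][lo])
print(f"module-low Kaplan-Meier: S(t) falls to {km['survival'].iloc[-1]:.2f} "
      f"by day {km['time'].iloc[-1]:.0f}")
# The simulator gives module-low samples a 3x hazard, so the screen should
# flag this module with the low group faring worse.
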