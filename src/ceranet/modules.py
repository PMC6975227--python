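"""Dense-module detection by maximal-clique extension.

Modules are grown from maximal cliques: starting from each maximal clique of
at least ``seed_min_size`` nodes, any outside vertex whose connectivity ratio
to the current cluster — |neighbors(v) in cluster| / |cluster| — reaches the
threshold (default 0.6) is absorbed, largest ratio first with ties broken by
node id. Clusters that end up identical to, or subsets of, an already
accepted larger cluster are discarded, and clusters below ``min_size`` nodes
are dropped.

The seeding detail matters: the dysregulation network is bipartite (miRNA vs
lncRNA/mRNA) and therefore triangle-free, so requiring 3-clique seeds would
return nothing; edges (2-cliques) seed by default. The exact update rule of
the published clique-extension tool this emulates is not public, so every
module records the procedure parameters used.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .network import DysregNetwork


@dataclass(frozen=True)
class Module:
    """A detected module with its extension audit trail."""

    nodes: frozenset
    class_counts: dict
    seed_size: int
    threshold: float
    additions: tuple = ()  # (node, ratio) in the order vertices were absorbed

    def __len__(self) -> int:
        return len(self.nodes)


def maximal_cliques(net: DysregNetwork | nx.Graph) -> list[frozenset]:
    """All maximal cliques (complete enumeration, Bron-Kerbosch)."""
    g = net.graph if isinstance(net, DysregNetwork) else net
    return sorted(
        (frozenset(c) for c in nx.find_cliques(g)),
        key=lambda c: (-len(c), sorted(c)),
    )


def clique_extension_clusters(
    net: DysregNetwork | nx.Graph,
    threshold: float = 0.6,
    min_size: int = 3,
    seed_min_size: int = 2,
) -> list[Module]:
    """Grow modules from maximal-clique seeds by neighbor-ratio extension."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    g = net.graph if isinstance(net, DysregNetwork) else net
    raw: list[tuple[frozenset, int, tuple]] = []
    for seed in maximal_cliques(g):
        if len(seed) < seed_min_size:
            continue
        cluster = set(seed)
        additions = []
        while True:
            best = None
            for v in set().union(*(set(g[u]) for u in cluster)) - cluster:
                ratio = sum(1 for u in g[v] if u in cluster) / len(cluster)
                if ratio >= threshold:
                    key = (-ratio, str(v))
                    if best is None or key < best[0]:
                        best = (key, v, ratio)
            if best is None:
                break
            cluster.add(best[1])
            additions.append((best[1], best[2]))
        if len(cluster) >= min_size:
            raw.append((frozenset(cluster), len(seed), tuple(additions)))

    accepted: list[tuple[frozenset, int, tuple]] = []
    for cluster, seed_size, additions in sorted(
        raw, key=lambda t: (-len(t[0]), sorted(t[0]))
    ):
        if any(cluster <= a[0] for a in accepted):
            continue
        accepted.append((cluster, seed_size, additions))

    modules = []
    for cluster, seed_size, additions in accepted:
        counts = Counter(g.nodes[n].get("cls", "unknown") for n in cluster)
        modules.append(
            Module(
                nodes=cluster,
                class_counts={
                    "miRNA": counts.get("miRNA", 0),
                    "lncRNA": counts.get("lncRNA", 0),
                    "mRNA": counts.get("mRNA", 0),
                },
                seed_size=seed_size,
                threshold=threshold,
                additions=additions,
            )
        )
    return modules
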