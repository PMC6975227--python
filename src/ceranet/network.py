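"""Dysregulated lncRNA-miRNA-mRNA network construction and topology.

The network is built from CLIP-supported (miRNA, target) pairs by a three-step
filter: (1) keep only differentially expressed molecules, (2) keep only pairs
whose expression is significantly Pearson-correlated across samples
(|r| > 0.4, p < 0.01 by default), (3) keep only miRNAs that retain at least
one lncRNA AND one mRNA partner; degree-zero nodes are then dropped. The
result is tripartite by construction: every edge joins a miRNA to a non-miRNA.

Topology diagnostics (degree fractions, log-log power-law fit of the degree
histogram, shortest-path-length histogram, closeness centrality) characterize
the scale-free / small-world behaviour expected of biological networks.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p-value (t-transform with n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DysregNetwork:
    """Tripartite dysregulation graph plus its edge table."""

    graph: nx.Graph
    edges: pd.DataFrame  # mirna_id, target_id, target_class, r, p_value

    def __post_init__(self):
        for u, v in self.graph.edges():
            cu = self.graph.nodes[u]["cls"]
            cv = self.graph.nodes[v]["cls"]
            if (cu == "miRNA") == (cv == "miRNA"):
                raise ValueError(f"non-tripartite edge {u}-{v} ({cu}-{cv})")

    @property
    def nodes(self) -> pd.DataFrame:
        rows = [
            (n, d["cls"], d.get("status", ""), self.graph.degree(n))
            for n, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows, columns=["id", "class", "status", "degree"])

    def class_counts(self) -> dict:
        return Counter(d["cls"] for _, d in self.graph.nodes(data=True))


def build_network(
    de_calls: pd.DataFrame,
    pairs: pd.DataFrame,
    expr: ExpressionMatrix,
    r_cut: float = 0.4,
    p_cut: float = 0.01,
    samples: str = "all",
    negative_only: bool = False,
) -> DysregNetwork:
    """Three-step dysregulated-network filter.

    Parameters
    ----------
    de_calls
        DE table with ``molecule_id``, ``class`` and ``status`` columns; only
        molecules whose status is not ``not_de`` enter the network.
    pairs
        (miRNA, target) relationship table with ``mirna_id``, ``target_id``
        and ``target_class``.
    expr
        Expression over which pair correlations are computed.
    samples
        ``"all"`` (default; tumor + normal, as the correlations are taken
        across samples) or ``"tumor"``.
    negative_only
        Additionally require r < 0 (miRNA repression sign); off by default
        since the filter is on |r| only.
    """
    de = de_calls[de_calls["status"] != "not_de"]
    de_ids = set(de["molecule_id"])
    status_of = dict(zip(de["molecule_id"], de["status"]))

    if samples == "tumor":
        expr = expr.subset_samples(expr.tumor_samples)
    elif samples != "all":
        raise ValueError("samples must be 'all' or 'tumor'")
    known = set(expr.molecules)
    cls_of = expr.molecule_class.to_dict()
    values = expr.values

    # step 1: drop pairs with a non-DE endpoint
    step1 = pairs[
        pairs["mirna_id"].isin(de_ids) & pairs["target_id"].isin(de_ids)
    ]
    # step 2: expression correlation across samples
    edge_rows = []
    for row in step1.itertuples(index=False):
        if row.mirna_id not in known or row.target_id not in known:
            log.warning("pair (%s, %s) missing from expression; skipped",
                        row.mirna_id, row.target_id)
            continue
        x = values.loc[row.mirna_id].to_numpy(float)
        y = values.loc[row.target_id].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            log.warning("pair (%s, %s) has zero variance; skipped",
                        row.mirna_id, row.target_id)
            continue
        r, p = pearson_with_p(x, y)
        if abs(r) > r_cut and p < p_cut and (not negative_only or r < 0):
            edge_rows.append((row.mirna_id, row.target_id, row.target_class, r, p))
    edges = pd.DataFrame(
        edge_rows, columns=["mirna_id", "target_id", "target_class", "r", "p_value"]
    ).drop_duplicates(subset=["mirna_id", "target_id"])

    # step 3: miRNAs must keep both a lncRNA and an mRNA partner
    by_mirna = edges.groupby("mirna_id")["target_class"].agg(set)
    shared = set(by_mirna.index[by_mirna.apply(lambda s: {"lncRNA", "mRNA"} <= s)])
    edges = edges[edges["mirna_id"].isin(shared)].reset_index(drop=True)

    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_node(row.mirna_id, cls="miRNA", status=status_of.get(row.mirna_id, ""))
        g.add_node(row.target_id, cls=str(cls_of.get(row.target_id, row.target_class)),
                   status=status_of.get(row.target_id, ""))
        g.add_edge(row.mirna_id, row.target_id, r=row.r, p=row.p_value)
    # any node that made it into g has degree >= 1 by construction
    return DysregNetwork(graph=g, edges=edges)


# --- topology diagnostics -----------------------------------------------------


def degree_summary(net: DysregNetwork | nx.Graph, low: int = 5, high: int = 10) -> dict:
    """Degree histogram plus the fractions of nodes below/above two cuts."""
    g = net.graph if isinstance(net, DysregNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = [d for _, d in g.degree()]
    hist = dict(sorted(Counter(degrees).items()))
    n = len(degrees)
    return {
        "histogram": hist,
        "frac_degree_lt": sum(1 for d in degrees if d < low) / n,
        "frac_degree_gt": sum(1 for d in degrees if d > high) / n,
        "low_cut": low,
        "high_cut": high,
        "n_nodes": n,
    }


def fit_power_law(histogram: dict) -> dict:
    """OLS fit of log10(frequency) on log10(degree) over degrees >= 1.

    Returns slope, R^2 and the magnitude of the Pearson correlation of the
    fitted points. Zero-frequency degrees are excluded; at least three
    distinct degrees are required. The fitting convention (histogram, not
    CCDF; no binning) is part of the returned metadata because alternative
    conventions change R^2.
    """
    pts = [(k, f) for k, f in histogram.items() if k >= 1 and f >= 1]
    if len(pts) < 3:
        raise ValueError("power-law fit needs >= 3 distinct degrees")
    logk = np.log10([k for k, _ in pts])
    logf = np.log10([f for _, f in pts])
    res = stats.linregress(logk, logf)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "correlation": float(abs(res.rvalue)),
        "n_points": len(pts),
        "method": "log10 frequency vs log10 degree, OLS, zero-frequency degrees excluded",
    }


def shortest_path_histogram(net: DysregNetwork | nx.Graph) -> dict:
    """BFS all-pairs shortest-path-length histogram over unordered pairs.

    Disconnected pairs are excluded from the histogram and counted separately.
    """
    g = net.graph if isinstance(net, DysregNetwork) else net
    counts: Counter = Counter()
    nodes = list(g.nodes())
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, d in lengths.items():
            if d > 0:
                counts[d] += 1
    hist = {d: c // 2 for d, c in sorted(counts.items())}
    n = len(nodes)
    connected_pairs = sum(hist.values())
    return {
        "histogram": hist,
        "disconnected_pairs": n * (n - 1) // 2 - connected_pairs,
    }


def closeness(net: DysregNetwork | nx.Graph) -> dict:
    """Closeness centrality (n_c - 1) / sum of distances within the component.

    Isolated nodes get 0.
    """
    g = net.graph if isinstance(net, DysregNetwork) else net
    return {n: float(c) for n, c in
            nx.closeness_centrality(g, wf_improved=False).items()}


def topology_summary(net: DysregNetwork | nx.Graph) -> dict:
    """All topology diagnostics in one JSON-serializable bundle."""
    g = net.graph if isinstance(net, DysregNetwork) else net
    deg = degree_summary(net)
    try:
        pl = fit_power_law(deg["histogram"])
    except ValueError as exc:
        pl = {"error": str(exc)}
    paths = shortest_path_histogram(net)
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "class_counts": dict(Counter(
            d.get("cls", "unknown") for _, d in g.nodes(data=True)
        )),
        "degree": deg,
        "power_law": pl,
        "shortest_paths": paths,
        "closeness": closeness(net),
    }


def graph_from_edge_list(edges: pd.DataFrame, classes: dict | None = None) -> nx.Graph:
    """Build a plain graph from an external edge-list table.

    Accepts any table whose first two columns are node ids (e.g. a published
    supplementary network table); ``classes`` optionally maps node id -> RNA
    class for class counting.
    """
    g = nx.Graph()
    for u, v in edges.iloc[:, :2].itertuples(index=False):
        u, v = str(u), str(v)
        g.add_node(u, cls=(classes or {}).get(u, "unknown"))
        g.add_node(v, cls=(classes or {}).get(v, "unknown"))
        g.add_edge(u, v)
    return g
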