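"""Gene-set overlap bookkeeping and hypergeometric enrichment.

Tests whether the network's protein-coding genes are enriched for a reference
catalog (cancer genes, housekeeping genes, RNA-binding proteins) by the
upper-tail hypergeometric probability of drawing at least the observed number
of catalog members when sampling the network genes from the expressed-gene
universe.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom


def hypergeometric_enrichment(
    hits_in_network: int,
    network_genes: int,
    set_in_universe: int,
    universe: int,
) -> float:
    """Upper-tail P(X >= hits) for X ~ Hypergeom(universe, set, network draws)."""
    if min(hits_in_network, network_genes, set_in_universe, universe) < 0:
        raise ValueError("counts must be nonnegative")
    if hits_in_network > min(network_genes, set_in_universe):
        raise ValueError("hits cannot exceed network size or set size")
    if max(network_genes, set_in_universe) > universe:
        raise ValueError("network and set sizes cannot exceed the universe")
    return float(hypergeom.sf(hits_in_network - 1, universe, set_in_universe,
                              network_genes))


def overlap_report(
    network_nodes: pd.DataFrame, gene_sets: dict, de_status: dict | None = None
) -> pd.DataFrame:
    """Per-set intersection with the network's protein-coding genes.

    ``network_nodes`` needs ``id`` and ``class`` columns. The up/down split
    maps binary-branch directions onto up (ON in cancer) / down (OFF in
    cancer) so every DE status contributes a direction.
    """
    coding = [
        str(i) for i, c in zip(network_nodes["id"], network_nodes["class"])
        if c == "mRNA"
    ]
    coding_set = set(coding)
    de_status = de_status or {}
    up_status = {"up", "on_in_cancer"}
    rows = []
    for name, members in gene_sets.items():
        inter = sorted(coding_set & set(members))
        n_up = sum(1 for g in inter if de_status.get(g) in up_status)
        n_down = sum(
            1 for g in inter if de_status.get(g) in {"down", "off_in_cancer"}
        )
        rows.append(
            {
                "set_name": name,
                "set_size": len(set(members)),
                "overlap": len(inter),
                "fraction_of_network_genes": (
                    len(inter) / len(coding_set) if coding_set else 0.0
                ),
                "n_up": n_up,
                "n_down": n_down,
                "members": ",".join(inter),
            }
        )
    return pd.DataFrame(rows)


def read_gene_set(path) -> list:
    """One gene id per line (blank lines and '#' comments ignored)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[-1])
    return out
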