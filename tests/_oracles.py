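"""Independent brute-force / closed-form oracles used across the test suite.

Each oracle recomputes a quantity from first principles by a route different
from the implementation it checks (exhaustive enumeration, direct formulas,
plain BFS), so agreement is evidence, not tautology.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction

import numpy as np


# --- Fisher's exact test by exhaustive enumeration ---------------------------

def fisher_two_sided_enum(a: int, b: int, c: int, d: int,
                          rel_tie: float = 1e-7) -> float:
    """Two-sided Fisher p: sum of hypergeometric probabilities of all tables
    with the observed margins that are no more probable than the observed one.

    Probabilities are exact rationals; ``rel_tie`` admits near-ties the way
    floating-point implementations conventionally do.
    """
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(x: int) -> Fraction:
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > n - row1:
            return Fraction(0)
        return Fraction(
            math.comb(row1, x) * math.comb(n - row1, col1 - x),
            math.comb(n, col1),
        )

    p_obs = pmf(a)
    cutoff = p_obs * (1 + Fraction(int(rel_tie * 10**18), 10**18))
    total = sum(
        (p for x in range(0, min(row1, col1) + 1)
         if (p := pmf(x)) > 0 and p <= cutoff),
        Fraction(0),
    )
    return float(min(total, Fraction(1)))


# --- graph oracles: plain-BFS distances, closeness, maximal cliques ----------

def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def closeness_bfs(adj: dict) -> dict:
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        tot = sum(dist.values())
        out[v] = (len(dist) - 1) / tot if tot > 0 else 0.0
    return out


def path_histogram_bfs(adj: dict) -> tuple[dict, int]:
    """(histogram over unordered connected pairs, disconnected pair count)."""
    hist: dict = {}
    nodes = sorted(adj)
    connected = 0
    for i, v in enumerate(nodes):
        dist = bfs_distances(adj, v)
        for u in nodes[i + 1:]:
            if u in dist:
                hist[dist[u]] = hist.get(dist[u], 0) + 1
                connected += 1
    n = len(nodes)
    return dict(sorted(hist.items())), n * (n - 1) // 2 - connected


def maximal_cliques_brute(adj: dict) -> set:
    """All maximal cliques by naive DFS extension over ordered vertices."""
    nodes = sorted(adj)
    cliques: set = set()

    def grow(clique: frozenset, candidates: list):
        extended = False
        for i, v in enumerate(candidates):
            if all(v in adj[u] for u in clique):
                grow(clique | {v}, candidates[i + 1:])
                extended = True
        if not extended:
            cliques.add(clique)

    grow(frozenset(), nodes)
    # the DFS records extension-terminal cliques; prune non-maximal leftovers
    return {
        c for c in cliques
        if not any(c < other for other in cliques)
        and not any(all(v in adj[u] for u in c) for v in set(nodes) - c)
    }


# --- statistics oracles -------------------------------------------------------

def pearson_formula(x, y) -> tuple[float, float]:
    """Textbook Pearson r and two-sided p via the t-transform."""
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r**2))
    return r, float(2 * tdist.sf(abs(t), n - 2))


def bh_stepup(p) -> np.ndarray:
    """Direct step-up formula: adj_(i) = min_{j>=i} p_(j) * m / j, capped."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def kmeans_1d_best_split_objective(scores) -> float:
    """Global 1-D 2-means objective by scanning every cutpoint."""
    s = np.sort(np.asarray(scores, float))
    best = math.inf
    for i in range(1, len(s)):
        left, right = s[:i], s[i:]
        obj = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        best = min(best, obj)
    return best


def logrank_tabulation(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """From-scratch O/E/Var log-rank tabulation over distinct event times."""
    from scipy.stats import chi2 as chi2_dist

    ta, ea = np.asarray(time_a, float), np.asarray(event_a, int)
    tb, eb = np.asarray(time_b, float), np.asarray(event_b, int)
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        d1 = int(((ta == t) & (ea == 1)).sum())
        d2 = int(((tb == t) & (eb == 1)).sum())
        n, d = n1 + n2, d1 + d2
        if n < 1 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var if var > 0 else 0.0
    return chi2, float(chi2_dist.sf(chi2, 1))


def km_product_limit(time, event) -> list:
    """Hand product-limit table: [(t, S(t))] at each distinct event time."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s = 1.0
    out = []
    for t in np.unique(time[event == 1]):
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1 - d / n_at_risk
        out.append((float(t), s))
    return out


def hypergeom_tail_enum(hits, draws, successes, universe) -> float:
    """Exact upper-tail P(X >= hits) by summing the pmf as rationals."""
    total = Fraction(0)
    denom = math.comb(universe, draws)
    for x in range(hits, min(draws, successes) + 1):
        total += Fraction(
            math.comb(successes, x) * math.comb(universe - successes, draws - x),
            denom,
        )
    return float(min(total, Fraction(1)))


def ols_loglog(hist: dict) -> tuple[float, float]:
    """Power-law fit by explicit normal equations on log10-log10 points."""
    pts = [(k, f) for k, f in hist.items() if k >= 1 and f >= 1]
    x = np.log10([k for k, _ in pts])
    y = np.log10([f for _, f in pts])
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    yhat = slope * x + intercept
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1 - ss_res / ss_tot
    return float(slope), float(r2)


def graph_to_adj(g) -> dict:
    return {n: set(g[n]) for n in g.nodes()}
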