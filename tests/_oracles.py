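"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by the most transparent route available
(exhaustive enumeration, exact rational arithmetic, hand-rolled BFS or
triple loops) and deliberately shares no code with the implementation it
checks.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from math import comb

import numpy as np


def bh_stepup(pvalues) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    for i in range(n - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_upper_exact(k: int, n_a: int, n_b: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N=n, K=n_a, draws=n_b), exact rational."""
    total = comb(n, n_b)
    acc = Fraction(0)
    for x in range(k, min(n_a, n_b) + 1):
        acc += Fraction(comb(n_a, x) * comb(n - n_a, n_b - x), total)
    return acc


def km_product_limit(times, events):
    """Product-limit curve as (event_times, survival), computed step by step."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ets = sorted(set(times[events == 1]))
    out_t, out_s = [], []
    s = 1.0
    for t in ets:
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= (at_risk - d) / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_chi2(t1, e1, t2, e2) -> float:
    """Two-group log-rank chi-square from the pooled risk table."""
    t1, e1 = np.asarray(t1, float), np.asarray(e1, int)
    t2, e2 = np.asarray(t2, float), np.asarray(e2, int)
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    grp = np.concatenate([np.zeros(t1.size), np.ones(t2.size)])
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(all_t[all_e == 1])):
        at = all_t >= t
        n = at.sum()
        n1 = (at & (grp == 0)).sum()
        d = ((all_t == t) & (all_e == 1)).sum()
        d1 = ((all_t == t) & (all_e == 1) & (grp == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var) if var > 0 else 0.0


def rank_auc(case_scores, control_scores) -> float:
    """Plain pair-counting AUC with half credit for ties."""
    num = 0.0
    for c in case_scores:
        for k in control_scores:
            if c > k:
                num += 1.0
            elif c == k:
                num += 0.5
    return num / (len(case_scores) * len(control_scores))


def _bfs(adj: dict, source):
    """BFS distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    q = deque([source])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def graph_adj(edges, nodes):
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def betweenness_naive(edges, nodes) -> dict:
    """Betweenness from the pair-count definition: for every ordered source,
    fraction of s-t shortest paths through v, pairs counted once."""
    adj = graph_adj(edges, nodes)
    bc = {v: 0.0 for v in nodes}
    nlist = list(nodes)
    for i, s in enumerate(nlist):
        dist_s, sig_s = _bfs(adj, s)
        for t in nlist[i + 1 :]:
            if t not in dist_s or sig_s.get(t, 0) == 0:
                continue
            dist_t, sig_t = _bfs(adj, t)
            for v in nodes:
                if v in (s, t) or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == dist_s[t]:
                    bc[v] += sig_s[v] * sig_t[v] / sig_s[t]
    return bc


def radiality_naive(edges, nodes) -> dict:
    """Radiality from the definition, per connected component via BFS."""
    adj = graph_adj(edges, nodes)
    rad = {v: 0.0 for v in nodes}
    seen = set()
    for start in nodes:
        if start in seen:
            continue
        dist0, _ = _bfs(adj, start)
        comp = list(dist0)
        seen |= set(comp)
        if len(comp) == 1:
            continue
        dists = {v: _bfs(adj, v)[0] for v in comp}
        diam = max(d for v in comp for d in dists[v].values())
        for v in comp:
            rad[v] = sum(diam + 1 - dists[v][u] for u in comp if u != v) / (len(comp) - 1)
    return rad


def tom_triple_loop(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap from the definition, one entry at a time."""
    a = adjacency
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def es_running_sum(ordered_hits, weights, weight_p=1.0) -> float:
    """Weighted KS enrichment score walked step by step."""
    w = np.abs(np.asarray(weights, float)) ** weight_p
    hits = np.asarray(ordered_hits, bool)
    hit_total = w[hits].sum()
    n_miss = (~hits).sum()
    run, best = 0.0, 0.0
    for i in range(len(hits)):
        if hits[i]:
            run += w[i] / hit_total
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best
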