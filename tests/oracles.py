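"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own code paths: the transport oracle
solves the optimal-transport linear program directly, the graph oracles
enumerate paths and partitions exhaustively, and the AUROC oracle loops over
all case-control pairs.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def lp_transport_distance(u, v) -> float:
    """Optimal-transport cost between empirical samples by linear program.

    Variables are the coupling masses pi[i, j] >= 0 with marginals 1/|u| and
    1/|v|; objective sum pi[i, j] * |u_i - v_j|.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    m, n = u.size, v.size
    cost = np.abs(u[:, None] - v[None, :]).ravel()
    a_eq = []
    b_eq = []
    for i in range(m):
        row = np.zeros(m * n)
        row[i * n : (i + 1) * n] = 1.0
        a_eq.append(row)
        b_eq.append(1.0 / m)
    for j in range(n):
        row = np.zeros(m * n)
        row[j::n] = 1.0
        a_eq.append(row)
        b_eq.append(1.0 / n)
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success, res.message
    return float(res.fun)


def exhaustive_auroc(scores_cases, scores_controls) -> float:
    """P(case > control) + 0.5 P(tie) by explicit double loop."""
    wins = 0.0
    for a in scores_cases:
        for b in scores_controls:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(scores_cases) * len(scores_controls))


def exhaustive_edge_betweenness(lengths: dict[tuple[int, int], float], n: int):
    """Edge betweenness by enumerating every simple path between node pairs.

    ``lengths`` maps undirected edges (i < j) to positive lengths.  For each
    unordered node pair, all simple paths are enumerated, minimal-length
    paths found, and each edge on a minimal path credited 1/(number of
    minimal paths).  Returns {edge: betweenness}.
    """
    def edge(a, b):
        return (a, b) if a < b else (b, a)

    adj = {i: set() for i in range(n)}
    for (i, j) in lengths:
        adj[i].add(j)
        adj[j].add(i)
    bc = {e: 0.0 for e in lengths}
    for s, t in itertools.combinations(range(n), 2):
        paths = []

        def walk(node, visited, dist, path_edges):
            if node == t:
                paths.append((dist, list(path_edges)))
                return
            for nxt in adj[node]:
                if nxt in visited:
                    continue
                e = edge(node, nxt)
                visited.add(nxt)
                path_edges.append(e)
                walk(nxt, visited, dist + lengths[e], path_edges)
                path_edges.pop()
                visited.remove(nxt)

        walk(s, {s}, 0.0, [])
        if not paths:
            continue
        dmin = min(d for d, _ in paths)
        minimal = [p for d, p in paths if d <= dmin * (1 + 1e-12)]
        for p in minimal:
            for e in p:
                bc[e] += 1.0 / len(minimal)
    return bc


def set_partitions(items):
    """All partitions of a list (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def exhaustive_max_modularity(weights: np.ndarray):
    """Maximum weighted modularity over every partition of the nodes.

    ``weights`` is a symmetric nonnegative matrix with zero diagonal.
    Returns (best_q, best_partition as list of sets).
    """
    n = weights.shape[0]
    two_m = weights.sum()
    deg = weights.sum(axis=1)
    best_q, best = -np.inf, None
    for part in set_partitions(range(n)):
        q = 0.0
        for block in part:
            idx = np.array(block)
            q += weights[np.ix_(idx, idx)].sum() / two_m
            q -= (deg[idx].sum() / two_m) ** 2
        if q > best_q:
            best_q, best = q, [set(b) for b in part]
    return best_q, best


def greedy_match_oracle(cases, controls, cfg, order):
    """Reference greedy matcher: explicit eligibility scan + argmin.

    ``order`` is the case processing order (indices).  Mirrors the documented
    contract with an independent, unoptimised implementation.
    """
    everyone = list(cases) + list(controls)

    def sd(values):
        s = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        return s if s > 0 else 1.0

    icv_sd = sd([r.icv for r in everyone])
    age_sd = sd([r.age for r in everyone])
    fwd_sd = sd([r.mean_fwd for r in everyone])
    used = set()
    pairs = []
    unmatched = []
    for idx in order:
        c = cases[idx]
        candidates = []
        for k in controls:
            if k.subject_id in used or k.sex != c.sex or k.collection != c.collection:
                continue
            da = abs(k.age - c.age)
            df = abs(k.mean_fwd - c.mean_fwd)
            di = abs(k.icv - c.icv)
            if da > cfg.caliper_age or df > cfg.caliper_fwd:
                continue
            if di > cfg.caliper_icv * icv_sd:
                continue
            dist = np.sqrt(
                (da / age_sd) ** 2 + (df / fwd_sd) ** 2 + (di / icv_sd) ** 2
            )
            candidates.append((dist, k.subject_id))
        if candidates:
            _, best = min(candidates, key=lambda t: t[0])
            used.add(best)
            pairs.append((c.subject_id, best))
        else:
            unmatched.append(c.subject_id)
    return pairs, unmatched
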