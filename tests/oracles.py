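"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Rank-sum test


def exact_rank_sum_p_greater(x, y) -> float:
    """One-sided (greater) conditional permutation p-value via the U statistic.

    Counts U = #{x_i > y_j} + 0.5 #{x_i == y_j} for every assignment of the
    pooled values to the first group.
    """
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    observed = u_stat(list(x), list(y))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        chosen = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_stat(chosen, rest) >= observed - 1e-9:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Boolean dynamics


def synchronous_step(nodes, edges, rule, state: dict) -> dict:
    """One update computed per node from the raw edge list."""
    nxt = {}
    for n in nodes:
        a = sum(e.weight for e in edges if e.target == n and e.sign == "activation" and state[e.source])
        i = sum(e.weight for e in edges if e.target == n and e.sign == "inhibition" and state[e.source])
        if rule == "threshold":
            nxt[n] = 1 if a > i else (0 if i > a else state[n])
        else:
            nxt[n] = 0 if i > 0 else (1 if a > 0 else state[n])
    return nxt


def attractor_from(nodes, edges, rule, start: dict) -> frozenset:
    """The attractor's state set reached from ``start`` (exhaustive trace)."""
    seen = []
    state = dict(start)
    key = tuple(state[n] for n in nodes)
    while key not in seen:
        seen.append(key)
        state = synchronous_step(nodes, edges, rule, state)
        key = tuple(state[n] for n in nodes)
    return frozenset(seen[seen.index(key) :])


# ---------------------------------------------------------------------------
# Graphs


def scc_partition_by_reachability(nodes, pairs) -> set[frozenset]:
    """SCCs from the boolean transitive closure (Floyd-Warshall style)."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    reach = np.eye(n, dtype=bool)
    for s, t in pairs:
        reach[idx[s], idx[t]] = True
    for k in range(n):
        reach |= reach[:, k : k + 1] & reach[k : k + 1, :]
    comps = set()
    for i in range(n):
        comp = frozenset(nodes[j] for j in range(n) if reach[i, j] and reach[j, i])
        comps.add(comp)
    return comps


def all_elementary_cycles(nodes, pairs) -> set[tuple]:
    """Every elementary cycle by brute-force DFS over simple paths."""
    succ = {v: [] for v in nodes}
    for s, t in pairs:
        succ[s].append(t)
    cycles = set()

    def canon(cyc):
        k = min(range(len(cyc)), key=lambda i: cyc[i])
        return tuple(cyc[k:]) + tuple(cyc[:k])

    def dfs(path, visiting):
        head = path[-1]
        for nxt in succ[head]:
            if nxt == path[0]:
                cycles.add(canon(path))
            elif nxt not in visiting and nxt > path[0]:
                dfs(path + [nxt], visiting | {nxt})

    for v in nodes:
        dfs([v], {v})
    return cycles


# ---------------------------------------------------------------------------
# MRNET


def mrmr_strengths(mi: np.ndarray) -> np.ndarray:
    """Brute-force greedy MRMR selection, written as plain loops."""
    g = mi.shape[0]
    score = [[None] * g for _ in range(g)]
    for t in range(g):
        remaining = [j for j in range(g) if j != t]
        chosen = []
        while remaining:
            best_j, best_s = None, None
            for j in remaining:
                red = sum(mi[j][k] for k in chosen) / len(chosen) if chosen else 0.0
                s = mi[j][t] - red
                if best_s is None or s > best_s:
                    best_j, best_s = j, s
            score[best_j][t] = best_s
            chosen.append(best_j)
            remaining.remove(best_j)
    out = np.zeros((g, g))
    for i in range(g):
        for j in range(g):
            if i != j:
                out[i, j] = max(score[i][j], score[j][i], 0.0)
    return out


def plugin_mi_from_counts(joint: np.ndarray) -> float:
    """Plug-in MI (nats) from a joint count table, via the definition."""
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            if p[i, j] > 0:
                mi += p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
    return mi
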