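"""Independent brute-force oracles for the test suite.

Everything here is deliberately naive — exhaustive enumeration, exact
rational arithmetic, quadratic loops — and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

MATCH, MISMATCH, GAP = 1, -1, -2


def enumerate_global_alignments(a: str, b: str):
    """All global alignments of a and b as (score, identity) pairs.

    Exponential; only for strings of length <= ~7.
    """
    results = []

    def rec(i, j, score, matches, columns):
        if i == len(a) and j == len(b):
            results.append((score, matches / columns if columns else 1.0))
            return
        if i < len(a) and j < len(b):
            s = MATCH if a[i] == b[j] else MISMATCH
            rec(i + 1, j + 1, score + s, matches + (a[i] == b[j]), columns + 1)
        if i < len(a):
            rec(i + 1, j, score + GAP, matches, columns + 1)
        if j < len(b):
            rec(i, j + 1, score + GAP, matches, columns + 1)

    rec(0, 0, 0, 0, 0)
    return results


def optimal_alignment_identities(a: str, b: str) -> set[float]:
    """Identities of every maximum-score global alignment of a and b."""
    alignments = enumerate_global_alignments(a, b)
    best = max(s for s, _ in alignments)
    return {ident for s, ident in alignments if s == best}


def hypergeom_right_tail_exact(n11: int, n10: int, n01: int, n00: int) -> Fraction:
    """Exact one-sided Fisher p as a rational number (full tail enumeration)."""
    N = n11 + n10 + n01 + n00
    K = n11 + n10
    n = n11 + n01
    denom = math.comb(N, n)
    total = Fraction(0)
    for k in range(n11, min(K, n) + 1):
        total += Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
    return total


def bky_two_stage_reject(p_values, q: float):
    """Direct loop implementation of the two-stage step-up at level q."""
    m = len(p_values)
    q1 = q / (1.0 + q)

    def bh_reject(pvals, level):
        indexed = sorted(range(m), key=lambda i: pvals[i])
        cutoff = -1
        for rank, i in enumerate(indexed, start=1):
            if pvals[i] <= level * rank / m:
                cutoff = rank
        rejected = [False] * m
        for rank, i in enumerate(indexed, start=1):
            if rank <= cutoff:
                rejected[i] = True
        return rejected

    stage1 = bh_reject(p_values, q1)
    r1 = sum(stage1)
    if r1 == 0:
        return [False] * m
    if r1 == m:
        return [True] * m
    return bh_reject(p_values, q1 * m / (m - r1))


def bky_adjusted_closed_form(p_values):
    """Smallest rejecting FDR level per hypothesis, by interval enumeration.

    Works on the BH-adjusted values: on each interval of the stage-1 level
    t = q/(1+q) where the stage-1 rejection count r1 is constant, hypothesis
    i is rejected iff t >= bh_i (m - r1) / m, giving a closed-form minimum.
    q <= 1 corresponds to t <= 1/2.
    """
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    bh = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, p_values[i] * m / rank)
        bh[i] = running
    uniq = sorted(set(bh))
    r1_at = [sum(1 for v in bh if v <= t_k) for t_k in uniq]
    out = []
    for i in range(m):
        best_t = None
        for k, t_k in enumerate(uniq):
            r1 = r1_at[k]
            upper = uniq[k + 1] if k + 1 < len(uniq) else 0.5 + 1e-12
            if r1 == m:
                cand = t_k
            else:
                cand = max(t_k, bh[i] * (m - r1) / m)
            if cand <= 0.5 and cand < upper:
                best_t = cand
                break
        out.append(1.0 if best_t is None else best_t / (1.0 - best_t))
    return out


def connected_components_bfs(edges):
    """Components of an undirected edge list, as frozensets of nodes."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen = set()
    components = []
    for start in adj:
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            v = queue.pop()
            if v in comp:
                continue
            comp.add(v)
            queue.extend(adj[v] - comp)
        seen |= comp
        components.append(frozenset(comp))
    return components


def best_injective_assignment(weights: dict) -> float:
    """Max total weight over injective node -> position assignments.

    ``weights[(node, position)]`` = weight; exhaustive over all subsets and
    permutations, for <= ~6 nodes/positions.
    """
    nodes = sorted({n for n, _ in weights})
    positions = sorted({p for _, p in weights})
    best = 0.0
    for r in range(1, min(len(nodes), len(positions)) + 1):
        for chosen in itertools.combinations(nodes, r):
            for perm in itertools.permutations(positions, r):
                total = 0.0
                ok = True
                for n, p in zip(chosen, perm):
                    w = weights.get((n, p), 0.0)
                    if w <= 0:
                        ok = False
                        break
                    total += w
                if ok:
                    best = max(best, total)
    return best


def gotoh_local_score(query: str, target: str, matrix, open_gap=-11.0, extend_gap=-1.0):
    """Smith-Waterman with affine gaps; returns the best local score."""
    n, m = len(query), len(target)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]
    F = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_gap, E[i][j - 1] + extend_gap)
            F[i][j] = max(H[i - 1][j] + open_gap, F[i - 1][j] + extend_gap)
            s = matrix[query[i - 1], target[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
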